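"""Relative NIR-II photoluminescence quantum yield, extinction and brightness.

The quantum yield Φ of a sample is measured relative to a reference dye of
known Φ_ref (IR-26 in 1,2-dichloroethane, Φ = 0.5%) by the dilution-series
slope method: integrated emission (900-1500 nm) is plotted against absorbance
at the excitation wavelength for ~5 dilutions, and

    Φ_sample = Φ_ref * (slope_sample / slope_ref) * (η_sample / η_ref)**2

where η are the solvent refractive indices.  Molar extinction follows
Beer-Lambert (ε = A / (c·l)) and fluorophore brightness is the product ε·Φ
at the excitation wavelength, in M⁻¹cm⁻¹.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, InputError
from .spectra import BandWindow, SampleMeta, Spectrum, integrate_band

__all__ = [
    "REFRACTIVE_INDEX",
    "QY_INTEGRATION_WINDOW",
    "DilutionSeries",
    "SlopeFit",
    "QYResult",
    "BrightnessRecord",
    "fit_slope",
    "relative_qy",
    "integrated_emission",
    "beer_lambert_epsilon",
    "brightness",
]

#: Solvent refractive indices at visible/NIR wavelengths (dimensionless).
#: Override per-sample via SampleMeta.refractive_index.
REFRACTIVE_INDEX = {
    "water": 1.333,
    "thf": 1.407,
    "dce": 1.444,  # 1,2-dichloroethane, the IR-26 reference solvent
}

#: Emission integration window of the slope-method protocol.
QY_INTEGRATION_WINDOW = BandWindow(900.0, 1500.0)


@dataclass(frozen=True)
class DilutionSeries:
    """(absorbance, integrated emission) pairs at decreasing concentration.

    Absorbance at the excitation wavelength is kept <= 0.2 (protocol caps it
    at ~0.1) so inner-filter effects stay negligible.
    """

    absorbance: np.ndarray
    integrated_emission: np.ndarray
    meta: SampleMeta = field(default_factory=SampleMeta)

    def __post_init__(self):
        a = np.asarray(self.absorbance, dtype=float)
        em = np.asarray(self.integrated_emission, dtype=float)
        object.__setattr__(self, "absorbance", a)
        object.__setattr__(self, "integrated_emission", em)
        if a.size != em.size or a.size < 3:
            raise InputError("dilution series needs >= 3 (absorbance, emission) pairs")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(em))):
            raise InputError("dilution series contains non-finite values")
        if np.any(a <= 0) or np.any(a > 0.2):
            raise InputError("absorbances must lie in (0, 0.2]")
        if np.unique(a).size != a.size:
            raise InputError("absorbances must be distinct")
        if np.any(em < 0):
            raise InputError("integrated emission must be >= 0")


@dataclass(frozen=True)
class SlopeFit:
    slope: float
    intercept: float
    slope_se: float
    r_squared: float

    def __post_init__(self):
        if self.slope_se < 0:
            raise InputError("slope_se must be >= 0")


@dataclass(frozen=True)
class QYResult:
    phi: float
    phi_se: float
    reference_phi: float

    def __post_init__(self):
        if self.phi < 0:
            raise DegenerateInputError("phi must be >= 0")


@dataclass(frozen=True)
class BrightnessRecord:
    epsilon_M1cm1: float
    phi: float
    brightness_M1cm1: float

    def __post_init__(self):
        expected = self.epsilon_M1cm1 * self.phi
        if abs(self.brightness_M1cm1 - expected) > 1e-12 * max(abs(expected), 1.0):
            raise InputError("brightness must equal epsilon * phi")


def fit_slope(series: DilutionSeries, through_origin: bool = False) -> SlopeFit:
    """OLS line through the dilution series (free intercept by default).

    A free intercept tolerates a constant background in the integrated
    emission; ``through_origin=True`` forces the physical zero for
    sensitivity checks.
    """
    a, em = series.absorbance, series.integrated_emission
    if np.ptp(a) == 0:
        raise DegenerateInputError("degenerate series: absorbances are collinear")
    if through_origin:
        slope = float(np.dot(a, em) / np.dot(a, a))
        resid = em - slope * a
        dof = a.size - 1
        se = math.sqrt(float(np.dot(resid, resid)) / dof / float(np.dot(a, a))) if dof else 0.0
        ss_tot = float(np.dot(em - em.mean(), em - em.mean()))
        r2 = 1.0 - float(np.dot(resid, resid)) / ss_tot if ss_tot > 0 else 1.0
        return SlopeFit(slope, 0.0, se, max(min(r2, 1.0), 0.0))
    fit = stats.linregress(a, em)
    return SlopeFit(float(fit.slope), float(fit.intercept), float(fit.stderr), float(fit.rvalue**2))


def integrated_emission(spec: Spectrum, window: BandWindow = QY_INTEGRATION_WINDOW) -> float:
    """Integral of an emission spectrum over the protocol window (900-1500 nm)."""
    return integrate_band(spec, window)


def relative_qy(
    slope_sample: float | SlopeFit,
    slope_ref: float | SlopeFit,
    eta_sample: float,
    eta_ref: float,
    phi_ref: float,
) -> QYResult:
    """Slope-method quantum yield with the refractive-index correction.

    Standard errors, when SlopeFit objects are supplied, propagate in
    quadrature from the two slope SEs.
    """
    s_s, se_s = (slope_sample.slope, slope_sample.slope_se) if isinstance(slope_sample, SlopeFit) else (float(slope_sample), 0.0)
    s_r, se_r = (slope_ref.slope, slope_ref.slope_se) if isinstance(slope_ref, SlopeFit) else (float(slope_ref), 0.0)
    if s_s <= 0 or s_r <= 0:
        raise DegenerateInputError(
            f"non-positive slope (sample {s_s}, reference {s_r}): failed dilution series"
        )
    if not (0 < phi_ref <= 1):
        raise InputError("phi_ref must lie in (0, 1]")
    if eta_sample <= 1 or eta_ref <= 1:
        raise InputError("refractive indices must exceed 1")
    phi = phi_ref * (s_s / s_r) * (eta_sample / eta_ref) ** 2
    rel_var = (se_s / s_s) ** 2 + (se_r / s_r) ** 2
    return QYResult(phi, phi * math.sqrt(rel_var), phi_ref)


def beer_lambert_epsilon(absorbance: float, concentration_M: float, path_cm: float = 1.0) -> float:
    """Molar extinction coefficient ε = A / (c·l) in M⁻¹cm⁻¹."""
    if concentration_M <= 0 or path_cm <= 0:
        raise InputError("concentration and path length must be > 0")
    return absorbance / (concentration_M * path_cm)


def brightness(epsilon: float, phi: float) -> BrightnessRecord:
    """Fluorophore brightness ε·Φ at the excitation wavelength."""
    if epsilon < 0:
        raise InputError("epsilon must be >= 0")
    if not (0 <= phi <= 1):
        raise InputError("phi must lie in [0, 1]")
    return BrightnessRecord(epsilon, phi, epsilon * phi)
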