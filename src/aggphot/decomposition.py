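"""Gaussian mixture decomposition of absorption/emission spectra.

Aggregated NIR-II fluorophores show two spectrally distinct populations:
isolated molecules (monomers) and close-packed pairs (dimers) whose bands are
red-shifted (emission near 940 vs 1050 nm, absorption near 760 vs 840 nm).
This module fits a sum of Gaussian bands plus an optional linear baseline to
a spectrum, assigns each band to a population from its fitted center, and
reports population weights as analytic area fractions
(area = amplitude * sigma * sqrt(2*pi)) — areas, not peak heights, are the
spectrally meaningful photon counts.

The fit is deterministic for a fixed input: initialization derives from a
5-point moving-average smoothing (highest local maximum inside each prior
window seeds the center), and the jittered restarts used on non-convergence
come from a fixed table rather than an RNG.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import ConfigError, DegenerateInputError, FitError
from .spectra import BandWindow, Spectrum, SpectrumKind, integrate_band

__all__ = [
    "BandLabel",
    "GaussianBand",
    "ComponentPriors",
    "DecompositionResult",
    "default_priors",
    "fit_gaussian_mixture",
    "population_weights",
    "select_band_count",
    "decompose_titration",
]

SQRT_2PI = math.sqrt(2.0 * math.pi)

SIGMA_BOUNDS_NM = (2.0, 200.0)

#: Default center windows from the observed band positions: emission bands of
#: monomers (~940 nm) and dimers (~1050 nm); absorption bands at ~760/~840 nm.
DEFAULT_CENTER_WINDOWS = {
    SpectrumKind.EMISSION: {"monomer": BandWindow(900, 980), "dimer": BandWindow(1000, 1120)},
    SpectrumKind.ABSORPTION: {"monomer": BandWindow(720, 800), "dimer": BandWindow(810, 880)},
}

# fixed jitter table for restarts on non-convergence: (center shift as a
# fraction of the prior window width, sigma scale factor)
_JITTER_TABLE = ((-0.25, 0.5), (0.25, 1.5), (0.0, 2.0))


class BandLabel(str, Enum):
    MONOMER = "monomer"
    DIMER = "dimer"
    UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class GaussianBand:
    """One fitted Gaussian component a*exp(-(x-mu)^2 / (2 sigma^2))."""

    center_nm: float
    sigma_nm: float
    amplitude: float
    label: BandLabel = BandLabel.UNASSIGNED

    def __post_init__(self):
        if self.sigma_nm <= 0:
            raise DegenerateInputError("sigma_nm must be > 0")
        if self.amplitude <= 0:
            raise DegenerateInputError("amplitude must be > 0")

    @property
    def area(self) -> float:
        return self.amplitude * self.sigma_nm * SQRT_2PI

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(-((x - self.center_nm) ** 2) / (2.0 * self.sigma_nm**2))


@dataclass(frozen=True)
class ComponentPriors:
    """Allowed center windows per population label, and the component budget."""

    monomer: BandWindow
    dimer: BandWindow
    max_components: int = 2

    def __post_init__(self):
        if self.max_components < 1:
            raise ConfigError("max_components must be >= 1")
        if not (self.monomer.hi_nm <= self.dimer.lo_nm or self.dimer.hi_nm <= self.monomer.lo_nm):
            raise ConfigError("monomer and dimer center windows must be disjoint")

    def label_for_center(self, center: float) -> BandLabel:
        if self.monomer.contains(center):
            return BandLabel.MONOMER
        if self.dimer.contains(center):
            return BandLabel.DIMER
        return BandLabel.UNASSIGNED


def default_priors(kind: SpectrumKind | str, max_components: int = 2) -> ComponentPriors:
    wins = DEFAULT_CENTER_WINDOWS[SpectrumKind(kind)]
    return ComponentPriors(wins["monomer"], wins["dimer"], max_components)


@dataclass(frozen=True)
class DecompositionResult:
    bands: tuple[GaussianBand, ...]
    baseline: tuple[float, float]  # (b0, b1); (0, 0) when no baseline was fit
    residual_rms: float
    weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "bands", tuple(sorted(self.bands, key=lambda b: b.center_nm)))
        if self.weights:
            total = sum(self.weights.values())
            if abs(total - 1.0) > 1e-9:
                raise DegenerateInputError(f"weights sum to {total}, expected 1")

    def model(self, x: np.ndarray) -> np.ndarray:
        y = self.baseline[0] + self.baseline[1] * np.asarray(x, dtype=float)
        for band in self.bands:
            y = y + band(x)
        return y


def population_weights(bands) -> dict[str, float]:
    """Area fraction per label: sum of labelled band areas over the total area."""
    band_list = list(bands.bands) if isinstance(bands, DecompositionResult) else list(bands)
    if not band_list:
        raise DegenerateInputError("no bands to weight")
    total = sum(b.area for b in band_list)
    if total <= 0:
        raise DegenerateInputError("zero total band area")
    out: dict[str, float] = {}
    for b in band_list:
        out[b.label.value] = out.get(b.label.value, 0.0) + b.area / total
    return out


def _moving_average(y: np.ndarray, width: int = 5) -> np.ndarray:
    kernel = np.ones(width) / width
    pad = width // 2
    ypad = np.pad(y, pad, mode="edge")
    return np.convolve(ypad, kernel, mode="valid")


def _window_seed(wl: np.ndarray, smooth: np.ndarray, win: BandWindow) -> tuple[float, float]:
    """(center, amplitude) seed: highest local maximum of the smoothed data in the window."""
    mask = (wl >= win.lo_nm) & (wl <= win.hi_nm)
    if not np.any(mask):
        return win.center_nm, float(np.max(smooth))
    idx = np.flatnonzero(mask)
    seg = smooth[idx]
    interior = np.flatnonzero((seg[1:-1] >= seg[:-2]) & (seg[1:-1] >= seg[2:])) + 1
    best = idx[interior[np.argmax(seg[interior])]] if interior.size else idx[np.argmax(seg)]
    return float(wl[best]), float(smooth[best])


def _initial_guesses(
    spec: Spectrum, n: int, priors: ComponentPriors
) -> tuple[list[tuple[float, float, float]], list[BandWindow]]:
    """Per-component (amplitude, center, sigma) seeds and their center bounds."""
    wl = spec.wavelengths_nm
    smooth = _moving_average(spec.intensities)
    seeds: list[tuple[float, float, float]] = []
    windows: list[BandWindow] = []
    labelled = [priors.monomer, priors.dimer]
    if n == 1:
        # single band: use whichever labelled window holds the stronger peak
        cands = [(_window_seed(wl, smooth, w), w) for w in labelled]
        (c, a), w = max(cands, key=lambda t: t[0][1])
        seeds.append((max(a, 1e-12), c, w.width_nm / 4.0))
        windows.append(w)
    else:
        for w in labelled[: min(n, 2)]:
            c, a = _window_seed(wl, smooth, w)
            seeds.append((max(a, 1e-12), c, w.width_nm / 4.0))
            windows.append(w)
        # extra unassigned components roam the full support, seeded at the
        # strongest smoothed point outside the labelled windows
        support = spec.support
        for _ in range(n - 2):
            outside = np.ones_like(wl, dtype=bool)
            for w in labelled:
                outside &= ~((wl >= w.lo_nm) & (wl <= w.hi_nm))
            j = int(np.argmax(np.where(outside, smooth, -np.inf)))
            seeds.append((max(float(smooth[j]), 1e-12), float(wl[j]), support.width_nm / 8.0))
            windows.append(support)
    return seeds, windows


def _pack_bounds(
    seeds, windows, peak: float, use_baseline: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    p0, lo, hi = [], [], []
    for (a, c, s), w in zip(seeds, windows):
        p0 += [a, min(max(c, w.lo_nm), w.hi_nm), float(np.clip(s, *SIGMA_BOUNDS_NM))]
        lo += [0.0, w.lo_nm, SIGMA_BOUNDS_NM[0]]
        hi += [10.0 * peak, w.hi_nm, SIGMA_BOUNDS_NM[1]]
    if use_baseline:
        p0 += [0.0, 0.0]
        lo += [-np.inf, -np.inf]
        hi += [np.inf, np.inf]
    return np.array(p0), np.array(lo), np.array(hi)


def _mixture_model(params: np.ndarray, x: np.ndarray, n: int, use_baseline: bool) -> np.ndarray:
    y = np.zeros_like(x)
    for i in range(n):
        a, c, s = params[3 * i : 3 * i + 3]
        y += a * np.exp(-((x - c) ** 2) / (2.0 * s**2))
    if use_baseline:
        y += params[3 * n] + params[3 * n + 1] * x
    return y


def fit_gaussian_mixture(
    spec: Spectrum,
    n: int,
    priors: ComponentPriors | None = None,
    baseline: bool | None = None,
) -> DecompositionResult:
    """Least-squares fit of ``n`` Gaussian bands (+ optional linear baseline).

    Centers are bounded to the prior windows, sigma to [2, 200] nm and
    amplitudes to >= 0.  ``baseline=None`` enables the linear baseline for
    emission spectra (NIR-II detector offsets) and disables it for absorption.
    """
    if priors is None:
        priors = default_priors(spec.kind)
    if n < 1:
        raise ConfigError("n must be >= 1")
    if n > priors.max_components:
        raise ConfigError(f"n={n} exceeds max_components={priors.max_components}")
    if baseline is None:
        baseline = spec.kind == SpectrumKind.EMISSION

    x, y = spec.wavelengths_nm, spec.intensities
    peak = float(np.max(np.abs(y))) or 1.0
    seeds, windows = _initial_guesses(spec, n, priors)

    attempts = [(0.0, 1.0), *_JITTER_TABLE]
    best = None
    for shift_frac, sig_scale in attempts:
        jittered = [
            (a, min(max(c + shift_frac * w.width_nm, w.lo_nm), w.hi_nm), s * sig_scale)
            for (a, c, s), w in zip(seeds, windows)
        ]
        p0, lo, hi = _pack_bounds(jittered, windows, peak, baseline)
        sol = least_squares(
            lambda p: _mixture_model(p, x, n, baseline) - y,
            p0, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12,
        )
        if best is None or sol.cost < best.cost:
            best = sol
        if sol.success:
            best = sol if sol.cost <= best.cost else best
            break
    if best is None or not best.success:
        rms = math.sqrt(2.0 * best.cost / x.size) if best is not None else float("nan")
        raise FitError(f"Gaussian mixture fit did not converge (n={n})", best_residual=rms)

    p = best.x
    bands = []
    for i in range(n):
        a, c, s = p[3 * i : 3 * i + 3]
        bands.append(GaussianBand(float(c), float(s), float(max(a, 1e-300)), priors.label_for_center(float(c))))
    b0, b1 = (float(p[3 * n]), float(p[3 * n + 1])) if baseline else (0.0, 0.0)
    rms = math.sqrt(float(np.mean((_mixture_model(p, x, n, baseline) - y) ** 2)))
    res = DecompositionResult(tuple(bands), (b0, b1), rms)
    return DecompositionResult(res.bands, res.baseline, res.residual_rms, population_weights(res))


def _bic(rss: float, m: int, k: int) -> float:
    return m * math.log(max(rss, 1e-300) / m) + k * math.log(m)


def select_band_count(
    spec: Spectrum,
    priors: ComponentPriors | None = None,
    baseline: bool | None = None,
) -> int:
    """Number of bands minimizing BIC = m*ln(RSS/m) + k*ln(m); ties take fewer bands."""
    if priors is None:
        priors = default_priors(spec.kind)
    if priors.max_components > 4:
        raise ConfigError("max_components must be <= 4 for model selection")
    use_baseline = (spec.kind == SpectrumKind.EMISSION) if baseline is None else baseline
    m = len(spec)
    best_n, best_bic = None, np.inf
    for n in range(1, priors.max_components + 1):
        try:
            res = fit_gaussian_mixture(spec, n, priors, baseline=use_baseline)
        except FitError:
            continue
        k = 3 * n + (2 if use_baseline else 0)
        bic = _bic(m * res.residual_rms**2, m, k)
        if bic < best_bic - 1e-12:  # strict improvement; ties keep smaller n
            best_n, best_bic = n, bic
    if best_n is None:
        raise FitError("no band count converged")
    return best_n


INTENSITY_WINDOW = BandWindow(900.0, 1500.0)


def decompose_titration(
    series: list[Spectrum],
    priors: ComponentPriors | None = None,
    intensity_window: BandWindow = INTENSITY_WINDOW,
) -> pd.DataFrame:
    """Per-spectrum model selection and decomposition along a water-fraction series.

    Returns a DataFrame with columns ``f_w``, ``n_bands``, ``dimer_weight``
    (0 when a single monomer band is selected) and ``total_intensity``
    (integral over the 900-1500 nm window by default).
    """
    if len(series) < 2:
        raise DegenerateInputError("titration needs >= 2 spectra")
    fws = [s.meta.water_fraction for s in series]
    if len(set(fws)) != len(fws):
        raise DegenerateInputError("water fractions must be distinct")
    rows = []
    for spec in series:
        fw = spec.meta.water_fraction
        try:
            n = select_band_count(spec, priors)
            res = fit_gaussian_mixture(spec, n, priors)
        except FitError as exc:
            raise FitError(f"decomposition failed at f_w={fw}: {exc}") from exc
        rows.append(
            {
                "f_w": fw,
                "n_bands": n,
                "dimer_weight": res.weights.get(BandLabel.DIMER.value, 0.0),
                "total_intensity": integrate_band(spec, intensity_window),
            }
        )
    return pd.DataFrame(rows).sort_values("f_w", ignore_index=True)
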