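"""IRF-convolved multi-exponential fitting of transient-absorption kinetics.

A femtosecond pump-probe trace at a single probe wavelength (here inside the
ground-state-bleach region, so ΔOD < 0) is modelled as a sum of exponential
decays convolved with a Gaussian instrument response of FWHM ~120 fs.  The
Gaussian ⊗ exponential convolution has the closed form

    (A/2) · exp(s²/(2τ²) − t'/τ) · erfc(s/(√2 τ) − t'/(√2 s)),

with t' = t − t0 and s = FWHM/(2√(2 ln 2)).  Direct evaluation overflows at
long delays; this module evaluates it through the scaled complementary error
function erfcx, which is exact and stable for every sign of the argument.

Fitting uses variable projection: the time constants (and t0, and optionally
the IRF width) are optimized nonlinearly with τ in log space, while the
amplitudes and the constant offset are solved linearly at every step.
Amplitude fractions |Aᵢ|/Σ|Aⱼ| are the per-channel populations; components
are classified by time-constant windows into ultrafast intermolecular
nonradiative decay (interNR, the dimer quenching channel), dimer emission,
and monomer fluorescence.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares
from scipy.special import erfcx

from .errors import ConfigError, DegenerateInputError, FitError, InputError

__all__ = [
    "DecayChannel",
    "KineticTrace",
    "IRFSpec",
    "ExpComponent",
    "MultiExpFit",
    "ModelSelection",
    "ClassificationRules",
    "LifetimeReport",
    "read_trace",
    "convolved_multiexp",
    "fit_multiexponential",
    "amplitude_fractions",
    "select_component_count",
    "classify_decay_components",
    "lifetime_consistency",
]

SQRT2 = math.sqrt(2.0)
FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.3548...

TAU_BOUNDS_PS = (0.05, 5000.0)


class DecayChannel(str, Enum):
    INTER_NR = "interNR"
    DIMER_EMISSION = "dimer_emission"
    MONOMER_FLUORESCENCE = "monomer_fluorescence"
    UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class KineticTrace:
    """ΔOD versus pump-probe delay at one probe wavelength."""

    delays_ps: np.ndarray
    delta_od: np.ndarray
    probe_nm: float = float("nan")
    pump_nm: float = 808.0

    def __post_init__(self):
        t = np.asarray(self.delays_ps, dtype=float)
        y = np.asarray(self.delta_od, dtype=float)
        object.__setattr__(self, "delays_ps", t)
        object.__setattr__(self, "delta_od", y)
        if t.size != y.size or t.size < 20:
            raise InputError("trace needs >= 20 equal-length (delay, ΔOD) points")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
            raise InputError("trace contains non-finite values")
        if np.any(np.diff(t) <= 0):
            raise InputError("delays must be strictly increasing")
        if t[0] >= 0 or t[-1] <= 0:
            raise InputError("delays must span negative and positive times")


@dataclass(frozen=True)
class IRFSpec:
    """Gaussian instrument response: FWHM in ps (default 120 fs) and time zero."""

    fwhm_ps: float = 0.12
    t0_ps: float = 0.0

    def __post_init__(self):
        if self.fwhm_ps <= 0:
            raise InputError("IRF fwhm must be > 0")

    @property
    def sigma_ps(self) -> float:
        return self.fwhm_ps / FWHM_TO_SIGMA


@dataclass(frozen=True)
class ExpComponent:
    tau_ps: float
    amplitude: float  # signed; ground-state-bleach components are negative
    label: DecayChannel = DecayChannel.UNASSIGNED

    def __post_init__(self):
        if self.tau_ps <= 0:
            raise InputError("tau_ps must be > 0")


@dataclass(frozen=True)
class MultiExpFit:
    components: tuple[ExpComponent, ...]
    irf: IRFSpec
    offset: float
    residual_rms: float
    fractions: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self):
        comps = tuple(sorted(self.components, key=lambda c: c.tau_ps))
        object.__setattr__(self, "components", comps)
        if not self.fractions:
            object.__setattr__(self, "fractions", tuple(amplitude_fractions(comps)))
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise DegenerateInputError("amplitude fractions must sum to 1")

    @property
    def taus_ps(self) -> tuple[float, ...]:
        return tuple(c.tau_ps for c in self.components)

    def model(self, delays_ps: np.ndarray) -> np.ndarray:
        return convolved_multiexp(delays_ps, self.components, self.irf, self.offset)


@dataclass(frozen=True)
class ModelSelection:
    candidates: dict[int, float]  # n -> BIC
    chosen_n: int

    def __post_init__(self):
        if self.chosen_n not in self.candidates:
            raise ConfigError("chosen_n must be one of the candidates")


def read_trace(path: str | Path, probe_nm: float = float("nan"), pump_nm: float = 808.0) -> KineticTrace:
    """Read a two-column (delay_ps, delta_od) text trace; '#' lines are comments."""
    rows = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) < 2:
            raise InputError(f"{path}:{lineno}: expected two columns")
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError:
            if rows:
                raise InputError(f"{path}:{lineno}: non-numeric row") from None
    arr = np.array(rows)
    return KineticTrace(arr[:, 0], arr[:, 1], probe_nm=probe_nm, pump_nm=pump_nm)


def _conv_exp_basis(t: np.ndarray, tau: float, t0: float, sigma: float) -> np.ndarray:
    """Unit-amplitude Gaussian(σ) ⊗ exp(-t/τ) step response, stable for all σ/τ.

    For erfc arguments x >= 0 the product erfcx(x)·exp(-t'²/2σ²) is used
    directly; for x < 0, erfc(x) = 2 - erfc(-x) splits the term into
    exp(σ²/2τ² - t'/τ) - ½·erfcx(-x)·exp(-t'²/2σ²), whose exponents are both
    non-positive there.
    """
    tp = t - t0
    if sigma <= 0:
        return np.where(tp >= 0, np.exp(-np.clip(tp, 0, None) / tau), 0.0)
    x = sigma / (SQRT2 * tau) - tp / (SQRT2 * sigma)
    gauss = np.exp(-(tp**2) / (2.0 * sigma**2))
    out = np.empty_like(tp, dtype=float)
    pos = x >= 0
    out[pos] = 0.5 * erfcx(x[pos]) * gauss[pos]
    neg = ~pos
    g = sigma**2 / (2.0 * tau**2) - tp[neg] / tau
    out[neg] = np.exp(g) - 0.5 * erfcx(-x[neg]) * gauss[neg]
    return out


def convolved_multiexp(delays_ps, components, irf: IRFSpec, offset: float = 0.0) -> np.ndarray:
    """Sum of IRF-convolved exponential components plus a constant offset."""
    t = np.asarray(delays_ps, dtype=float)
    y = np.full_like(t, float(offset))
    for comp in components:
        if comp.tau_ps <= 0:
            raise InputError("tau must be > 0")
        y = y + comp.amplitude * _conv_exp_basis(t, comp.tau_ps, irf.t0_ps, irf.sigma_ps)
    return y


def amplitude_fractions(fit) -> list[float]:
    """|Aᵢ| / Σ|Aⱼ| per component (constant offset excluded)."""
    comps = fit.components if isinstance(fit, MultiExpFit) else tuple(fit)
    if not comps:
        raise DegenerateInputError("no components")
    mags = np.array([abs(c.amplitude) for c in comps])
    total = mags.sum()
    if total == 0:
        raise DegenerateInputError("all amplitudes are zero")
    return list(mags / total)


def _estimate_t0(t: np.ndarray, y: np.ndarray) -> float:
    """Half-rise of |signal|: first crossing of half the absolute maximum."""
    a = np.abs(y)
    ipk = int(np.argmax(a))
    half = 0.5 * a[ipk]
    below = np.flatnonzero(a[: ipk + 1] <= half)
    if below.size == 0:
        return float(t[0])
    i = below[-1]
    if i == ipk:
        return float(t[ipk])
    # linear interpolation between the last sub-half point and the next one
    f = (half - a[i]) / max(a[i + 1] - a[i], 1e-300)
    return float(t[i] + f * (t[i + 1] - t[i]))


def _design_matrix(t, taus, t0, sigma) -> np.ndarray:
    cols = [_conv_exp_basis(t, tau, t0, sigma) for tau in taus]
    cols.append(np.ones_like(t))
    return np.column_stack(cols)


def _linear_solve(M: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    beta, *_ = np.linalg.lstsq(M, y, rcond=None)
    return beta, M @ beta - y


def fit_multiexponential(
    trace: KineticTrace,
    n: int,
    irf_fixed: IRFSpec | None = None,
    t0_ps: float | None = None,
) -> MultiExpFit:
    """Variable-projection fit of ``n`` IRF-convolved exponentials + offset.

    Time constants (log-space, bounded to [0.05, 5000] ps) and t0 — plus the
    IRF width when ``irf_fixed`` is None — are the nonlinear parameters;
    amplitudes and offset are solved linearly at every residual evaluation.
    Starting τ's come from the best n-subset (by linear residual) of an
    8-point log grid.
    """
    if not 1 <= n <= 4:
        raise ConfigError("n must be in [1, 4]")
    t, y = trace.delays_ps, trace.delta_od
    if t.size < 5 * (2 * n + 3):
        raise InputError(f"trace too short for n={n}: needs >= {5 * (2 * n + 3)} points")

    fit_fwhm = irf_fixed is None
    fwhm0 = 0.12 if fit_fwhm else irf_fixed.fwhm_ps
    t0_init = _estimate_t0(t, y) if t0_ps is None else float(t0_ps)
    dt = float(np.median(np.diff(t)))

    # candidate time constants on a log grid; best subset by linear residual
    lo_tau = max(2.0 * dt, TAU_BOUNDS_PS[0])
    hi_tau = min((t[-1] - t[0]) / 2.0, TAU_BOUNDS_PS[1])
    grid = np.geomspace(lo_tau, max(hi_tau, lo_tau * 10), 8)
    sigma0 = fwhm0 / FWHM_TO_SIGMA
    best_subset, best_rss = None, np.inf
    for subset in itertools.combinations(range(grid.size), n):
        taus = grid[list(subset)]
        _, resid = _linear_solve(_design_matrix(t, taus, t0_init, sigma0), y)
        rss = float(resid @ resid)
        if rss < best_rss:
            best_subset, best_rss = taus, rss

    t0_halfwidth = max(5.0 * sigma0, 2.0 * dt, 0.2)

    def theta_unpack(theta):
        taus = np.exp(theta[:n])
        t0 = theta[n]
        sigma = np.exp(theta[n + 1]) / FWHM_TO_SIGMA if fit_fwhm else sigma0
        return taus, t0, sigma

    def residual(theta):
        taus, t0, sigma = theta_unpack(theta)
        _, resid = _linear_solve(_design_matrix(t, taus, t0, sigma), y)
        return resid

    theta0 = list(np.log(best_subset)) + [t0_init]
    lo = [math.log(TAU_BOUNDS_PS[0])] * n + [t0_init - t0_halfwidth]
    hi = [math.log(TAU_BOUNDS_PS[1])] * n + [t0_init + t0_halfwidth]
    if fit_fwhm:
        theta0.append(math.log(fwhm0))
        lo.append(math.log(1e-3))
        hi.append(math.log(10.0))

    sol = least_squares(residual, theta0, bounds=(lo, hi), method="trf", xtol=1e-14, ftol=1e-14)
    if not sol.success:
        raise FitError(
            f"multi-exponential fit did not converge (n={n})",
            best_residual=math.sqrt(2.0 * sol.cost / t.size),
        )

    taus, t0, sigma = theta_unpack(sol.x)
    beta, resid = _linear_solve(_design_matrix(t, taus, t0, sigma), y)
    order = np.argsort(taus)
    taus, amps = taus[order], beta[:n][order]
    if n > 1 and np.any(np.diff(taus) / taus[:-1] < 0.10):
        warnings.warn(
            f"time constants collapse within 10% ({taus}); consider n={n - 1}",
            RuntimeWarning,
            stacklevel=2,
        )
    comps = tuple(ExpComponent(float(tau), float(a)) for tau, a in zip(taus, amps))
    irf = IRFSpec(fwhm_ps=float(sigma * FWHM_TO_SIGMA), t0_ps=float(t0))
    rms = math.sqrt(float(np.mean(resid**2)))
    return MultiExpFit(comps, irf, float(beta[n]), rms)


def select_component_count(
    trace: KineticTrace,
    max_n: int = 4,
    irf_fixed: IRFSpec | None = None,
) -> ModelSelection:
    """Component count minimizing BIC = m·ln(RSS/m) + k·ln(m); ties prefer fewer."""
    if max_n > 4:
        raise ConfigError("max_n must be <= 4")
    m = trace.delays_ps.size
    candidates: dict[int, float] = {}
    chosen, best_bic = None, np.inf
    for n in range(1, max_n + 1):
        try:
            fit = fit_multiexponential(trace, n, irf_fixed=irf_fixed)
        except (FitError, InputError):
            continue
        # nonlinear: n taus + t0 (+ fwhm); linear: n amplitudes + offset
        k = 2 * n + 2 + (1 if irf_fixed is None else 0)
        rss = m * fit.residual_rms**2
        bic = m * math.log(max(rss, 1e-300) / m) + k * math.log(m)
        candidates[n] = bic
        if bic < best_bic - 1e-12:
            chosen, best_bic = n, bic
    if chosen is None:
        raise FitError("no component count converged")
    return ModelSelection(candidates, chosen)


@dataclass(frozen=True)
class ClassificationRules:
    """τ windows separating decay channels (ps).

    Defaults bracket the observed constants: sub-ps intermolecular
    nonradiative decay (0.43-0.98 ps), dimer emission (7.7-11.6 ps) and
    monomer fluorescence (>= 134 ps).
    """

    inter_nr_max_ps: float = 2.0
    dimer_emission_max_ps: float = 50.0

    def label(self, tau_ps: float) -> DecayChannel:
        if tau_ps < self.inter_nr_max_ps:
            return DecayChannel.INTER_NR
        if tau_ps < self.dimer_emission_max_ps:
            return DecayChannel.DIMER_EMISSION
        return DecayChannel.MONOMER_FLUORESCENCE


def classify_decay_components(fit: MultiExpFit, rules: ClassificationRules | None = None) -> MultiExpFit:
    """Relabel every component by its time-constant window (deterministic)."""
    rules = rules or ClassificationRules()
    comps = tuple(replace(c, label=rules.label(c.tau_ps)) for c in fit.components)
    return replace(fit, components=comps)


@dataclass(frozen=True)
class LifetimeReport:
    tau_long_ps: float | None
    fluorescence_lifetime_ps: float
    relative_difference: float | None
    consistent: bool


def lifetime_consistency(
    fit: MultiExpFit, fluorescence_lifetime_ps: float, tol: float = 0.2
) -> LifetimeReport:
    """Check the longest-lived component against an independent fluorescence lifetime.

    The default tolerance 0.2 accommodates the typical 10-15% disagreement
    between the transient-absorption long component and a TCSPC lifetime.
    """
    labelled = classify_decay_components(fit)
    longs = [c for c in labelled.components if c.label == DecayChannel.MONOMER_FLUORESCENCE]
    if not longs:
        return LifetimeReport(None, fluorescence_lifetime_ps, None, False)
    tau_long = max(c.tau_ps for c in longs)
    rel = abs(tau_long - fluorescence_lifetime_ps) / fluorescence_lifetime_ps
    return LifetimeReport(tau_long, fluorescence_lifetime_ps, rel, rel <= tol)
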