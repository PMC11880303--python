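"""Synthetic instrument and animal data with the statistical structure the
analysis stages assume.

Every generator is a pure function of its config plus an integer seed
(bit-identical reruns); zero-noise outputs satisfy their defining closed
forms exactly, so recovery tests compare estimates against known generating
truth.  The preset registry reproduces each study condition by name:
two-band monomer/dimer mixture spectra (emission ~940/1050 nm, absorption
~760/840 nm), a water-fraction titration, linear quantum-yield dilution
series, 2-3 component ground-state-bleach traces convolved with a 120 fs
IRF, Gaussian-ridge vessel images, and a rise-and-fall tumor-uptake time
course peaking at 24 h.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError
from .imaging import ROI, IntensityImage
from .kinetics import ExpComponent, IRFSpec, KineticTrace, convolved_multiexp
from .quantum_yield import REFRACTIVE_INDEX, DilutionSeries
from .spectra import SampleMeta, Spectrum, SpectrumKind

__all__ = [
    "MixtureSpectrumConfig",
    "TitrationConfig",
    "QYSeriesConfig",
    "TraceConfig",
    "VesselImageConfig",
    "TimeCourseConfig",
    "gen_mixture_spectrum",
    "gen_titration_series",
    "gen_qy_series",
    "gen_ta_trace",
    "gen_vessel_image",
    "gen_timecourse_images",
    "PRESETS",
    "preset",
]

SQRT_2PI = math.sqrt(2.0 * math.pi)


# ---------------------------------------------------------------- spectra


@dataclass(frozen=True)
class MixtureSpectrumConfig:
    """Two-Gaussian monomer + dimer band mixture on a wavelength grid.

    ``dimer_fraction`` is the dimer share of the total band area; band widths
    default to σ = 40/60 nm (emission) chosen to mimic realistic NIR-II
    lineshapes.  Additive Gaussian noise has sd = noise_sigma_rel * max.
    """

    monomer_center_nm: float = 940.0
    monomer_sigma_nm: float = 40.0
    dimer_center_nm: float = 1050.0
    dimer_sigma_nm: float = 60.0
    dimer_fraction: float = 0.0
    total_area: float = 1000.0
    grid_lo_nm: float = 850.0
    grid_hi_nm: float = 1500.0
    grid_step_nm: float = 1.0
    noise_sigma_rel: float = 0.0
    kind: SpectrumKind = SpectrumKind.EMISSION
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.dimer_fraction <= 1.0:
            raise ConfigError("dimer_fraction must lie in [0, 1]")
        if self.grid_step_nm <= 0:
            raise ConfigError("grid step must be > 0")


ABSORPTION_MIXTURE = MixtureSpectrumConfig(
    monomer_center_nm=760.0,
    monomer_sigma_nm=25.0,
    dimer_center_nm=840.0,
    dimer_sigma_nm=20.0,
    grid_lo_nm=650.0,
    grid_hi_nm=950.0,
    kind=SpectrumKind.ABSORPTION,
)


def _gaussian(x: np.ndarray, center: float, sigma: float, area: float) -> np.ndarray:
    amp = area / (sigma * SQRT_2PI)
    return amp * np.exp(-((x - center) ** 2) / (2.0 * sigma**2))


def gen_mixture_spectrum(cfg: MixtureSpectrumConfig, seed: int | None = None, water_fraction: float = 1.0) -> Spectrum:
    """Monomer + dimer Gaussian mixture with seeded additive noise."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    wl = np.arange(cfg.grid_lo_nm, cfg.grid_hi_nm + cfg.grid_step_nm / 2, cfg.grid_step_nm)
    clean = _gaussian(wl, cfg.monomer_center_nm, cfg.monomer_sigma_nm, cfg.total_area * (1 - cfg.dimer_fraction))
    if cfg.dimer_fraction > 0:
        clean = clean + _gaussian(wl, cfg.dimer_center_nm, cfg.dimer_sigma_nm, cfg.total_area * cfg.dimer_fraction)
    y = clean + rng.normal(0.0, cfg.noise_sigma_rel * float(clean.max()), wl.size) if cfg.noise_sigma_rel > 0 else clean
    if cfg.kind == SpectrumKind.EMISSION:
        y = np.clip(y, 0.0, None)
    meta = SampleMeta(sample_id="synthetic_mixture", solvent="water", water_fraction=water_fraction)
    return Spectrum(wl, y, cfg.kind, meta)


@dataclass(frozen=True)
class TitrationConfig:
    """Water-fraction titration: dimer fraction 0 up to the aggregation onset
    (f_w = 0.1), rising linearly to ``dimer_fraction_max`` at f_w = 1, while
    the total emitted intensity falls linearly (aggregation-caused quenching).
    """

    f_w_grid: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
    onset_f_w: float = 0.1
    dimer_fraction_max: float = 0.643
    intensity_drop: float = 0.7  # total intensity falls to (1 - drop) at f_w = 1
    base: MixtureSpectrumConfig = field(default_factory=MixtureSpectrumConfig)
    noise_sigma_rel: float = 0.0
    seed: int = 0

    def dimer_fraction_at(self, f_w: float) -> float:
        if f_w <= self.onset_f_w:
            return 0.0
        return self.dimer_fraction_max * (f_w - self.onset_f_w) / (1.0 - self.onset_f_w)

    def intensity_at(self, f_w: float) -> float:
        return 1.0 - self.intensity_drop * f_w


def gen_titration_series(cfg: TitrationConfig, seed: int | None = None) -> list[Spectrum]:
    """One mixture spectrum per f_w point following both schedules."""
    base_seed = cfg.seed if seed is None else seed
    out = []
    for i, f_w in enumerate(cfg.f_w_grid):
        sub = replace(
            cfg.base,
            dimer_fraction=cfg.dimer_fraction_at(f_w),
            total_area=cfg.base.total_area * cfg.intensity_at(f_w),
            noise_sigma_rel=cfg.noise_sigma_rel,
        )
        out.append(gen_mixture_spectrum(sub, seed=base_seed + 1000 * i, water_fraction=f_w))
    return out


# ---------------------------------------------------------------- quantum yield


@dataclass(frozen=True)
class QYSeriesConfig:
    """Sample/reference dilution series constructed so the slope-method
    estimate equals ``true_phi`` exactly at zero noise."""

    true_phi: float = 0.075
    ref_phi: float = 0.005
    absorbances: tuple[float, ...] = (0.02, 0.04, 0.06, 0.08, 0.10)
    eta_sample: float = REFRACTIVE_INDEX["water"]
    eta_ref: float = REFRACTIVE_INDEX["dce"]
    noise_rel: float = 0.0
    ref_scale: float = 1.0e6  # arbitrary reference emission gain (counts/OD)
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.true_phi <= 1 and 0 < self.ref_phi <= 1):
            raise ConfigError("quantum yields must lie in (0, 1]")
        if max(self.absorbances) > 0.2:
            raise ConfigError("absorbances must be <= 0.2")


def gen_qy_series(cfg: QYSeriesConfig, seed: int | None = None) -> tuple[DilutionSeries, DilutionSeries]:
    """(sample, reference) series with multiplicative per-point emission noise."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    a = np.asarray(cfg.absorbances, dtype=float)
    k_ref = cfg.ref_scale
    # inverting the slope-method formula fixes the sample gain
    k_sample = k_ref * (cfg.true_phi / cfg.ref_phi) * (cfg.eta_ref / cfg.eta_sample) ** 2
    em_sample = k_sample * a
    em_ref = k_ref * a
    if cfg.noise_rel > 0:
        em_sample = em_sample * (1.0 + rng.normal(0.0, cfg.noise_rel, a.size))
        em_ref = em_ref * (1.0 + rng.normal(0.0, cfg.noise_rel, a.size))
    meta_s = SampleMeta(sample_id="synthetic_sample", solvent="water", refractive_index=cfg.eta_sample)
    meta_r = SampleMeta(sample_id="synthetic_reference", solvent="dce", refractive_index=cfg.eta_ref)
    return (
        DilutionSeries(a, np.clip(em_sample, 0, None), meta_s),
        DilutionSeries(a, np.clip(em_ref, 0, None), meta_r),
    )


# ---------------------------------------------------------------- TA traces


def default_delay_grid() -> np.ndarray:
    """60 linear points over [-1, 1] ps then 120 log-spaced points to 1500 ps."""
    lin = np.linspace(-1.0, 1.0, 60)
    log = np.geomspace(1.0, 1500.0, 121)[1:]
    return np.concatenate([lin, log])


@dataclass(frozen=True)
class TraceConfig:
    """Ground-state-bleach kinetic trace: IRF-convolved multi-exponential.

    ``fractions`` are |A| shares summing to 1; ``sign`` is -1 for GSB.
    Additive Gaussian noise has sd = noise_rel * max |signal|.
    """

    taus_ps: tuple[float, ...] = (0.43, 7.73, 179.0)
    fractions: tuple[float, ...] = (0.60, 0.30, 0.10)
    sign: float = -1.0
    irf: IRFSpec = field(default_factory=IRFSpec)
    probe_nm: float = 762.0
    noise_rel: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if len(self.taus_ps) != len(self.fractions):
            raise ConfigError("taus and fractions must have equal length")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ConfigError("fractions must sum to 1")
        if any(t <= 0 for t in self.taus_ps):
            raise ConfigError("taus must be > 0")

    @property
    def components(self) -> tuple[ExpComponent, ...]:
        return tuple(
            ExpComponent(tau, self.sign * frac) for tau, frac in zip(self.taus_ps, self.fractions)
        )


def gen_ta_trace(cfg: TraceConfig, seed: int | None = None, delays_ps: Sequence[float] | None = None) -> KineticTrace:
    """Noisy kinetic trace on the default (-1 to 1500 ps) delay grid."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    t = np.asarray(delays_ps, dtype=float) if delays_ps is not None else default_delay_grid()
    clean = convolved_multiexp(t, cfg.components, cfg.irf)
    y = clean + rng.normal(0.0, cfg.noise_rel * float(np.abs(clean).max()), t.size) if cfg.noise_rel > 0 else clean
    return KineticTrace(t, y, probe_nm=cfg.probe_nm)


# ---------------------------------------------------------------- images


@dataclass(frozen=True)
class VesselImageConfig:
    """Vertical Gaussian-ridge vessel over a flat background.

    The ridge crest sits exactly on the central pixel column, so a one-column
    crest ROI reads background + peak and the preset signal/background ratio
    is exact at zero noise.  Noise is Poisson shot noise (optional) followed
    by additive Gaussian read noise.
    """

    shape: tuple[int, int] = (128, 128)
    pixel_size_mm: float = 0.05
    vessel_fwhm_mm: float = 0.25
    peak_level: float = 760.0
    background_level: float = 250.0
    poisson: bool = True
    read_noise_sd: float = 5.0
    filter_name: str = ""
    seed: int = 0

    def __post_init__(self):
        if self.vessel_fwhm_mm <= 2.0 * self.pixel_size_mm:
            raise ConfigError("vessel FWHM must exceed 2 pixels")

    @property
    def crest_col(self) -> int:
        return self.shape[1] // 2

    @property
    def signal_roi(self) -> ROI:
        r = self.shape[0]
        return ROI(r // 8, r - r // 8, self.crest_col, self.crest_col + 1)

    @property
    def background_roi(self) -> ROI:
        r = self.shape[0]
        return ROI(r // 8, r - r // 8, 2, 12)

    @property
    def profile_line(self) -> tuple[tuple[int, int], tuple[int, int]]:
        """Horizontal line across the ridge at mid-height."""
        row = self.shape[0] // 2
        return (row, 0), (row, self.shape[1] - 1)


def gen_vessel_image(cfg: VesselImageConfig, seed: int | None = None, time_h: float = float("nan")) -> IntensityImage:
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    nrow, ncol = cfg.shape
    cols_mm = np.arange(ncol) * cfg.pixel_size_mm
    sigma_mm = cfg.vessel_fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    crest_mm = cfg.crest_col * cfg.pixel_size_mm
    ridge = cfg.peak_level * np.exp(-((cols_mm - crest_mm) ** 2) / (2.0 * sigma_mm**2))
    clean = cfg.background_level + np.tile(ridge, (nrow, 1))
    img = rng.poisson(clean).astype(float) if cfg.poisson else clean.copy()
    if cfg.read_noise_sd > 0:
        img = img + rng.normal(0.0, cfg.read_noise_sd, clean.shape)
    return IntensityImage(np.clip(img, 0.0, None), cfg.pixel_size_mm, filter_name=cfg.filter_name, time_h=time_h)


@dataclass(frozen=True)
class TimeCourseConfig:
    """Tumor-uptake time course I(t) = I_max (t/t_peak)^a exp(a (1 - t/t_peak)).

    The gamma-like rise-and-fall peaks exactly at ``t_peak_h``; ``shape_a``
    controls how sharp the rise is (a = 0 degenerates to a flat course).
    """

    times_h: tuple[float, ...] = (0.0, 6.0, 12.0, 24.0, 36.0, 48.0)
    t_peak_h: float = 24.0
    shape_a: float = 2.0
    tumor_sigma_mm: float = 0.4
    seed: int = 0

    def __post_init__(self):
        if self.t_peak_h not in self.times_h:
            raise ConfigError("t_peak_h must be one of the time points")

    def uptake(self, t_h: float) -> float:
        if self.shape_a == 0:
            return 1.0
        if t_h <= 0:
            return 0.0
        x = t_h / self.t_peak_h
        return x**self.shape_a * math.exp(self.shape_a * (1.0 - x))


def tumor_roi(base: VesselImageConfig) -> ROI:
    """Centered square ROI covering the synthetic tumor blob core."""
    r, c = base.shape
    h = max(4, int(round(0.4 / base.pixel_size_mm / 2)))
    return ROI(r // 2 - h, r // 2 + h, c // 2 - h, c // 2 + h)


def gen_timecourse_images(
    cfg: TimeCourseConfig, base: VesselImageConfig | None = None, seed: int | None = None
) -> list[IntensityImage]:
    """Tumor-blob image per time point; blob brightness follows the uptake model."""
    base = base or VesselImageConfig()
    base_seed = cfg.seed if seed is None else seed
    nrow, ncol = base.shape
    rows_mm = (np.arange(nrow) - nrow // 2)[:, None] * base.pixel_size_mm
    cols_mm = (np.arange(ncol) - ncol // 2)[None, :] * base.pixel_size_mm
    blob = np.exp(-(rows_mm**2 + cols_mm**2) / (2.0 * cfg.tumor_sigma_mm**2))
    images = []
    for i, t_h in enumerate(cfg.times_h):
        rng = np.random.default_rng(base_seed + 1000 * i)
        clean = base.background_level + base.peak_level * cfg.uptake(t_h) * blob
        img = rng.poisson(clean).astype(float) if base.poisson else clean.copy()
        if base.read_noise_sd > 0:
            img = img + rng.normal(0.0, base.read_noise_sd, clean.shape)
        images.append(
            IntensityImage(np.clip(img, 0.0, None), base.pixel_size_mm, filter_name=base.filter_name, time_h=t_h)
        )
    return images


# ---------------------------------------------------------------- presets

#: Study-condition registry.  Emission dimer fractions: NP1s 0.643 (dominant
#: dimer population); the 0.735 decomposition is carried as
#: ``high_dimer_emission`` without asserting sample ownership; NP3s uses a
#: reduced 0.45.  GSB presets carry the published time-constant sets; the
#: NP3s long-component amplitude fraction is 0.202 with the remainder split
#: 2:1 across the faster components; 4F and NP1s fractions default to
#: 0.60/0.40 and 0.60/0.30/0.10 ascending in τ.
PRESETS: Mapping[str, object] = {
    "np1s_emission": MixtureSpectrumConfig(dimer_fraction=0.643, noise_sigma_rel=0.01),
    "np3s_emission": MixtureSpectrumConfig(dimer_fraction=0.45, noise_sigma_rel=0.01),
    "high_dimer_emission": MixtureSpectrumConfig(dimer_fraction=0.735, noise_sigma_rel=0.01),
    "np1s_absorption": replace(ABSORPTION_MIXTURE, dimer_fraction=0.643, noise_sigma_rel=0.01),
    "fw_titration": TitrationConfig(noise_sigma_rel=0.01),
    "np3s_qy": QYSeriesConfig(true_phi=0.075, noise_rel=0.02),
    "np1s_qy": QYSeriesConfig(true_phi=0.026, noise_rel=0.02),
    "f4_thf_qy": QYSeriesConfig(true_phi=0.171, eta_sample=REFRACTIVE_INDEX["thf"], noise_rel=0.02),
    "np1s_gsb": TraceConfig(taus_ps=(0.43, 7.73, 179.0), fractions=(0.60, 0.30, 0.10), probe_nm=762.0, noise_rel=0.01),
    "f4_thf_gsb": TraceConfig(taus_ps=(4.6, 134.0), fractions=(0.60, 0.40), probe_nm=766.0, noise_rel=0.01),
    "np3s_gsb": TraceConfig(taus_ps=(0.98, 11.6, 496.0), fractions=(0.532, 0.266, 0.202), probe_nm=762.0, noise_rel=0.01),
    "nir2b_vessel": VesselImageConfig(vessel_fwhm_mm=0.25, peak_level=760.0, background_level=250.0, filter_name="1500LP"),
    "nir2_1300_vessel": VesselImageConfig(vessel_fwhm_mm=0.30, peak_level=437.5, background_level=250.0, filter_name="1300LP"),
    "nir2_980_vessel": VesselImageConfig(vessel_fwhm_mm=0.49, peak_level=177.5, background_level=250.0, filter_name="980LP"),
    "tumor_course": TimeCourseConfig(),
}


def preset(name: str):
    try:
        return PRESETS[name]
    except KeyError:
        raise ConfigError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
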