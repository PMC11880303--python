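"""Vessel-profile FWHM, ROI signal-to-background ratio, and uptake time courses.

In vivo NIR-II angiography quality is summarized by the apparent width
(FWHM) of a vessel cross-section, obtained from a Gaussian + linear-baseline
fit to a line profile drawn across the vessel, and by the signal-to-
background ratio, the mean intensity of a signal ROI over the mean of a
background ROI.  Tumor accumulation is tracked as the ROI mean over a series
of time-stamped images.

Pixel convention: 0-based indices with pixel centers at integer coordinates;
physical position = index * pixel_size_mm.  Off-grid sampling is bilinear.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.optimize import least_squares

from .errors import DegenerateInputError, FitError, InputError

__all__ = [
    "FWHM_PER_SIGMA",
    "IntensityImage",
    "LineProfile",
    "ProfileFit",
    "ROI",
    "SBRResult",
    "TimeCourse",
    "read_image",
    "write_image",
    "extract_line_profile",
    "fit_profile_fwhm",
    "compute_sbr",
    "roi_timecourse",
]

FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class IntensityImage:
    """Single-channel non-negative intensity image with a physical pixel size."""

    pixels: np.ndarray
    pixel_size_mm: float
    filter_name: str = ""
    time_h: float = float("nan")

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 2 or min(px.shape) < 16:
            raise InputError("image must be 2-D and at least 16x16")
        if not np.all(np.isfinite(px)) or np.any(px < 0):
            raise InputError("image must be finite and non-negative")
        if self.pixel_size_mm <= 0:
            raise InputError("pixel_size_mm must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class LineProfile:
    positions_mm: np.ndarray
    intensities: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.positions_mm, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "positions_mm", p)
        object.__setattr__(self, "intensities", y)
        if p.size != y.size or p.size < 9:
            raise InputError("profile needs >= 9 equal-length points")
        if np.any(np.diff(p) <= 0):
            raise InputError("positions must be strictly increasing")


@dataclass(frozen=True)
class ProfileFit:
    amplitude: float
    center_mm: float
    sigma_mm: float
    baseline: tuple[float, float]
    r_squared: float

    def __post_init__(self):
        if self.amplitude <= 0 or self.sigma_mm <= 0:
            raise FitError("profile fit produced non-positive amplitude or width")

    @property
    def fwhm_mm(self) -> float:
        return FWHM_PER_SIGMA * self.sigma_mm


@dataclass(frozen=True)
class ROI:
    """Axis-aligned rectangle in pixel coordinates: half-open row/col ranges."""

    row_start: int
    row_stop: int
    col_start: int
    col_stop: int

    def __post_init__(self):
        if self.row_start >= self.row_stop or self.col_start >= self.col_stop:
            raise InputError("ROI must be non-empty")
        if min(self.row_start, self.col_start) < 0:
            raise InputError("ROI indices must be >= 0")

    def pixels(self, img: IntensityImage) -> np.ndarray:
        if self.row_stop > img.shape[0] or self.col_stop > img.shape[1]:
            raise InputError(f"ROI {self} exceeds image bounds {img.shape}")
        return img.pixels[self.row_start : self.row_stop, self.col_start : self.col_stop]

    def overlaps(self, other: "ROI") -> bool:
        return not (
            self.row_stop <= other.row_start
            or other.row_stop <= self.row_start
            or self.col_stop <= other.col_start
            or other.col_stop <= self.col_start
        )


@dataclass(frozen=True)
class SBRResult:
    mean_signal: float
    mean_background: float
    sbr: float


@dataclass(frozen=True)
class TimeCourse:
    times_h: np.ndarray
    intensities: np.ndarray
    peak_time_h: float

    def __post_init__(self):
        t = np.asarray(self.times_h, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "intensities", y)
        if self.peak_time_h not in t:
            raise DegenerateInputError("peak_time_h must be one of the time points")


def read_image(path: str | Path, pixel_size_mm: float, **kw) -> IntensityImage:
    """Read a single-channel TIFF (or PNG) into an IntensityImage."""
    import tifffile

    p = Path(path)
    if p.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(p)
    else:
        from PIL import Image

        arr = np.asarray(Image.open(p))
    return IntensityImage(np.asarray(arr, dtype=float), pixel_size_mm, **kw)


def write_image(img: IntensityImage, path: str | Path) -> None:
    """Write as 16-bit grayscale TIFF (values clipped to the uint16 range)."""
    import tifffile

    arr = np.clip(np.round(img.pixels), 0, 65535).astype(np.uint16)
    tifffile.imwrite(Path(path), arr)


def extract_line_profile(
    img: IntensityImage,
    p_start: tuple[float, float],
    p_end: tuple[float, float],
    width_px: int = 1,
) -> LineProfile:
    """Bilinear line profile from p_start to p_end (row, col pixel coords).

    Samples at pixel-size steps along the segment; ``width_px`` parallel
    samples, spaced one pixel apart perpendicular to the segment, are
    averaged at each position.  Positions are mm from p_start.
    """
    if width_px < 1 or width_px % 2 == 0:
        raise InputError("width_px must be a positive odd integer")
    r0, c0 = map(float, p_start)
    r1, c1 = map(float, p_end)
    nrow, ncol = img.shape
    for r, c in ((r0, c0), (r1, c1)):
        if not (0 <= r <= nrow - 1 and 0 <= c <= ncol - 1):
            raise InputError(f"endpoint ({r}, {c}) outside image of shape {img.shape}")
    length_px = math.hypot(r1 - r0, c1 - c0)
    if length_px == 0:
        raise InputError("degenerate segment")
    n_samples = int(math.floor(length_px)) + 1
    ts = np.arange(n_samples)  # one sample per pixel step
    ur, uc = (r1 - r0) / length_px, (c1 - c0) / length_px  # along-track unit
    pr, pc = -uc, ur  # perpendicular unit
    offsets = np.arange(width_px) - width_px // 2
    rows = r0 + ts[None, :] * ur + offsets[:, None] * pr
    cols = c0 + ts[None, :] * uc + offsets[:, None] * pc
    if rows.min() < 0 or rows.max() > nrow - 1 or cols.min() < 0 or cols.max() > ncol - 1:
        raise InputError("profile band samples outside the image; shrink width or line")
    samples = map_coordinates(img.pixels, [rows.ravel(), cols.ravel()], order=1, mode="nearest")
    prof = samples.reshape(width_px, n_samples).mean(axis=0)
    return LineProfile(ts * img.pixel_size_mm, prof)


def _gauss_lin(p: np.ndarray, x: np.ndarray) -> np.ndarray:
    a, c, s, b0, b1 = p
    return a * np.exp(-((x - c) ** 2) / (2.0 * s**2)) + b0 + b1 * x


def fit_profile_fwhm(profile: LineProfile) -> ProfileFit:
    """Gaussian + linear-baseline least squares; FWHM = 2√(2 ln 2)·σ."""
    x, y = profile.positions_mm, profile.intensities
    span = float(x[-1] - x[0])
    base0 = float(np.percentile(y, 10))
    ipk = int(np.argmax(y))
    amp0 = float(y[ipk] - base0)
    if amp0 <= 0:
        raise FitError("profile has no peak above baseline")
    # σ seed from the half-max crossing width around the peak
    above = y - base0 > 0.5 * amp0
    sig0 = max(float(np.count_nonzero(above)) * float(np.median(np.diff(x))) / FWHM_PER_SIGMA, span / 50)
    p0 = [amp0, float(x[ipk]), sig0, base0, 0.0]
    lo = [0.0, float(x[0]), span / 1000, -np.inf, -np.inf]
    hi = [np.inf, float(x[-1]), span, np.inf, np.inf]
    sol = least_squares(lambda p: _gauss_lin(p, x) - y, p0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14)
    if not sol.success:
        raise FitError("Gaussian profile fit did not converge")
    resid = _gauss_lin(sol.x, x) - y
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
    a, c, s, b0, b1 = sol.x
    noise_floor = float(np.std(resid))
    if a <= noise_floor:
        raise FitError(f"fitted amplitude {a:.3g} below noise floor {noise_floor:.3g}")
    return ProfileFit(float(a), float(c), float(s), (float(b0), float(b1)), r2)


def compute_sbr(img: IntensityImage, signal: ROI, background: ROI) -> SBRResult:
    """Mean signal-ROI intensity over mean background-ROI intensity."""
    if signal.overlaps(background):
        raise InputError("signal and background ROIs must be disjoint")
    ms = float(signal.pixels(img).mean())
    mb = float(background.pixels(img).mean())
    if mb <= 0:
        raise DegenerateInputError("background mean must be > 0")
    return SBRResult(ms, mb, ms / mb)


def roi_timecourse(images: list[IntensityImage], roi: ROI) -> TimeCourse:
    """ROI mean intensity per time point; peak time is the argmax."""
    if len(images) < 3:
        raise InputError("time course needs >= 3 time points")
    shapes = {img.shape for img in images}
    sizes = {img.pixel_size_mm for img in images}
    if len(shapes) != 1 or len(sizes) != 1:
        raise InputError("time-course images must share geometry")
    times = np.array([img.time_h for img in images], dtype=float)
    if np.any(~np.isfinite(times)) or np.any(np.diff(times) <= 0):
        raise InputError("images must carry strictly increasing finite time_h")
    means = np.array([float(roi.pixels(img).mean()) for img in images])
    return TimeCourse(times, means, float(times[int(np.argmax(means))]))
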