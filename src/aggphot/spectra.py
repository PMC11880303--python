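"""Spectrum data model, delimited-text I/O, and elementary numerics.

All spectra are handled on the wavelength axis in nanometres; intensities are
optical density for absorption spectra and arbitrary detector counts for
emission.  Interpolation is linear throughout (monotone-safe, exactly
testable); the Jacobian correction needed for energy-domain lineshape work is
deliberately not applied.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import DegenerateInputError, InputError

__all__ = [
    "SpectrumKind",
    "SampleMeta",
    "BandWindow",
    "Spectrum",
    "read_spectrum",
    "write_spectrum",
    "normalize",
    "integrate_band",
    "resample",
]


class SpectrumKind(str, Enum):
    ABSORPTION = "absorption"
    EMISSION = "emission"


@dataclass(frozen=True)
class SampleMeta:
    """Provenance of a measured spectrum.

    ``refractive_index`` is the solvent refractive index η (dimensionless),
    ``water_fraction`` the THF/water titration coordinate f_w in [0, 1],
    ``concentration_M`` molar concentration (NaN when unknown) and
    ``path_length_cm`` the cuvette path length.
    """

    sample_id: str = ""
    solvent: str = ""
    refractive_index: float = 1.333
    water_fraction: float = 0.0
    concentration_M: float = float("nan")
    path_length_cm: float = 1.0

    def __post_init__(self):
        if not (1.0 <= self.refractive_index <= 2.0):
            raise InputError(
                f"refractive_index {self.refractive_index} outside [1.0, 2.0]"
            )
        if not (0.0 <= self.water_fraction <= 1.0):
            raise InputError(f"water_fraction {self.water_fraction} outside [0, 1]")
        if self.path_length_cm <= 0:
            raise InputError("path_length_cm must be > 0")


@dataclass(frozen=True)
class BandWindow:
    """Closed wavelength interval [lo_nm, hi_nm] used for integration and priors."""

    lo_nm: float
    hi_nm: float

    def __post_init__(self):
        if not self.lo_nm < self.hi_nm:
            raise InputError(f"BandWindow requires lo < hi, got [{self.lo_nm}, {self.hi_nm}]")

    @property
    def width_nm(self) -> float:
        return self.hi_nm - self.lo_nm

    @property
    def center_nm(self) -> float:
        return 0.5 * (self.lo_nm + self.hi_nm)

    def contains(self, x: float) -> bool:
        return self.lo_nm <= x <= self.hi_nm


@dataclass(frozen=True)
class Spectrum:
    """Wavelength-indexed intensity record.

    Invariants enforced on construction: equal lengths >= 5, strictly
    increasing wavelengths, finite values, non-negative emission intensities.
    """

    wavelengths_nm: np.ndarray
    intensities: np.ndarray
    kind: SpectrumKind = SpectrumKind.EMISSION
    meta: SampleMeta = field(default_factory=SampleMeta)

    def __post_init__(self):
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "intensities", y)
        if wl.ndim != 1 or y.ndim != 1 or wl.size != y.size:
            raise InputError("wavelengths and intensities must be 1-D and equal length")
        if wl.size < 5:
            raise InputError(f"spectrum needs >= 5 points, got {wl.size}")
        if not (np.all(np.isfinite(wl)) and np.all(np.isfinite(y))):
            raise InputError("spectrum contains non-finite values")
        if np.any(np.diff(wl) <= 0):
            raise InputError("wavelengths must be strictly increasing")
        if self.kind == SpectrumKind.EMISSION and np.any(y < 0):
            raise InputError("emission intensities must be >= 0")

    def __len__(self) -> int:
        return int(self.wavelengths_nm.size)

    @property
    def support(self) -> BandWindow:
        return BandWindow(float(self.wavelengths_nm[0]), float(self.wavelengths_nm[-1]))

    def with_intensities(self, y: np.ndarray) -> "Spectrum":
        return replace(self, intensities=np.asarray(y, dtype=float))


_SEP_RE = re.compile(r"[,\s;]+")


def _parse_rows(text: str, source: str) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p for p in _SEP_RE.split(line) if p]
        if len(parts) < 2:
            raise InputError(f"{source}:{lineno}: expected two columns, got {line!r}")
        try:
            x, y = float(parts[0]), float(parts[1])
        except ValueError:
            if xs:  # non-numeric after data has started is an error
                raise InputError(f"{source}:{lineno}: non-numeric row {line!r}") from None
            continue  # tolerate a single header row before the data
        if not (np.isfinite(x) and np.isfinite(y)):
            raise InputError(f"{source}:{lineno}: non-finite value in {line!r}")
        xs.append(x)
        ys.append(y)
    if len(xs) < 5:
        raise InputError(f"{source}: needs >= 5 data rows, found {len(xs)}")
    return np.array(xs), np.array(ys)


def read_spectrum(
    path: str | Path | io.TextIOBase,
    kind: SpectrumKind | str = SpectrumKind.EMISSION,
    meta: SampleMeta | None = None,
) -> Spectrum:
    """Read a two-column delimited-text spectrum (comma or whitespace separated).

    Lines starting with ``#`` are comments; a single non-numeric header row is
    tolerated.  Rows are sorted by wavelength and duplicate wavelengths are
    collapsed to their mean intensity.
    """
    if isinstance(path, io.TextIOBase):
        text, source = path.read(), "<stream>"
    else:
        p = Path(path)
        text, source = p.read_text(), str(p)
    x, y = _parse_rows(text, source)
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    # collapse exact duplicate wavelengths by mean
    ux, inv = np.unique(x, return_inverse=True)
    if ux.size != x.size:
        sums = np.bincount(inv, weights=y)
        counts = np.bincount(inv)
        y = sums / counts
        x = ux
    if x.size < 5:
        raise InputError(f"{source}: fewer than 5 distinct wavelengths after collapsing")
    return Spectrum(x, y, SpectrumKind(kind), meta or SampleMeta())


def write_spectrum(spec: Spectrum, path: str | Path) -> None:
    """Write a spectrum as CSV with a ``# wavelength_nm,intensity`` header."""
    lines = ["# wavelength_nm,intensity"]
    lines += [f"{w:.17g},{i:.17g}" for w, i in zip(spec.wavelengths_nm, spec.intensities)]
    Path(path).write_text("\n".join(lines) + "\n")


def normalize(spec: Spectrum) -> Spectrum:
    """Scale intensities so the maximum equals 1; wavelengths are untouched."""
    peak = float(np.max(spec.intensities))
    if peak <= 0:
        raise DegenerateInputError("cannot normalize a spectrum with max intensity <= 0")
    return spec.with_intensities(spec.intensities / peak)


def integrate_band(spec: Spectrum, win: BandWindow) -> float:
    """Trapezoidal area of the spectrum over ``win`` (intensity * nm).

    Window endpoints falling between samples are obtained by linear
    interpolation, so the integral is additive over adjacent windows.
    """
    wl, y = spec.wavelengths_nm, spec.intensities
    lo = max(win.lo_nm, float(wl[0]))
    hi = min(win.hi_nm, float(wl[-1]))
    if lo >= hi:
        raise DegenerateInputError(
            f"window [{win.lo_nm}, {win.hi_nm}] does not overlap support "
            f"[{wl[0]}, {wl[-1]}]"
        )
    inner = wl[(wl > lo) & (wl < hi)]
    grid = np.concatenate(([lo], inner, [hi]))
    vals = np.interp(grid, wl, y)
    return float(np.trapezoid(vals, grid))


def resample(spec: Spectrum, grid_nm: Sequence[float]) -> Spectrum:
    """Linear interpolation of the spectrum onto ``grid_nm`` (no extrapolation)."""
    grid = np.asarray(grid_nm, dtype=float)
    wl = spec.wavelengths_nm
    if grid[0] < wl[0] or grid[-1] > wl[-1]:
        raise InputError(
            f"resample grid [{grid[0]}, {grid[-1]}] extends beyond support "
            f"[{wl[0]}, {wl[-1]}]"
        )
    y = np.interp(grid, wl, spec.intensities)
    return replace(spec, wavelengths_nm=grid, intensities=y)
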