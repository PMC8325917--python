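"""Crown-centroid reflectance extraction and bad-band removal.

The imaging spectrometer delivers 426 bands from 380 nm upward in 5 nm
steps.  Wavelength windows dominated by atmospheric water-vapour
absorption ("bad bands") carry mostly noise and are dropped before the
spectrum enters the fusion feature vector; the default windows remove 57
bands, leaving the 369-value reflectance block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

from .geospatial_io import RasterTile, centroid_pixel

__all__ = [
    "WavelengthGrid",
    "Spectrum",
    "BadBandMask",
    "build_wavelength_grid",
    "apply_bad_bands",
    "extract_crown_spectrum",
    "DEFAULT_BAD_BAND_WINDOWS",
    "DEFAULT_SCALE_FACTOR",
]

#: water-vapour absorption windows (nm, inclusive); removes 57 of 426 bands
DEFAULT_BAD_BAND_WINDOWS: tuple[tuple[float, float], ...] = (
    (1340.0, 1445.0),
    (1790.0, 1960.0),
)

#: stored reflectance = true reflectance * scale (uint16 raster convention)
DEFAULT_SCALE_FACTOR = 10000.0


@dataclass(frozen=True)
class WavelengthGrid:
    """Ordered band-center wavelengths in nm."""

    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        if len(w) == 0 or np.any(np.diff(w) <= 0):
            raise ValueError("wavelengths must be nonempty and strictly increasing")
        object.__setattr__(self, "wavelengths", w)

    def __len__(self) -> int:
        return len(self.wavelengths)


@dataclass(frozen=True)
class Spectrum:
    """Reflectance per band (unitless, [0, 1] after scaling) on a grid."""

    values: np.ndarray
    grid: WavelengthGrid

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if len(v) != len(self.grid):
            raise ValueError("spectrum length does not match its wavelength grid")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class BadBandMask:
    """Inclusive wavelength windows (nm) to remove."""

    windows: tuple[tuple[float, float], ...] = DEFAULT_BAD_BAND_WINDOWS

    def __post_init__(self) -> None:
        wins = tuple((float(a), float(b)) for a, b in self.windows)
        for a, b in wins:
            if b < a:
                raise ValueError("window upper bound below lower bound")
        ordered = sorted(wins)
        for (a1, b1), (a2, b2) in zip(ordered, ordered[1:]):
            if a2 <= b1:
                raise ValueError("bad-band windows must not overlap")
        object.__setattr__(self, "windows", wins)

    def good(self, grid: WavelengthGrid) -> np.ndarray:
        """Boolean mask of bands to keep."""
        w = grid.wavelengths
        bad = np.zeros(len(w), dtype=bool)
        for a, b in self.windows:
            bad |= (w >= a) & (w <= b)
        return ~bad


def build_wavelength_grid(
    n_bands: int = 426, start_nm: float = 380.0, step_nm: float = 5.0
) -> WavelengthGrid:
    """Band centers start_nm + k*step_nm for k = 0..n_bands-1."""
    if n_bands < 1:
        raise ValueError("n_bands must be >= 1")
    return WavelengthGrid(start_nm + step_nm * np.arange(n_bands))


def apply_bad_bands(spectrum: Spectrum, mask: BadBandMask) -> np.ndarray:
    """Drop bands inside any mask window, preserving band order.

    Raises if the mask removes everything (an over-broad configuration).
    """
    keep = mask.good(spectrum.grid)
    if not keep.any():
        raise ValueError("bad-band mask removes every band")
    return spectrum.values[keep]


def extract_crown_spectrum(
    hs_tile: RasterTile,
    polygon: Polygon,
    scale_factor: float = DEFAULT_SCALE_FACTOR,
    grid: WavelengthGrid | None = None,
) -> Spectrum:
    """Reflectance at the crown-centroid pixel, divided by ``scale_factor``.

    The crown is represented by the single cell containing its polygon
    centroid; no averaging over the crown footprint is performed.
    """
    if hs_tile.values.ndim != 3:
        raise ValueError("hyperspectral tile must be rows x cols x bands")
    row, col = centroid_pixel(hs_tile, polygon)
    values = np.asarray(hs_tile.values[row, col, :], dtype=float) / scale_factor
    if grid is None:
        grid = build_wavelength_grid(hs_tile.values.shape[2])
    return Spectrum(values=values, grid=grid)
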