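"""Lidar pseudo-waveforms: vertical point-density profiles per crown.

A pseudo-waveform approximates full-waveform lidar from discrete
returns: after removing height anomalies (points outside the 1st–99th
height percentiles of the whole cloud), the points inside a crown
polygon are binned by height above ground into ``n_bins`` bins spanning
[0, max_height], and the per-bin proportions plus the total point count
form the crown's structural feature block (length ``n_bins + 1``, 40 by
default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon

from .geospatial_io import PointCloud

logger = logging.getLogger(__name__)

__all__ = [
    "HeightFilterConfig",
    "BinningConfig",
    "PseudoWaveform",
    "filter_height_anomalies",
    "compute_pseudowaveform",
    "waveform_features",
]


@dataclass(frozen=True)
class HeightFilterConfig:
    """Percentile bounds for valid heights, computed per point-cloud file."""

    lower_percentile: float = 1.0
    upper_percentile: float = 99.0

    def __post_init__(self) -> None:
        if not (0 <= self.lower_percentile < self.upper_percentile <= 100):
            raise ValueError("require 0 <= lower < upper <= 100")


@dataclass(frozen=True)
class BinningConfig:
    """Vertical binning: n_bins equal-width bins over [0, max_height] m.

    The defaults give 39 bins of width 40/39 ~ 1.026 m, so the lidar
    feature block (proportions + total count) has length 40.
    """

    n_bins: int = 39
    max_height: float = 40.0

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if self.max_height <= 0:
            raise ValueError("max_height must be positive")

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(0.0, self.max_height, self.n_bins + 1)


@dataclass(frozen=True)
class PseudoWaveform:
    """Per-bin point proportions plus the total point count for one crown."""

    proportions: np.ndarray
    total_points: int
    bin_edges: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if np.any(p < 0):
            raise ValueError("proportions must be nonnegative")
        if self.total_points > 0:
            if abs(p.sum() - 1.0) > 1e-9:
                raise ValueError("proportions must sum to 1 when points are present")
        elif p.any():
            raise ValueError("empty crown must have an all-zero waveform")
        object.__setattr__(self, "proportions", p)


def filter_height_anomalies(
    cloud: PointCloud, config: HeightFilterConfig = HeightFilterConfig()
) -> PointCloud:
    """Drop points whose heights fall outside the configured percentiles.

    Percentiles are computed over the whole input cloud (linear
    interpolation between order statistics) and the bounds are inclusive.
    Below-ground echoes and spuriously high returns are removed this way.
    """
    if len(cloud) == 0:
        raise ValueError("cannot filter an empty point cloud")
    h = cloud.heights
    lo, hi = np.percentile(h, [config.lower_percentile, config.upper_percentile])
    keep = (h >= lo) & (h <= hi)
    return PointCloud(cloud.points[keep])


def compute_pseudowaveform(
    cloud: PointCloud, polygon: Polygon, config: BinningConfig = BinningConfig()
) -> PseudoWaveform:
    """Bin the points inside ``polygon`` by height.

    Clipping uses the polygon bounding box with half-open max edges
    (crowns are axis-aligned rectangles).  Bins are half-open [lo, hi)
    with the final bin closed; points outside [0, max_height] are assigned
    to the nearest end bin rather than dropped (and logged), so no
    structural signal is silently lost.  An empty crown yields the
    all-zero waveform.
    """
    edges = config.edges
    xmin, ymin, xmax, ymax = polygon.bounds
    pts = cloud.points
    inside = (
        (pts[:, 0] >= xmin)
        & (pts[:, 0] < xmax)
        & (pts[:, 1] >= ymin)
        & (pts[:, 1] < ymax)
    )
    h = pts[inside, 2]
    total = int(len(h))
    if total == 0:
        return PseudoWaveform(np.zeros(config.n_bins), 0, edges)
    n_outside = int(((h < 0) | (h > config.max_height)).sum())
    if n_outside:
        logger.info("%d points outside [0, %.1f] assigned to end bins", n_outside, config.max_height)
    idx = np.digitize(h, edges[1:-1], right=False)  # [lo, hi) bins, last closed
    counts = np.bincount(idx, minlength=config.n_bins)
    return PseudoWaveform(counts / total, total, edges)


def waveform_features(waveform: PseudoWaveform) -> np.ndarray:
    """Feature block: the bin proportions followed by the total point count."""
    return np.concatenate([waveform.proportions, [float(waveform.total_points)]])
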