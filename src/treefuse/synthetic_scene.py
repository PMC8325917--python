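"""Synthetic multi-sensor forest plots with known taxon structure.

Emulates the airborne data products the classifier consumes — 10 cm RGB
orthoimagery, 1 m / 426-band hyperspectral reflectance, and a discrete
lidar point cloud at ~3.15 points/m^2, delivered in 20 m x 20 m plot
tiles — with per-taxon archetypes controlling crown colour, reflectance
signature, and vertical point-height profile.  Every crown carries its
true taxon label, so each downstream stage can be verified without any
external data.
"""

from __future__ import annotations

import colorsys
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box, mapping

from .geospatial_io import CrownRecord, PointCloud, RasterTile, write_raster, write_xyz

__all__ = [
    "TaxonArchetype",
    "SceneConfig",
    "SyntheticPlot",
    "make_archetypes",
    "generate_plot",
    "inject_height_anomalies",
    "write_plot",
    "write_scene_set",
]

#: default hyperspectral wavelength count (visible to shortwave infrared)
DEFAULT_N_BANDS = 426


@dataclass(frozen=True)
class TaxonArchetype:
    """Ground-truth generative parameters for one taxon."""

    taxon_code: str
    mean_spectrum: np.ndarray  # n_bands reflectances in [0, 1]
    crown_color: np.ndarray  # RGB in [0, 1]
    crown_size_range: tuple[float, float]  # min/max side length, m
    height_mean: float  # mean canopy point height, m
    height_spread: float  # std of canopy point heights, m

    def __post_init__(self) -> None:
        if np.any(self.mean_spectrum < 0) or np.any(self.mean_spectrum > 1):
            raise ValueError("mean_spectrum must lie in [0, 1]")
        if self.crown_size_range[0] <= 0:
            raise ValueError("crown sides must be positive")
        if self.height_mean < 0:
            raise ValueError("height mean must be nonnegative")


@dataclass(frozen=True)
class SceneConfig:
    """Geometry, sensor and population parameters for plot generation."""

    plot_side: float = 20.0  # m
    rgb_resolution: float = 0.10  # m
    hs_resolution: float = 1.0  # m
    n_bands: int = DEFAULT_N_BANDS
    point_density: float = 3.15  # points per m^2
    n_taxa: int = 31
    class_weights: tuple[float, ...] | None = None  # geometric decay if None
    crowns_per_plot: int = 6
    spectral_noise: float = 0.01  # additive Gaussian sd on reflectance
    color_noise: float = 0.02  # additive Gaussian sd on RGB
    ground_height_max: float = 1.5  # non-crown returns lie below this, m
    seed: int = 0

    def __post_init__(self) -> None:
        for res, name in ((self.rgb_resolution, "rgb"), (self.hs_resolution, "hs")):
            n = self.plot_side / res
            if abs(n - round(n)) > 1e-9:
                raise ValueError(f"{name}_resolution must divide plot_side evenly")
        if self.point_density <= 0:
            raise ValueError("point_density must be positive")
        if self.class_weights is not None:
            w = np.asarray(self.class_weights, dtype=float)
            if len(w) != self.n_taxa:
                raise ValueError("class_weights length must equal n_taxa")
            if np.any(w < 0) or w.sum() == 0:
                raise ValueError("class_weights must be nonnegative, not all zero")

    def weights(self) -> np.ndarray:
        """Relative taxon abundances; default is a geometric decay so one
        class dominates, mimicking the strong imbalance of real plot data."""
        if self.class_weights is not None:
            w = np.asarray(self.class_weights, dtype=float)
        else:
            w = 0.8 ** np.arange(self.n_taxa)
        return w / w.sum()


@dataclass
class SyntheticPlot:
    """One generated plot: rasters, points, and labelled crown records."""

    rgb: RasterTile
    hs_cube: RasterTile
    points: PointCloud
    crowns: list[CrownRecord]
    taxa: dict[str, str] = field(default_factory=dict)  # individual_id -> taxon


def _smooth_spectrum(rng: np.random.Generator, n_bands: int) -> np.ndarray:
    """A smooth random reflectance curve built from a few sinusoids."""
    x = np.linspace(0, 1, n_bands)
    s = np.zeros(n_bands)
    for harmonic in range(1, 5):
        amp = rng.uniform(0.02, 0.12) / harmonic
        phase = rng.uniform(0, 2 * np.pi)
        s += amp * np.sin(2 * np.pi * harmonic * x + phase)
    return np.clip(0.25 + rng.uniform(-0.1, 0.25) + s, 0.02, 0.95)


def make_archetypes(
    n_taxa: int,
    seed: int,
    n_bands: int = DEFAULT_N_BANDS,
    min_separation: float = 0.02,
    max_height: float = 38.0,
) -> list[TaxonArchetype]:
    """Create ``n_taxa`` archetypes with pairwise-distinct spectra, colours
    and height profiles.  Deterministic given ``seed``.

    Spectra are redrawn until every pair differs by more than
    ``min_separation`` in at least one band; colours are spread around the
    hue wheel and height means spaced across the canopy range, so those are
    distinct by construction.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = np.random.default_rng(seed)
    spectra: list[np.ndarray] = []
    while len(spectra) < n_taxa:
        cand = _smooth_spectrum(rng, n_bands)
        if all(np.max(np.abs(cand - s)) > min_separation for s in spectra):
            spectra.append(cand)

    height_means = np.linspace(6.0, min(max_height, 34.0), n_taxa)
    archetypes = []
    for k in range(n_taxa):
        hue = k / n_taxa
        sat = 0.55 + 0.3 * (k % 2)
        val = 0.45 + 0.35 * ((k // 2) % 2)
        color = np.array(colorsys.hsv_to_rgb(hue, sat, val))
        archetypes.append(
            TaxonArchetype(
                taxon_code=f"TX{k:02d}",
                mean_spectrum=spectra[k],
                crown_color=color,
                crown_size_range=(2.5, 5.0),
                height_mean=float(height_means[k]),
                height_spread=1.0,
            )
        )
    return archetypes


def _place_crowns(
    rng: np.random.Generator,
    cfg: SceneConfig,
    archetypes: list[TaxonArchetype],
) -> list[tuple[int, tuple[float, float, float, float]]]:
    """Rejection-sample up to ``crowns_per_plot`` non-overlapping rectangles
    (taxon index, (xmin, ymin, xmax, ymax)) inside the plot."""
    weights = cfg.weights()[: len(archetypes)]
    weights = weights / weights.sum()
    placed: list[tuple[int, tuple[float, float, float, float]]] = []
    attempts = 0
    while len(placed) < cfg.crowns_per_plot and attempts < 400:
        attempts += 1
        t = int(rng.choice(len(archetypes), p=weights))
        lo, hi = archetypes[t].crown_size_range
        w = rng.uniform(lo, hi)
        h = rng.uniform(lo, hi)
        if w >= cfg.plot_side or h >= cfg.plot_side:
            continue
        x0 = rng.uniform(0, cfg.plot_side - w)
        y0 = rng.uniform(0, cfg.plot_side - h)
        rect = (x0, y0, x0 + w, y0 + h)
        overlaps = any(
            not (rect[2] <= r[0] or r[2] <= rect[0] or rect[3] <= r[1] or r[3] <= rect[1])
            for _, r in placed
        )
        if not overlaps:
            placed.append((t, rect))
    return placed


def generate_plot(
    config: SceneConfig,
    archetypes: list[TaxonArchetype],
    seed: int,
    origin: tuple[float, float] = (0.0, 0.0),
    plot_id: str = "plot_000",
    site_id: str = "SYN1",
    id_offset: int = 0,
) -> SyntheticPlot:
    """Generate one plot with RGB / hyperspectral rasters, a point cloud and
    labelled crowns drawn from the archetypes.

    ``origin`` is the (west, north) map corner of the plot.  Crown pixels
    take the taxon colour/spectrum plus additive Gaussian noise; lidar
    points fall uniformly in x-y at the configured density, with crown
    points drawing heights from the taxon height profile and open-ground
    points from a low uniform understory layer.
    """
    if not archetypes:
        raise ValueError("archetypes must be nonempty")
    if config.n_bands != len(archetypes[0].mean_spectrum):
        raise ValueError("config n_bands inconsistent with archetype spectra")
    rng = np.random.default_rng(seed)
    x_w, y_n = origin
    side = config.plot_side

    placed = _place_crowns(rng, config, archetypes)

    # --- RGB raster (rows run north -> south) ---
    n_rgb = int(round(side / config.rgb_resolution))
    rgb = np.empty((n_rgb, n_rgb, 3))
    background = np.array([0.30, 0.25, 0.18])  # bare soil / litter
    rgb[:] = background
    # cell-centre coordinate grids in local plot coordinates (x east, y north-up)
    cx = (np.arange(n_rgb) + 0.5) * config.rgb_resolution
    cy = side - (np.arange(n_rgb) + 0.5) * config.rgb_resolution
    for t, (x0, y0, x1, y1) in placed:
        cols = (cx >= x0) & (cx < x1)
        rows = (cy >= y0) & (cy < y1)
        block = np.ix_(rows, cols)
        base = archetypes[t].crown_color
        rgb[block] = base
        if config.color_noise > 0:
            shape = rgb[block].shape
            rgb[block] = np.clip(rgb[block] + rng.normal(0, config.color_noise, shape), 0, 1)

    # --- hyperspectral cube ---
    n_hs = int(round(side / config.hs_resolution))
    hs = np.empty((n_hs, n_hs, config.n_bands))
    bg_spec = np.full(config.n_bands, 0.12)
    hs[:] = bg_spec
    hx = (np.arange(n_hs) + 0.5) * config.hs_resolution
    hy = side - (np.arange(n_hs) + 0.5) * config.hs_resolution
    for t, (x0, y0, x1, y1) in placed:
        cols = (hx >= x0) & (hx < x1)
        rows = (hy >= y0) & (hy < y1)
        block = np.ix_(rows, cols)
        hs[block] = archetypes[t].mean_spectrum
        if config.spectral_noise > 0:
            shape = hs[block].shape
            hs[block] = np.clip(hs[block] + rng.normal(0, config.spectral_noise, shape), 0, 1)

    # --- lidar point cloud (Poisson count, uniform x-y) ---
    n_pts = int(rng.poisson(config.point_density * side * side))
    px = rng.uniform(0, side, n_pts)
    py = rng.uniform(0, side, n_pts)
    pz = rng.uniform(0, config.ground_height_max, n_pts)
    for t, (x0, y0, x1, y1) in placed:
        inside = (px >= x0) & (px < x1) & (py >= y0) & (py < y1)
        k = int(inside.sum())
        if k:
            arch = archetypes[t]
            pz[inside] = np.clip(rng.normal(arch.height_mean, arch.height_spread, k), 0.1, None)
    points = PointCloud(np.column_stack([px + x_w, y_n - side + py, pz]))

    # --- crown records in map coordinates ---
    crowns: list[CrownRecord] = []
    taxa: dict[str, str] = {}
    for i, (t, (x0, y0, x1, y1)) in enumerate(placed):
        ind = f"IND{id_offset + i:05d}"
        poly = box(x_w + x0, y_n - side + y0, x_w + x1, y_n - side + y1)
        code = archetypes[t].taxon_code
        crowns.append(
            CrownRecord(individual_id=ind, taxon_code=code, polygon=poly, site_id=site_id, plot_id=plot_id)
        )
        taxa[ind] = code

    rgb_tile = RasterTile(origin=(x_w, y_n), resolution=config.rgb_resolution, values=rgb)
    hs_tile = RasterTile(origin=(x_w, y_n), resolution=config.hs_resolution, values=hs)
    return SyntheticPlot(rgb=rgb_tile, hs_cube=hs_tile, points=points, crowns=crowns, taxa=taxa)


def inject_height_anomalies(
    points: PointCloud, n_low: int, n_high: int, seed: int
) -> PointCloud:
    """Append spurious below-minimum and above-maximum returns.

    Emulates the timing-error artifacts of real discrete-return lidar:
    below-ground echoes and high outliers (e.g. bird strikes).  The x-y
    locations are resampled from existing points.
    """
    if n_low < 0 or n_high < 0:
        raise ValueError("anomaly counts must be nonnegative")
    if n_low == 0 and n_high == 0:
        return points
    rng = np.random.default_rng(seed)
    xyz = points.points
    zmin, zmax = xyz[:, 2].min(), xyz[:, 2].max()
    extra = []
    for _ in range(n_low):
        i = rng.integers(len(xyz))
        extra.append([xyz[i, 0], xyz[i, 1], zmin - rng.uniform(5.0, 60.0)])
    for _ in range(n_high):
        i = rng.integers(len(xyz))
        extra.append([xyz[i, 0], xyz[i, 1], zmax + rng.uniform(5.0, 60.0)])
    return PointCloud(np.vstack([xyz, np.array(extra)]))


# ---------------------------------------------------------------------------
# On-disk scene sets


def write_plot(plot: SyntheticPlot, out_dir, scale_factor: float = 10000.0) -> None:
    """Write one plot as rgb.tif / hs.tif (+ world files), points.xyz and
    crowns.geojson.  Hyperspectral values are stored as uint16 scaled
    reflectance (NEON convention)."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rgb8 = np.clip(plot.rgb.values * 255, 0, 255).astype(np.uint8)
    write_raster(out / "rgb.tif", RasterTile(plot.rgb.origin, plot.rgb.resolution, rgb8))
    hs16 = np.clip(plot.hs_cube.values * scale_factor, 0, 65535).astype(np.uint16)
    write_raster(out / "hs.tif", RasterTile(plot.hs_cube.origin, plot.hs_cube.resolution, hs16))
    write_xyz(out / "points.xyz", plot.points)
    features = [
        {
            "type": "Feature",
            "properties": {"individual_id": c.individual_id},
            "geometry": mapping(c.polygon),
        }
        for c in plot.crowns
    ]
    (out / "crowns.geojson").write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def write_scene_set(
    config: SceneConfig,
    archetypes: list[TaxonArchetype],
    out_dir,
    n_train_plots: int = 8,
    n_test_plots: int = 3,
    seed: int = 0,
) -> None:
    """Materialise a train/test scene set.

    Layout: ``<out>/train/plot_XXX/{rgb.tif,hs.tif,points.xyz,crowns.geojson}``
    plus one ``field.csv`` per split.  Test-crown labels are withheld from
    the test field table and written to ``<out>/test_labels.csv``, mimicking
    a competition release.
    """
    from pathlib import Path

    out = Path(out_dir)
    rows_train, rows_test, label_rows = [], [], []
    counter = 0
    for split, n_plots in (("train", n_train_plots), ("test", n_test_plots)):
        for p in range(n_plots):
            plot_id = f"{split}_plot_{p:03d}"
            plot = generate_plot(
                config,
                archetypes,
                seed=seed + counter + 1,
                origin=(100.0 * counter, 0.0),
                plot_id=plot_id,
                site_id="SYN1",
                id_offset=1000 * counter,
            )
            write_plot(plot, out / split / plot_id)
            for c in plot.crowns:
                row = {
                    "individual_id": c.individual_id,
                    "taxon_code": c.taxon_code,
                    "site_id": c.site_id,
                    "plot_id": c.plot_id,
                }
                if split == "train":
                    rows_train.append(row)
                else:
                    label_rows.append(row)
                    rows_test.append({**row, "taxon_code": ""})
            counter += 1
    pd.DataFrame(rows_train).to_csv(out / "train" / "field.csv", index=False)
    pd.DataFrame(rows_test).to_csv(out / "test" / "field.csv", index=False)
    pd.DataFrame(label_rows).to_csv(out / "test_labels.csv", index=False)
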