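"""End-to-end orchestration: synthesize -> extract -> train -> predict ->
post-process -> report.

This module holds the library-level stage functions; :mod:`treefuse.cli`
exposes them as shell commands.  Each stage writes its artifacts under
``config.out_dir`` (scene files, model checkpoints, feature tables, the
submission CSV and the score report) together with a checksum marker, so
re-running a stage with unchanged inputs and configuration is a no-op.
All randomness derives from the single seed in :class:`PipelineConfig`.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluation import OTHER_LABEL, ScoreReport, confusion_matrix, score_report
from .fusion import (
    FusionConfig,
    FusionModel,
    apply_other_threshold,
    assemble_features,
    predict_taxa,
    train_fusion,
)
from .geospatial_io import clip_raster, load_crowns, read_raster, read_xyz
from .hyperspectral import (
    BadBandMask,
    apply_bad_bands,
    build_wavelength_grid,
    extract_crown_spectrum,
)
from .pseudowaveform import (
    BinningConfig,
    HeightFilterConfig,
    compute_pseudowaveform,
    filter_height_anomalies,
    waveform_features,
)
from .rgb_classifier import (
    ChipStandardization,
    ImageChip,
    RGBModel,
    RGBTrainConfig,
    fit_rgb_classifier,
    predict_rgb_probs,
)
from .synthetic_scene import SceneConfig, make_archetypes, write_scene_set

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "run_synthesize",
    "run_train_rgb",
    "run_extract_features",
    "run_train_fusion",
    "run_predict",
    "run_evaluate",
    "run_end_to_end",
    "extract_crown_data",
]


@dataclass(frozen=True)
class PipelineConfig:
    """One config object covering every stage; loadable from YAML."""

    out_dir: str = "scene"
    n_taxa: int = 6
    n_train_plots: int = 10
    n_test_plots: int = 4
    crowns_per_plot: int = 6
    spectral_noise: float = 0.01
    color_noise: float = 0.02
    n_bands: int = 426
    scale_factor: float = 10000.0
    rgb_target_side: int = 224
    rgb_epochs: int = 12
    rgb_backbone: int | str = "small"
    fusion_epochs: int = 2000
    fusion_restarts: int = 3
    fusion_batch_size: int = 64
    fusion_max_lr: float = 1e-2
    other_threshold: float = 0.5
    other_mass: float = 0.5
    rgb_val_fraction: float = 0.20
    fusion_val_fraction: float = 0.20
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    def scene_config(self) -> SceneConfig:
        return SceneConfig(
            n_taxa=self.n_taxa,
            n_bands=self.n_bands,
            crowns_per_plot=self.crowns_per_plot,
            spectral_noise=self.spectral_noise,
            color_noise=self.color_noise,
            seed=self.seed,
        )


def _digest(config: PipelineConfig, stage: str) -> str:
    payload = {"stage": stage, **asdict(config)}
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()


def _current(out: Path, stage: str, config: PipelineConfig, outputs: list[Path]) -> bool:
    marker = out / f".{stage}.hash"
    ok = marker.exists() and marker.read_text().strip() == _digest(config, stage)
    return ok and all(p.exists() for p in outputs)


def _mark(out: Path, stage: str, config: PipelineConfig) -> None:
    (out / f".{stage}.hash").write_text(_digest(config, stage))


def run_synthesize(config: PipelineConfig) -> Path:
    """Materialize the train/test scene set on disk (idempotent)."""
    out = Path(config.out_dir)
    if _current(out, "synthesize", config, [out / "train" / "field.csv"]):
        logger.info("synthesize: outputs current, skipping")
        return out
    archetypes = make_archetypes(config.n_taxa, config.seed, n_bands=config.n_bands)
    write_scene_set(
        config.scene_config(),
        archetypes,
        out,
        n_train_plots=config.n_train_plots,
        n_test_plots=config.n_test_plots,
        seed=config.seed,
    )
    _mark(out, "synthesize", config)
    return out


def extract_crown_data(split_dir, field_csv, config: PipelineConfig) -> list[dict]:
    """Per-crown raw features for every plot directory under ``split_dir``.

    Returns one dict per crown: the record, its RGB chip, the good-band
    reflectance vector, and the 40-element lidar feature block.
    """
    split_dir = Path(split_dir)
    mask = BadBandMask()
    grid = build_wavelength_grid(config.n_bands)
    binning = BinningConfig()
    hfilter = HeightFilterConfig()
    rows: list[dict] = []
    for plot_dir in sorted(p for p in split_dir.iterdir() if p.is_dir()):
        crowns = load_crowns(plot_dir / "crowns.geojson", field_csv)
        rgb_tile = read_raster(plot_dir / "rgb.tif")
        hs_tile = read_raster(plot_dir / "hs.tif")
        cloud = filter_height_anomalies(read_xyz(plot_dir / "points.xyz"), hfilter)
        for rec in crowns:
            chip_tile = clip_raster(rgb_tile, rec.polygon)
            chip = ImageChip(
                values=np.asarray(chip_tile.values, dtype=float) / 255.0,
                individual_id=rec.individual_id,
                label=rec.taxon_code,
            )
            spectrum = extract_crown_spectrum(hs_tile, rec.polygon, config.scale_factor, grid)
            good = apply_bad_bands(spectrum, mask)
            wf = compute_pseudowaveform(cloud, rec.polygon, binning)
            rows.append(
                {
                    "record": rec,
                    "chip": chip,
                    "reflectance": good,
                    "lidar": waveform_features(wf),
                }
            )
    return rows


def _rgb_config(config: PipelineConfig) -> RGBTrainConfig:
    return RGBTrainConfig(
        backbone_depth=config.rgb_backbone,
        val_fraction=config.rgb_val_fraction,
        epochs=config.rgb_epochs,
        seed=config.seed,
    )


def run_train_rgb(config: PipelineConfig) -> Path:
    """Fit the first-stage RGB classifier on the training chips."""
    out = run_synthesize(config)
    model_path = out / "rgb_model.npz"
    if _current(out, "train_rgb", config, [model_path]):
        logger.info("train_rgb: outputs current, skipping")
        return model_path
    train_rows = extract_crown_data(out / "train", out / "train" / "field.csv", config)
    std = ChipStandardization(target_side=config.rgb_target_side)
    model = fit_rgb_classifier([r["chip"] for r in train_rows], _rgb_config(config), std)
    model.save(model_path)
    _mark(out, "train_rgb", config)
    return model_path


def run_extract_features(config: PipelineConfig) -> tuple[Path, Path]:
    """Assemble the fusion feature table for both splits.

    Writes ``features_train.csv`` / ``features_test.csv``: individual_id,
    one column per feature, and the label (blank for test crowns).
    """
    out = run_synthesize(config)
    paths = (out / "features_train.csv", out / "features_test.csv")
    if _current(out, "extract_features", config, list(paths)):
        logger.info("extract_features: outputs current, skipping")
        return paths
    model = RGBModel.load(run_train_rgb(config))
    std = ChipStandardization(target_side=config.rgb_target_side)
    for split, path in zip(("train", "test"), paths):
        rows = extract_crown_data(out / split, out / split / "field.csv", config)
        table = []
        for r in rows:
            probs = predict_rgb_probs(model, r["chip"], std)
            fv = assemble_features(probs.values, r["reflectance"], r["lidar"])
            rec = r["record"]
            table.append(
                {
                    "individual_id": rec.individual_id,
                    **{f"f{i:03d}": v for i, v in enumerate(fv.values)},
                    "label": rec.taxon_code or "",
                }
            )
        pd.DataFrame(table).to_csv(path, index=False)
    _mark(out, "extract_features", config)
    return paths


def _read_features(path) -> tuple[list[str], np.ndarray, list[str]]:
    df = pd.read_csv(path, dtype={"individual_id": str, "label": str}, keep_default_na=False)
    cols = [c for c in df.columns if c.startswith("f")]
    return df["individual_id"].tolist(), df[cols].to_numpy(float), df["label"].tolist()


def run_train_fusion(config: PipelineConfig) -> Path:
    """Train the fusion network on the training feature table."""
    out = Path(config.out_dir)
    model_path = out / "fusion_model.npz"
    if _current(out, "train_fusion", config, [model_path]):
        logger.info("train_fusion: outputs current, skipping")
        return model_path
    train_path, _ = run_extract_features(config)
    _, x, y = _read_features(train_path)
    fusion_cfg = FusionConfig(
        epochs=config.fusion_epochs,
        batch_size=config.fusion_batch_size,
        max_learning_rate=config.fusion_max_lr,
        n_restarts=config.fusion_restarts,
        seed=config.seed,
    )
    model = train_fusion(x, y, fusion_cfg)
    model.save(model_path)
    _mark(out, "train_fusion", config)
    return model_path


def run_predict(config: PipelineConfig) -> Path:
    """Predict test-crown taxa, apply the open-set threshold, and write the
    submission CSV (one probability column per taxon plus "Other")."""
    out = Path(config.out_dir)
    sub_path = out / "submission.csv"
    if _current(out, "predict", config, [sub_path]):
        logger.info("predict: outputs current, skipping")
        return sub_path
    model = FusionModel.load(run_train_fusion(config))
    _, test_path = run_extract_features(config)
    ids, x, _ = _read_features(test_path)
    probs = predict_taxa(model, x)
    augmented = np.stack(
        [apply_other_threshold(p, config.other_threshold, config.other_mass) for p in probs]
    )
    class_order = list(model.class_order) + [OTHER_LABEL]
    submission = pd.DataFrame(augmented, columns=class_order)
    submission.insert(0, "individual_id", ids)
    submission.to_csv(sub_path, index=False)
    _mark(out, "predict", config)
    return sub_path


def run_evaluate(config: PipelineConfig) -> ScoreReport:
    """Score the submission against the withheld test labels.

    True taxa absent from the training classes are grouped into "Other"
    (open-set evaluation).  Writes ``report.csv`` and ``confusion.csv``.
    """
    out = Path(config.out_dir)
    sub = pd.read_csv(run_predict(config), dtype={"individual_id": str})
    class_order = [c for c in sub.columns if c != "individual_id"]
    labels = pd.read_csv(out / "test_labels.csv", dtype={"individual_id": str}).set_index(
        "individual_id"
    )
    true = [labels.loc[i, "taxon_code"] for i in sub["individual_id"]]
    known = set(class_order) - {OTHER_LABEL}
    true_reduced = [t if t in known else OTHER_LABEL for t in true]
    augmented = sub[class_order].to_numpy(float)
    report = score_report(true_reduced, augmented, class_order)
    pred_hard = [class_order[i] for i in augmented.argmax(axis=1)]
    cm = confusion_matrix(true, pred_hard, sorted(known), reduce_unknown=True)
    report.to_frame().to_csv(out / "report.csv")
    cm.to_frame().to_csv(out / "confusion.csv")
    return report


def run_end_to_end(config: PipelineConfig) -> tuple[pd.DataFrame, ScoreReport]:
    """Run every stage in sequence and return (submission, report)."""
    report = run_evaluate(config)
    submission = pd.read_csv(Path(config.out_dir) / "submission.csv", dtype={"individual_id": str})
    return submission, report
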