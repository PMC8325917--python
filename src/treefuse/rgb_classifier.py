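"""Crown RGB chips and the first-stage convolutional classifier.

Rectangular crown crops are standardized to a square chip (resize the
short side, center-crop the long side, per-channel normalization with
ImageNet-style constants), then a compact convolutional network of
configurable depth maps each chip to a probability vector over the
taxa seen in training.  Those probability vectors are the first block of
the downstream fusion feature vector.

The network is implemented in numpy and randomly initialized; the named
depths (18, 34, 50, 101, 152) select progressively deeper conv stacks of
the same design, and ``"small"`` is the lightweight default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _nn
from ._nn import Sequential, softmax

__all__ = [
    "ImageChip",
    "ChipStandardization",
    "ClassProbabilities",
    "RGBTrainConfig",
    "standardize_chip",
    "fit_rgb_classifier",
    "predict_rgb_probs",
    "compare_backbones",
    "RGBModel",
]

#: conventional ImageNet channel statistics (RGB order)
IMAGENET_MEANS = (0.485, 0.456, 0.406)
IMAGENET_STDS = (0.229, 0.224, 0.225)

#: named encoder depth -> number of conv blocks in the compact backbone
_DEPTH_BLOCKS = {"small": 1, 18: 2, 34: 3, 50: 4, 101: 5, 152: 6}


@dataclass(frozen=True)
class ImageChip:
    """One crown's RGB crop (H x W x 3 intensities in [0, 1])."""

    values: np.ndarray
    individual_id: str
    label: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3 or v.shape[2] != 3 or v.shape[0] < 1 or v.shape[1] < 1:
            raise ValueError("chip must be H x W x 3 with H, W >= 1")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class ChipStandardization:
    target_side: int = 224
    channel_means: tuple[float, float, float] = IMAGENET_MEANS
    channel_stds: tuple[float, float, float] = IMAGENET_STDS

    def __post_init__(self) -> None:
        if self.target_side < 8:
            raise ValueError("target_side must be >= 8")
        if any(s <= 0 for s in self.channel_stds):
            raise ValueError("channel stds must be positive")


@dataclass(frozen=True)
class ClassProbabilities:
    """A normalized probability vector in canonical class order."""

    values: np.ndarray
    class_order: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if len(v) != len(self.class_order):
            raise ValueError("probability length must match class order")
        if np.any(v < 0) or abs(v.sum() - 1.0) > 1e-6:
            raise ValueError("probabilities must be nonnegative and sum to 1")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class RGBTrainConfig:
    backbone_depth: int | str = "small"
    val_fraction: float = 0.20
    epochs: int = 10
    learning_rate: float = 5e-2
    batch_size: int = 32
    input_side: int = 32  # chips are average-pooled to this before the convs
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.val_fraction < 1):
            raise ValueError("val_fraction must lie in (0, 1)")
        if self.backbone_depth not in _DEPTH_BLOCKS:
            raise ValueError(f"backbone_depth must be one of {sorted(map(str, _DEPTH_BLOCKS))}")


def _resize_bilinear(img: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Bilinear resize (align-corners=False convention)."""
    h, w, c = img.shape
    ys = (np.arange(out_h) + 0.5) * h / out_h - 0.5
    xs = (np.arange(out_w) + 0.5) * w / out_w - 0.5
    y0 = np.clip(np.floor(ys).astype(int), 0, h - 1)
    x0 = np.clip(np.floor(xs).astype(int), 0, w - 1)
    y1 = np.clip(y0 + 1, 0, h - 1)
    x1 = np.clip(x0 + 1, 0, w - 1)
    wy = np.clip(ys - y0, 0, 1)[:, None, None]
    wx = np.clip(xs - x0, 0, 1)[None, :, None]
    top = img[y0][:, x0] * (1 - wx) + img[y0][:, x1] * wx
    bot = img[y1][:, x0] * (1 - wx) + img[y1][:, x1] * wx
    return top * (1 - wy) + bot * wy


def standardize_chip(chip: ImageChip, standardization: ChipStandardization = ChipStandardization()) -> np.ndarray:
    """Resize-then-crop a rectangular chip to a normalized square.

    The short side is resized to ``target_side`` preserving aspect ratio
    (upsampling slivers is allowed), the long side is center-cropped, and
    each channel is normalized as (value - mean) / std.  Deterministic.
    """
    img = chip.values
    h, w, _ = img.shape
    side = standardization.target_side
    scale = side / min(h, w)
    new_h = max(side, int(round(h * scale)))
    new_w = max(side, int(round(w * scale)))
    img = _resize_bilinear(img, new_h, new_w)
    r0 = (new_h - side) // 2
    c0 = (new_w - side) // 2
    img = img[r0 : r0 + side, c0 : c0 + side, :]
    means = np.asarray(standardization.channel_means)
    stds = np.asarray(standardization.channel_stds)
    return (img - means) / stds


class RGBModel:
    """Compact conv backbone + linear head over the training classes."""

    def __init__(self, class_order: tuple[str, ...], config: RGBTrainConfig) -> None:
        self.class_order = tuple(class_order)
        self.config = config
        rng = np.random.default_rng(config.seed)
        n_blocks = _DEPTH_BLOCKS[config.backbone_depth]
        layers: list[_nn.Layer] = []
        c_in, c_out = 3, 8
        for b in range(n_blocks):
            layers.append(_nn.Conv3x3(c_in, c_out, rng))
            layers.append(_nn.ReLU())
            if b < 2:  # keep the spatial grid from collapsing for deep stacks
                layers.append(_nn.AvgPool(2))
            c_in, c_out = c_out, min(2 * c_out, 32)
        layers.append(_nn.GlobalAvgPool())
        layers.append(_nn.Linear(c_in, len(self.class_order), rng))
        self.net = Sequential(layers)
        self.trained = False
        self.history: list[float] = []

    def _pool_input(self, x: np.ndarray) -> np.ndarray:
        """Average-pool standardized chips down to ``input_side`` so the
        numpy convolutions stay cheap; no information relevant to crown
        colour/coarse texture is needed at full 224 px for this backbone."""
        side = x.shape[1]
        f = max(1, side // self.config.input_side)
        if f > 1:
            n, h, w, c = x.shape
            hh, ww = h // f, w // f
            x = x[:, : hh * f, : ww * f, :].reshape(n, hh, f, ww, f, c).mean(axis=(2, 4))
        return x

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        logits = self.net.forward(self._pool_input(x))
        return softmax(logits)

    def save(self, path) -> None:
        """Checkpoint: parameters + class order + training config (npz)."""
        import json

        from dataclasses import asdict

        params = {f"p{i}": p for i, p in enumerate(self.net.parameters())}
        np.savez(
            path,
            classes=np.array(self.class_order),
            config=np.array(json.dumps(asdict(self.config))),
            trained=np.array(int(self.trained)),
            **params,
        )

    @classmethod
    def load(cls, path) -> "RGBModel":
        import json

        data = np.load(path, allow_pickle=False)
        config = RGBTrainConfig(**json.loads(str(data["config"])))
        model = cls(tuple(data["classes"].tolist()), config)
        for i, p in enumerate(model.net.parameters()):
            p[...] = data[f"p{i}"]
        model.trained = bool(int(data["trained"]))
        return model


def _macro_prf(true_idx: np.ndarray, pred_idx: np.ndarray, n_classes: int):
    """Macro-averaged precision, recall, F1 over all classes (0 on empty)."""
    ps, rs, fs = [], [], []
    for k in range(n_classes):
        tp = int(((pred_idx == k) & (true_idx == k)).sum())
        fp = int(((pred_idx == k) & (true_idx != k)).sum())
        fn = int(((pred_idx != k) & (true_idx == k)).sum())
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        ps.append(p)
        rs.append(r)
        fs.append(f)
    return float(np.mean(ps)), float(np.mean(rs)), float(np.mean(fs))


def fit_rgb_classifier(
    labeled_chips: list[ImageChip],
    config: RGBTrainConfig = RGBTrainConfig(),
    standardization: ChipStandardization = ChipStandardization(),
) -> RGBModel:
    """Fine-tune the conv backbone on labelled chips.

    Chips are split by individual into training and validation subsets
    (``val_fraction``); training minimizes cross-entropy with minibatch
    SGD under a one-cycle learning-rate schedule.  Validation macro
    precision/recall/F1 and accuracy are stored on the returned model.
    """
    labels = sorted({c.label for c in labeled_chips if c.label is not None})
    if len(labels) < 2:
        raise ValueError("need at least two classes to fit a classifier")
    class_order = tuple(labels)
    label_to_idx = {c: i for i, c in enumerate(class_order)}

    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(labeled_chips))
    n_val = max(1, int(round(config.val_fraction * len(labeled_chips))))
    val_ids = set(order[:n_val].tolist())
    train_chips = [labeled_chips[i] for i in range(len(labeled_chips)) if i not in val_ids]
    val_chips = [labeled_chips[i] for i in sorted(val_ids)]
    if len({c.label for c in train_chips}) < 2:
        raise ValueError("training split is degenerate (fewer than two classes)")

    model = RGBModel(class_order, config)
    x_train = model._pool_input(
        np.stack([standardize_chip(c, standardization) for c in train_chips])
    )
    y_train = np.array([label_to_idx[c.label] for c in train_chips])
    x_val = np.stack([standardize_chip(c, standardization) for c in val_chips])
    y_val = np.array([label_to_idx[c.label] for c in val_chips])

    n = len(x_train)
    batches_per_epoch = max(1, int(np.ceil(n / config.batch_size)))
    total_steps = config.epochs * batches_per_epoch
    step = 0
    for _epoch in range(config.epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for b in range(batches_per_epoch):
            sel = perm[b * config.batch_size : (b + 1) * config.batch_size]
            xb, yb = x_train[sel], y_train[sel]
            logits = model.net.forward(xb)
            theta = softmax(logits)
            onehot = np.zeros_like(theta)
            onehot[np.arange(len(yb)), yb] = 1.0
            epoch_loss += float(-np.log(np.clip(theta[np.arange(len(yb)), yb], 1e-12, None)).sum())
            # softmax + cross-entropy gradient, mean over the minibatch
            dlogits = (theta - onehot) / len(yb)
            model.net.backward(dlogits)
            lr = _nn.one_cycle_lr(step, total_steps, config.learning_rate)
            model.net.sgd_step(lr)
            step += 1
        model.history.append(epoch_loss / n)

    model.trained = True
    probs = model.predict_proba(x_val)
    pred = probs.argmax(axis=1)
    p, r, f1 = _macro_prf(y_val, pred, len(class_order))
    model.val_metrics = {
        "macro_precision": p,
        "macro_recall": r,
        "macro_f1": f1,
        "accuracy": float((pred == y_val).mean()),
    }
    return model


def predict_rgb_probs(
    model: RGBModel,
    chip: ImageChip,
    standardization: ChipStandardization = ChipStandardization(),
) -> ClassProbabilities:
    """Probability vector over the model's training classes for one chip."""
    if not model.trained:
        raise RuntimeError("model has not been trained")
    x = standardize_chip(chip, standardization)[None]
    probs = model.predict_proba(x)[0]
    return ClassProbabilities(values=probs / probs.sum(), class_order=model.class_order)


def compare_backbones(
    depths,
    labeled_chips: list[ImageChip],
    config: RGBTrainConfig = RGBTrainConfig(),
    standardization: ChipStandardization = ChipStandardization(),
):
    """Train one model per encoder depth and tabulate validation macro
    F1 / precision / recall.  Returns (DataFrame, selected_depth); the
    selection maximizes macro F1, ties broken toward the smaller depth.
    """
    import pandas as pd
    from dataclasses import replace

    depths = list(depths)
    if not depths:
        raise ValueError("depths must be nonempty")
    rows = []
    for d in depths:
        model = fit_rgb_classifier(labeled_chips, replace(config, backbone_depth=d), standardization)
        rows.append(
            {
                "depth": d,
                "macro_f1": model.val_metrics["macro_f1"],
                "macro_precision": model.val_metrics["macro_precision"],
                "macro_recall": model.val_metrics["macro_recall"],
            }
        )
    table = pd.DataFrame(rows)

    def _rank(d):  # "small" sorts before every numeric depth
        return -1 if d == "small" else int(d)

    best_f1 = table["macro_f1"].max()
    candidates = [row["depth"] for _, row in table.iterrows() if row["macro_f1"] == best_f1]
    selected = min(candidates, key=_rank)
    return table, selected
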