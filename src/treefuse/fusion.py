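"""The fusion network: multimodal feature assembly, soft-F1 training,
taxon prediction, and open-set "other" post-processing.

The fusion feature vector concatenates, per individual crown, the
first-stage RGB class probabilities (K values), the good-band centroid
reflectances (369 by default), and the lidar pseudo-waveform block
(39 bin proportions + total point count).  Under the reference
configuration (K = 31) the vector has 440 elements.

The fusion model is a two-hidden-layer perceptron (64 and 32 units)
whose softmax output is trained by minibatch SGD under a one-cycle
learning-rate schedule, minimizing a per-example soft F1 loss

    L(theta) = K^-1 sum_k [ 1 - 2 theta_k y_k /
               (2 theta_k y_k + theta_k (1 - y_k) + (1 - theta_k) y_k + eps) ]

averaged within each minibatch.  The soft F1 loss is a differentiable
surrogate for 1 - F1 that is less dominated by abundant classes than
cross-entropy.  For a one-hot y it collapses to the closed form
1 - 2 theta_t / (K (1 + theta_t + eps)) where theta_t is the probability
assigned to the true class.

At prediction time, when the maximum class probability falls below a
threshold (0.5 by default) a fixed probability mass (0.5) is moved to an
appended "Other" class and the remaining entries are renormalized —
an open-set guard for taxa never seen in training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _nn
from ._nn import Sequential, softmax

__all__ = [
    "FusionFeatureVector",
    "FusionConfig",
    "FusionModel",
    "OTHER_LABEL",
    "assemble_features",
    "soft_f1_loss",
    "train_fusion",
    "predict_taxa",
    "apply_other_threshold",
]

OTHER_LABEL = "Other"

DEFAULT_EPSILON = 1e-7


@dataclass(frozen=True)
class FusionFeatureVector:
    """Concatenation rgb_probs | reflectance | lidar for one individual."""

    rgb_probs: np.ndarray
    reflectance: np.ndarray
    lidar: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rgb_probs, dtype=float)
        if abs(r.sum() - 1.0) > 1e-6:
            raise ValueError("rgb probability block must sum to 1")
        object.__setattr__(self, "rgb_probs", r)
        object.__setattr__(self, "reflectance", np.asarray(self.reflectance, dtype=float))
        object.__setattr__(self, "lidar", np.asarray(self.lidar, dtype=float))

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([self.rgb_probs, self.reflectance, self.lidar])

    def __len__(self) -> int:
        return len(self.rgb_probs) + len(self.reflectance) + len(self.lidar)


@dataclass(frozen=True)
class FusionConfig:
    hidden_sizes: tuple[int, ...] = (64, 32)
    batch_size: int = 64
    epochs: int = 20
    max_learning_rate: float = 1e-2
    weight_decay: float = 1e-3
    n_restarts: int = 1
    epsilon: float = DEFAULT_EPSILON
    loss: str = "soft_f1"  # or "cross_entropy"
    standardize_inputs: bool = True
    n_rgb: int | None = None  # expected block lengths; None disables the check
    n_reflectance: int | None = None
    n_lidar: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")
        if self.max_learning_rate <= 0:
            raise ValueError("max_learning_rate must be positive")
        if self.loss not in ("soft_f1", "cross_entropy"):
            raise ValueError("loss must be 'soft_f1' or 'cross_entropy'")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


def assemble_features(
    rgb_probs: np.ndarray,
    good_band_values: np.ndarray,
    lidar_features: np.ndarray,
    config: FusionConfig | None = None,
) -> FusionFeatureVector:
    """Concatenate the three modality blocks in fixed order.

    When ``config`` declares expected block lengths, mismatches raise —
    catching inconsistent upstream settings (e.g. a wrong bad-band mask).
    """
    if config is not None:
        for block, expected, name in (
            (rgb_probs, config.n_rgb, "rgb"),
            (good_band_values, config.n_reflectance, "reflectance"),
            (lidar_features, config.n_lidar, "lidar"),
        ):
            if expected is not None and len(block) != expected:
                raise ValueError(f"{name} block has length {len(block)}, expected {expected}")
    return FusionFeatureVector(rgb_probs, good_band_values, lidar_features)


def soft_f1_loss(theta: np.ndarray, y: np.ndarray, epsilon: float = DEFAULT_EPSILON) -> float:
    """Per-example soft F1 loss for a probability vector and one-hot label.

    Evaluates the K-term sum directly; each term is
    1 - 2 theta_k y_k / (2 theta_k y_k + theta_k (1-y_k) + (1-theta_k) y_k + eps).
    """
    theta = np.asarray(theta, dtype=float)
    y = np.asarray(y, dtype=float)
    if theta.shape != y.shape:
        raise ValueError("theta and y must have the same length")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if not (np.all((y == 0) | (y == 1)) and y.sum() == 1):
        raise ValueError("y must be one-hot")
    k = len(theta)
    num = 2.0 * theta * y
    den = 2.0 * theta * y + theta * (1.0 - y) + (1.0 - theta) * y + epsilon
    return float(np.mean(1.0 - num / den))


class FusionModel:
    """Two-hidden-layer perceptron with a K-way softmax output.

    With ``n_restarts > 1`` the model is a small deep ensemble: several
    identically configured networks trained from different random
    initialisations whose output probabilities are averaged.  Restarts
    reduce the chance that one unlucky initialisation settles in an
    optimum that fits the training set through non-generalising
    directions of the feature space.
    """

    def __init__(self, n_features: int, class_order: tuple[str, ...], config: FusionConfig) -> None:
        self.class_order = tuple(class_order)
        self.config = config
        self.n_features = n_features
        sizes = [n_features, *config.hidden_sizes, len(self.class_order)]
        self.nets: list[Sequential] = []
        for r in range(config.n_restarts):
            rng = np.random.default_rng([config.seed % 2**31, r])
            layers: list[_nn.Layer] = []
            for i in range(len(sizes) - 1):
                layers.append(_nn.Linear(sizes[i], sizes[i + 1], rng))
                if i < len(sizes) - 2:
                    layers.append(_nn.ReLU())
            self.nets.append(Sequential(layers))
        self.trained = False
        self.epoch_losses: list[float] = []
        self._mu = np.zeros(n_features)
        self._sigma = np.ones(n_features)

    @property
    def net(self) -> Sequential:
        """The first member network (the whole model when n_restarts=1)."""
        return self.nets[0]

    def _scale(self, x: np.ndarray) -> np.ndarray:
        return (x - self._mu) / self._sigma

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        xs = self._scale(np.atleast_2d(x))
        probs = np.mean([softmax(net.forward(xs)) for net in self.nets], axis=0)
        return probs / probs.sum(axis=-1, keepdims=True)

    def save(self, path) -> None:
        """Checkpoint: parameters, input scaling, class order, config (npz)."""
        import json
        from dataclasses import asdict

        cfg = asdict(self.config)
        cfg["hidden_sizes"] = list(cfg["hidden_sizes"])
        params = {
            f"p{r}_{i}": p
            for r, net in enumerate(self.nets)
            for i, p in enumerate(net.parameters())
        }
        np.savez(
            path,
            classes=np.array(self.class_order),
            config=np.array(json.dumps(cfg)),
            mu=self._mu,
            sigma=self._sigma,
            trained=np.array(int(self.trained)),
            **params,
        )

    @classmethod
    def load(cls, path) -> "FusionModel":
        import json

        data = np.load(path, allow_pickle=False)
        raw = json.loads(str(data["config"]))
        raw["hidden_sizes"] = tuple(raw["hidden_sizes"])
        config = FusionConfig(**raw)
        model = cls(len(data["mu"]), tuple(data["classes"].tolist()), config)
        for r, net in enumerate(model.nets):
            for i, p in enumerate(net.parameters()):
                p[...] = data[f"p{r}_{i}"]
        model._mu = data["mu"]
        model._sigma = data["sigma"]
        model.trained = bool(int(data["trained"]))
        return model


def train_fusion(
    features: np.ndarray,
    labels,
    config: FusionConfig = FusionConfig(),
) -> FusionModel:
    """Train the fusion network.

    ``features`` is (n, d); ``labels`` a sequence of taxon codes.  Classes
    are ordered alphabetically.  Inputs are z-scored with statistics fit
    on the training data (raw point counts and unit reflectances differ
    by orders of magnitude, which plain SGD at the reference learning
    rate cannot absorb otherwise).  The loss — soft F1 by default, with a
    cross-entropy switch — is averaged within each minibatch; the learning
    rate follows a one-cycle schedule peaking at ``max_learning_rate``.
    """
    features = np.asarray(features, dtype=float)
    labels = list(labels)
    class_order = tuple(sorted(set(labels)))
    if len(class_order) < 2:
        raise ValueError("need at least two classes to train the fusion network")
    if len(features) != len(labels):
        raise ValueError("features and labels must align")
    label_idx = np.array([class_order.index(l) for l in labels])

    model = FusionModel(features.shape[1], class_order, config)
    if config.standardize_inputs:
        model._mu = features.mean(axis=0)
        sigma = features.std(axis=0)
        model._sigma = np.where(sigma > 1e-12, sigma, 1.0)
    x = model._scale(features)
    k = len(class_order)
    onehot = np.zeros((len(labels), k))
    onehot[np.arange(len(labels)), label_idx] = 1.0

    n = len(x)
    batches = max(1, int(np.ceil(n / config.batch_size)))
    total_steps = config.epochs * batches
    per_net_losses = []
    for r, net in enumerate(model.nets):
        rng = np.random.default_rng([config.seed % 2**31, 1000 + r])
        losses = []
        step = 0
        for _epoch in range(config.epochs):
            perm = rng.permutation(n)
            running = 0.0
            for b in range(batches):
                sel = perm[b * config.batch_size : (b + 1) * config.batch_size]
                xb, yb = x[sel], onehot[sel]
                theta = softmax(net.forward(xb))
                if config.loss == "soft_f1":
                    num = 2.0 * theta * yb
                    den = theta + yb + config.epsilon  # algebraic form of the 4-term denominator
                    running += float(np.mean(1.0 - num / den, axis=1).sum())
                    dtheta = _nn.softf1_grad_wrt_probs(theta, yb, config.epsilon)
                else:
                    p_true = np.clip((theta * yb).sum(axis=1), 1e-12, None)
                    running += float(-np.log(p_true).sum())
                    dtheta = _nn.cross_entropy_grad_wrt_probs(theta, yb)
                dlogits = _nn.softmax_backprop(theta, dtheta) / len(sel)
                net.backward(dlogits)
                lr = _nn.one_cycle_lr(step, total_steps, config.max_learning_rate)
                net.sgd_step(lr, config.weight_decay)
                step += 1
            losses.append(running / n)
        per_net_losses.append(losses)
    model.epoch_losses = np.mean(per_net_losses, axis=0).tolist()
    model.trained = True
    return model


def predict_taxa(model: FusionModel, features: np.ndarray) -> np.ndarray:
    """Taxon probability vector(s) for assembled feature vector(s).

    Accepts one vector (d,) or a batch (n, d); returns the matching shape.
    """
    if not model.trained:
        raise RuntimeError("fusion model has not been trained")
    features = np.asarray(features, dtype=float)
    single = features.ndim == 1
    x = np.atleast_2d(features)
    n_in = model.net.layers[0].W.shape[0]
    if x.shape[1] != n_in:
        raise ValueError(f"feature length {x.shape[1]} does not match model input {n_in}")
    probs = model.predict_proba(x)
    return probs[0] if single else probs


def apply_other_threshold(
    probs: np.ndarray, threshold: float = 0.5, other_mass: float = 0.5
) -> np.ndarray:
    """Open-set guard: appends an "Other" class.

    If max(probs) < threshold, Other receives ``other_mass`` and the
    original entries are rescaled by (1 - other_mass) / sum(probs) so the
    augmented vector sums to one; otherwise the originals pass through
    unchanged with Other = 0.  Class ranking is preserved either way.
    """
    probs = np.asarray(probs, dtype=float)
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    if not (0 < other_mass < 1):
        raise ValueError("other_mass must lie in (0, 1)")
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-6:
        raise ValueError("input probabilities must be normalized")
    if probs.max() < threshold:
        scaled = probs * (1.0 - other_mass) / probs.sum()
        return np.concatenate([scaled, [other_mass]])
    return np.concatenate([probs, [0.0]])
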