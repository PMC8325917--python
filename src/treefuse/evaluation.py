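"""Competition-style evaluation: confusion matrices and score reports.

Implements the classification-report aggregation used to score taxon
predictions: one-vs-rest precision / recall / F1 with support per class,
macro (unweighted) and weighted (support-weighted) average F1, overall
accuracy, and categorical cross-entropy of the predicted probability
assigned to the true class.  Zero denominators yield zero scores, and
classes with zero support still appear in the report and in the macro
average.  A reduced confusion matrix groups all out-of-training taxa
into a single "Other" class for open-set evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

OTHER_LABEL = "Other"

__all__ = [
    "ConfusionMatrix",
    "ScoreReport",
    "confusion_matrix",
    "f1_from_pr",
    "aggregate_f1",
    "score_report",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    counts: np.ndarray  # C x C, rows = true, cols = predicted
    class_order: tuple[str, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if c.shape != (len(self.class_order), len(self.class_order)):
            raise ValueError("counts must be square over class_order")
        if np.any(c < 0):
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.class_order), columns=list(self.class_order))


@dataclass(frozen=True)
class ScoreReport:
    per_class: pd.DataFrame  # index: class; columns: precision, recall, f1, support
    macro_f1: float
    weighted_f1: float
    accuracy: float
    cross_entropy: float

    def to_frame(self) -> pd.DataFrame:
        """Tabular layout: per-class rows then accuracy / macro / weighted rows."""
        out = self.per_class.copy()
        n = int(out["support"].sum())
        macro_p = float(out["precision"].mean())
        macro_r = float(out["recall"].mean())
        if n > 0:
            w = out["support"] / n
            weighted_p = float((out["precision"] * w).sum())
            weighted_r = float((out["recall"] * w).sum())
        else:
            weighted_p = weighted_r = 0.0
        out.loc["accuracy"] = [self.accuracy] * 3 + [n]
        out.loc["macro avg"] = [macro_p, macro_r, self.macro_f1, n]
        out.loc["weighted avg"] = [weighted_p, weighted_r, self.weighted_f1, n]
        return out


def confusion_matrix(
    true_labels,
    predicted_labels,
    class_order,
    reduce_unknown: bool = False,
) -> ConfusionMatrix:
    """Count matrix with rows = true class, columns = predicted class.

    With ``reduce_unknown``, any true label outside ``class_order`` is
    mapped to "Other" (appended to the order if absent) — the open-set
    grouping used for test sites holding unseen taxa.  Without it, an
    out-of-order label raises.
    """
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences must have equal length")
    order = list(class_order)
    if reduce_unknown and OTHER_LABEL not in order:
        order.append(OTHER_LABEL)
    index = {c: i for i, c in enumerate(order)}
    counts = np.zeros((len(order), len(order)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index:
            if not reduce_unknown:
                raise ValueError(f"unknown true label {t!r}")
            t = OTHER_LABEL
        if p not in index:
            if not reduce_unknown:
                raise ValueError(f"unknown predicted label {p!r}")
            p = OTHER_LABEL
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, class_order=tuple(order))


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if not (0 <= precision <= 1 and 0 <= recall <= 1):
        raise ValueError("precision and recall must lie in [0, 1]")
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def aggregate_f1(per_class_f1, supports) -> tuple[float, float]:
    """(macro, weighted) averages of per-class F1 scores.

    Macro is the unweighted mean over all classes (including zero-support
    ones); weighted uses the support fractions.
    """
    f1 = np.asarray(per_class_f1, dtype=float)
    sup = np.asarray(supports, dtype=float)
    if f1.shape != sup.shape:
        raise ValueError("f1 and support vectors must align")
    macro = float(f1.mean())
    total = sup.sum()
    weighted = float((f1 * sup).sum() / total) if total > 0 else 0.0
    return macro, weighted


def score_report(
    true_labels,
    predicted_probability_vectors: np.ndarray,
    class_order,
    clip: float = 1e-15,
) -> ScoreReport:
    """Full evaluation report from predicted probability vectors.

    Hard labels are the argmax over ``class_order`` (ties to the lowest
    index).  Per-class one-vs-rest precision / recall / F1 use the
    zero-denominator-gives-zero convention; cross-entropy is the mean of
    -log of the probability assigned to the true class, clipped to
    [``clip``, 1].
    """
    true_labels = list(true_labels)
    probs = np.asarray(predicted_probability_vectors, dtype=float)
    order = list(class_order)
    if probs.ndim != 2 or probs.shape[1] != len(order):
        raise ValueError("probability vectors must be (n, len(class_order))")
    if np.any(probs < 0) or np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("probability vectors must be normalized")
    index = {c: i for i, c in enumerate(order)}
    unknown = [t for t in true_labels if t not in index]
    if unknown:
        raise ValueError(f"true labels outside class_order: {sorted(set(unknown))[:5]}")
    true_idx = np.array([index[t] for t in true_labels])
    pred_idx = probs.argmax(axis=1)

    rows = []
    for k, cls in enumerate(order):
        tp = int(((pred_idx == k) & (true_idx == k)).sum())
        fp = int(((pred_idx == k) & (true_idx != k)).sum())
        fn = int(((pred_idx != k) & (true_idx == k)).sum())
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        rows.append(
            {"precision": p, "recall": r, "f1": f1_from_pr(p, r), "support": tp + fn}
        )
    per_class = pd.DataFrame(rows, index=order)
    macro, weighted = aggregate_f1(per_class["f1"].to_numpy(), per_class["support"].to_numpy())
    accuracy = float((pred_idx == true_idx).mean()) if len(true_idx) else 0.0
    p_true = np.clip(probs[np.arange(len(true_idx)), true_idx], clip, 1.0)
    cross_entropy = float(-np.log(p_true).mean()) if len(true_idx) else 0.0
    return ScoreReport(
        per_class=per_class,
        macro_f1=macro,
        weighted_f1=weighted,
        accuracy=accuracy,
        cross_entropy=cross_entropy,
    )
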