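"""Classification metrics, cross-validated aggregation, and Grad-CAM.

Per-class "accuracy" here is one-vs-rest *binary* accuracy — the class
against all others pooled — not top-1 multiclass accuracy.  This is the
only convention under which per-class accuracies and their macro mean are
mutually consistent with the reporting format this package mirrors, so it
is the default everywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import rankdata

from .model import WaveletFusionViT


class UndefinedMetricError(ValueError):
    """A metric has an empty denominator (e.g. no positives for AUC/SN)."""


@dataclass
class ConfusionMatrix:
    """Rows = true class, columns = predicted class."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix counts must be nonnegative")

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ClassMetrics:
    """One-vs-rest percentages plus optional AUC fraction for one class."""

    sensitivity: float
    specificity: float
    accuracy: float
    auc: float | None = None


def confusion_matrix(true_labels, predicted_labels, n_classes: int) -> ConfusionMatrix:
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.shape != p.shape:
        raise ValueError("label arrays must align")
    counts = np.zeros((n_classes, n_classes), dtype=int)
    if t.size:
        if t.min() < 0 or t.max() >= n_classes or p.min() < 0 or p.max() >= n_classes:
            raise ValueError(f"label out of range [0, {n_classes})")
        np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts)


def one_vs_rest_metrics(cm: ConfusionMatrix, class_id: int) -> ClassMetrics:
    """SN = TP/(TP+FN), SP = TN/(TN+FP), ACC = (TP+TN)/total, as percentages."""
    c = cm.counts
    if not 0 <= class_id < cm.n_classes:
        raise ValueError(f"class_id {class_id} out of range")
    tp = int(c[class_id, class_id])
    fn = int(c[class_id].sum() - tp)
    fp = int(c[:, class_id].sum() - tp)
    tn = int(c.sum() - tp - fn - fp)
    if tp + fn == 0:
        raise UndefinedMetricError(f"class {class_id} has no support; SN undefined")
    if tn + fp == 0:
        raise UndefinedMetricError(f"class {class_id} covers all samples; SP undefined")
    return ClassMetrics(
        sensitivity=100.0 * tp / (tp + fn),
        specificity=100.0 * tn / (tn + fp),
        accuracy=100.0 * (tp + tn) / cm.total,
    )


def roc_auc(scores, binary_labels) -> float:
    """Rank-statistic AUC; tied scores contribute half per tied pair."""
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(binary_labels, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must align")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC undefined without both classes present")
    ranks = rankdata(s)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return float(auc)


def macro_mean(values) -> float:
    """Arithmetic average across classes (the "Means"-row convention)."""
    values = np.asarray(values, dtype=np.float64)
    return float(values.mean())


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding, matching how printed tables round .5 up."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# fold-level evaluation and aggregation


@dataclass
class FoldMetrics:
    per_class: list[ClassMetrics]
    cm: ConfusionMatrix | None = None

    def macro(self, metric: str) -> float:
        return macro_mean([getattr(m, metric) for m in self.per_class])


def evaluate_fold(true_labels, scores, n_classes: int) -> FoldMetrics:
    """Full per-class metrics for one validation fold from softmax scores."""
    scores = np.asarray(scores, dtype=np.float64)
    preds = scores.argmax(axis=1)
    cm = confusion_matrix(true_labels, preds, n_classes)
    t = np.asarray(true_labels, dtype=int)
    per_class = []
    for cls in range(n_classes):
        m = one_vs_rest_metrics(cm, cls)
        try:
            m.auc = roc_auc(scores[:, cls], (t == cls).astype(int))
        except UndefinedMetricError:
            m.auc = None
        per_class.append(m)
    return FoldMetrics(per_class=per_class, cm=cm)


@dataclass
class MetricsReport:
    """Cross-validated mean ± sample std per metric per class."""

    folds: list[FoldMetrics]
    n_classes: int

    def _values(self, metric: str, cls: int) -> np.ndarray:
        vals = [getattr(f.per_class[cls], metric) for f in self.folds]
        return np.array([v for v in vals if v is not None], dtype=np.float64)

    def mean_std(self, metric: str, cls: int) -> tuple[float, float]:
        v = self._values(metric, cls)
        if v.size == 0:
            raise UndefinedMetricError(f"{metric} undefined for class {cls} in all folds")
        std = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
        return float(v.mean()), std

    def macro_mean_std(self, metric: str) -> tuple[float, float]:
        per_fold = [f.macro(metric) for f in self.folds]
        v = np.array(per_fold, dtype=np.float64)
        std = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
        return float(v.mean()), std

    def summary(self) -> dict:
        out: dict = {"per_class": {}, "macro": {}}
        for cls in range(self.n_classes):
            entry = {}
            for metric in ("sensitivity", "specificity", "accuracy", "auc"):
                try:
                    m, s = self.mean_std(metric, cls)
                    entry[metric] = {"mean": m, "std": s}
                except UndefinedMetricError:
                    entry[metric] = None
            out["per_class"][cls] = entry
        for metric in ("sensitivity", "specificity", "accuracy"):
            m, s = self.macro_mean_std(metric)
            out["macro"][metric] = {"mean": m, "std": s}
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2))

    def to_csv(self, path: str | Path) -> None:
        rows = ["class,metric,mean,std"]
        summary = self.summary()
        for cls, entry in summary["per_class"].items():
            for metric, val in entry.items():
                if val is not None:
                    rows.append(f"{cls},{metric},{val['mean']},{val['std']}")
        for metric, val in summary["macro"].items():
            rows.append(f"macro,{metric},{val['mean']},{val['std']}")
        Path(path).write_text("\n".join(rows) + "\n")


def crossval_report(per_fold_metrics: list[FoldMetrics]) -> MetricsReport:
    if not per_fold_metrics:
        raise ValueError("at least one fold is required")
    n_classes = len(per_fold_metrics[0].per_class)
    return MetricsReport(folds=per_fold_metrics, n_classes=n_classes)


# ---------------------------------------------------------------------------
# Grad-CAM


def gradcam(model: WaveletFusionViT, image: np.ndarray, target_class: int) -> np.ndarray:
    """Relevance heatmap for ``target_class`` over the input image.

    Gradients of the target logit w.r.t. the final transformer block's
    token activations are channel-averaged into weights, the weighted token
    activations are rectified, laid out on the patch grid, bilinearly
    upsampled to image size and min-max normalized to ``[0, 1]``.  A
    gradient-free (degenerate) map comes back as all zeros.
    """
    from scipy.ndimage import zoom

    cfg = model.cfg
    if not 0 <= target_class < cfg.n_classes:
        raise ValueError(f"target_class {target_class} out of range")
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        image = image[None]
    logits = model.forward(image[None])
    onehot = np.zeros_like(logits.data)
    onehot[0, target_class] = 1.0
    logits.backward(onehot)
    tokens = model.last_block_tokens
    acts = tokens.data[0, 1:, :]          # patch tokens only (no class token)
    grads = tokens.grad[0, 1:, :]
    alpha = grads.mean(axis=0)            # channel weights
    cam = np.maximum(acts @ alpha, 0.0)
    g = cfg.image_size // cfg.patch_size
    cam = cam.reshape(g, g)
    cam = zoom(cam, cfg.image_size / g, order=1)
    lo, hi = cam.min(), cam.max()
    if hi - lo < 1e-12:
        return np.zeros((cfg.image_size, cfg.image_size))
    return (cam - lo) / (hi - lo)


def overlay_heatmap(image: np.ndarray, cam: np.ndarray) -> np.ndarray:
    """Blend a ``[0,1]`` heatmap over a grayscale image -> RGB uint8."""
    import matplotlib

    rgba = matplotlib.colormaps["jet"](np.clip(cam, 0, 1))[..., :3]
    gray = np.repeat(np.clip(image, 0, 1)[..., None], 3, axis=-1)
    blend = 0.5 * gray + 0.5 * rgba
    return np.clip(np.round(blend * 255), 0, 255).astype(np.uint8)
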