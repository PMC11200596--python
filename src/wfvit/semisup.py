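"""Semi-supervised training with self-adaptive pseudo-label thresholds.

Supervised cross-entropy on a small labeled subset is combined with an
unsupervised term: pseudo-labels are taken from predictions on weakly
augmented views, kept only where confidence clears a class-modulated
threshold, and used as cross-entropy targets for strongly augmented views.
The joint objective is the plain sum ``L = Ls + Lu``.

Thresholds follow the self-adaptive scheme of the cited matching
algorithm: a global level tracks the running mean of max-confidence via an
exponential moving average initialized at ``1/C``, and per-class levels
scale it by the running class-probability profile.  The optional fairness
regularizer of that algorithm is intentionally absent.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .autodiff import AdamW, Tensor
from .data import DataError, Dataset, augment, strong_augment, weak_augment
from .model import WaveletFusionViT


@dataclass
class LabeledSet:
    items: list[tuple[np.ndarray, int]]

    def __len__(self) -> int:
        return len(self.items)

    def images(self) -> np.ndarray:
        return np.stack([im for im, _ in self.items])

    def labels(self) -> np.ndarray:
        return np.array([lab for _, lab in self.items], dtype=int)


@dataclass
class UnlabeledSet:
    items: list[np.ndarray]

    def __len__(self) -> int:
        return len(self.items)


@dataclass
class ThresholdState:
    """Global and per-class confidence thresholds, evolved by EMA."""

    global_tau: float
    class_probs: np.ndarray
    ema_decay: float = 0.999

    @classmethod
    def initial(cls, n_classes: int, ema_decay: float = 0.999) -> "ThresholdState":
        return cls(
            global_tau=1.0 / n_classes,
            class_probs=np.full(n_classes, 1.0 / n_classes),
            ema_decay=ema_decay,
        )

    def per_class_thresholds(self) -> np.ndarray:
        return self.global_tau * self.class_probs / self.class_probs.max()


@dataclass
class LossReport:
    ls: float
    lu: float
    total: float
    utilization: float

    def __post_init__(self) -> None:
        assert self.total == self.ls + self.lu


# ---------------------------------------------------------------------------
# pure functions on prediction arrays


def select_labeled_subset(
    fold: Dataset, per_class: int, seed: int
) -> tuple[LabeledSet, UnlabeledSet]:
    """Draw ``per_class`` labeled items per class; the rest lose their labels."""
    labels = fold.labels()
    n_classes = len(fold.class_names)
    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    for cls in range(n_classes):
        members = np.flatnonzero(labels == cls)
        if members.size < per_class:
            raise DataError(
                f"class {fold.class_names[cls]} has {members.size} members, "
                f"fewer than per_class={per_class}"
            )
        chosen.extend(rng.choice(members, size=per_class, replace=False).tolist())
    chosen_set = set(chosen)
    labeled = LabeledSet([(fold.items[i][0], fold.items[i][1]) for i in sorted(chosen_set)])
    unlabeled = UnlabeledSet(
        [fold.items[i][0] for i in range(len(fold)) if i not in chosen_set]
    )
    return labeled, unlabeled


def supervised_loss(predictions: np.ndarray, labels: np.ndarray) -> float:
    """Mean cross-entropy of probability rows against integer labels."""
    predictions = np.asarray(predictions, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    n_classes = predictions.shape[-1]
    if labels.size and (labels.min() < 0 or labels.max() >= n_classes):
        raise ValueError(f"label out of range [0, {n_classes})")
    p = predictions[np.arange(len(labels)), labels]
    return float(np.mean(-np.log(np.clip(p, 1e-300, None))))


def pseudo_label(
    weak_predictions: np.ndarray, state: ThresholdState
) -> tuple[np.ndarray, np.ndarray]:
    """Argmax labels plus a confidence mask against per-class thresholds.

    Ties at the argmax resolve to the lowest class index.
    """
    weak_predictions = np.asarray(weak_predictions, dtype=np.float64)
    if weak_predictions.size == 0:
        return np.zeros(0, dtype=int), np.zeros(0, dtype=bool)
    labels = np.argmax(weak_predictions, axis=-1)
    conf = weak_predictions[np.arange(len(labels)), labels]
    mask = conf >= state.per_class_thresholds()[labels]
    return labels, mask


def update_thresholds(
    state: ThresholdState, weak_predictions: np.ndarray
) -> ThresholdState:
    """EMA update of the global level and the class-probability profile."""
    weak_predictions = np.asarray(weak_predictions, dtype=np.float64)
    if weak_predictions.size == 0:
        return state
    lam = state.ema_decay
    tau = lam * state.global_tau + (1 - lam) * float(weak_predictions.max(axis=-1).mean())
    probs = lam * state.class_probs + (1 - lam) * weak_predictions.mean(axis=0)
    return ThresholdState(global_tau=tau, class_probs=probs, ema_decay=lam)


def unsupervised_loss(
    strong_predictions: np.ndarray, labels: np.ndarray, confidence_mask: np.ndarray
) -> float:
    """Mean CE over mask-passing samples; 0 when nothing passes."""
    strong_predictions = np.asarray(strong_predictions, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    confidence_mask = np.asarray(confidence_mask, dtype=bool)
    if strong_predictions.shape[0] != labels.shape[0] != confidence_mask.shape[0]:
        raise ValueError("strong predictions, labels and mask must align")
    if not confidence_mask.any():
        return 0.0
    p = strong_predictions[confidence_mask, labels[confidence_mask]]
    return float(np.mean(-np.log(np.clip(p, 1e-300, None))))


# ---------------------------------------------------------------------------
# differentiable CE helper


def _ce_loss_t(logits: Tensor, labels: np.ndarray) -> Tensor:
    logsm = logits.log_softmax(axis=-1)
    picked = logsm[np.arange(len(labels)), np.asarray(labels, dtype=int)]
    return -picked.mean()


# ---------------------------------------------------------------------------
# training loops


def train_step(
    model: WaveletFusionViT,
    opt: AdamW,
    labeled_images: np.ndarray,
    labeled_labels: np.ndarray,
    unlabeled_images: list[np.ndarray],
    state: ThresholdState,
    rng: np.random.Generator,
    augment_unlabeled: bool = True,
) -> tuple[ThresholdState, LossReport]:
    """One optimizer step on ``L = Ls + Lu``."""
    logits_l = model.forward(labeled_images)
    ls = _ce_loss_t(logits_l, labeled_labels)

    if len(unlabeled_images) > 0:
        if augment_unlabeled:
            weak = np.stack([weak_augment(im, rng) for im in unlabeled_images])[:, None]
            strong = np.stack([strong_augment(im, rng) for im in unlabeled_images])[:, None]
        else:
            weak = strong = np.stack(unlabeled_images)[:, None]
        weak_probs = model.forward(weak).softmax(axis=-1).data  # no gradient flows back
        state = update_thresholds(state, weak_probs)
        plabels, mask = pseudo_label(weak_probs, state)
        if mask.any():
            logits_s = model.forward(strong[mask])
            lu = _ce_loss_t(logits_s, plabels[mask])
        else:
            lu = Tensor(0.0)
        utilization = float(mask.mean())
    else:
        lu = Tensor(0.0)
        utilization = 0.0

    total = ls + lu
    opt.zero_grad()
    if total.requires_grad:
        total.backward()
    opt.step()
    report = LossReport(
        ls=float(ls.data), lu=float(lu.data), total=float(ls.data) + float(lu.data),
        utilization=utilization,
    )
    return state, report


def train_ssl(
    model: WaveletFusionViT,
    labeled: LabeledSet,
    unlabeled: UnlabeledSet,
    epochs: int,
    seed: int = 0,
    labeled_batch: int = 8,
    unlabeled_ratio: int = 7,
    lr: float = 1e-3,
    ema_decay: float = 0.999,
    log_path: str | Path | None = None,
) -> tuple[WaveletFusionViT, ThresholdState, list[LossReport]]:
    """Joint supervised + pseudo-label training over the labeled subset and
    the unlabeled pool.  Labeled:unlabeled batch ratio defaults to 1:7."""
    if len(labeled) == 0:
        raise DataError("labeled set is empty")
    rng = np.random.default_rng(seed)
    opt = AdamW(model.flat_params(), lr=lr)
    state = ThresholdState.initial(model.cfg.n_classes, ema_decay=ema_decay)
    imgs = labeled.images()[:, None]  # (N, 1, H, W)
    labs = labeled.labels()
    pool = list(unlabeled.items)
    history: list[LossReport] = []
    rows = []
    step = 0
    for _epoch in range(epochs):
        order = rng.permutation(len(imgs))
        for start in range(0, len(imgs), labeled_batch):
            idx = order[start : start + labeled_batch]
            lb_imgs = np.stack(
                [augment(imgs[i, 0], 0.5, rng) for i in idx]
            )[:, None]
            n_u = min(len(pool), len(idx) * unlabeled_ratio)
            if n_u > 0:
                uidx = rng.choice(len(pool), size=n_u, replace=False)
                ub = [pool[i] for i in uidx]
            else:
                ub = []
            state, report = train_step(model, opt, lb_imgs, labs[idx], ub, state, rng)
            history.append(report)
            rows.append([step, report.ls, report.lu, report.total,
                         report.utilization, state.global_tau])
            step += 1
    if log_path is not None:
        with open(log_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["step", "ls", "lu", "total", "utilization", "global_tau"])
            w.writerows(rows)
    return model, state, history


def train_supervised(
    model: WaveletFusionViT,
    labeled: LabeledSet,
    epochs: int,
    seed: int = 0,
    batch_size: int = 8,
    lr: float = 1e-3,
    augment_prob: float = 0.5,
    log_path: str | Path | None = None,
) -> tuple[WaveletFusionViT, list[float]]:
    """Cross-entropy baseline on labeled data with the same augmentations."""
    if len(labeled) == 0:
        raise DataError("labeled set is empty")
    rng = np.random.default_rng(seed)
    opt = AdamW(model.flat_params(), lr=lr)
    imgs = labeled.images()
    labs = labeled.labels()
    losses: list[float] = []
    for _epoch in range(epochs):
        order = rng.permutation(len(imgs))
        epoch_losses = []
        for start in range(0, len(imgs), batch_size):
            idx = order[start : start + batch_size]
            batch = np.stack([augment(imgs[i], augment_prob, rng) for i in idx])[:, None]
            logits = model.forward(batch)
            loss = _ce_loss_t(logits, labs[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        losses.append(float(np.mean(epoch_losses)))
    if log_path is not None:
        with open(log_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["epoch", "loss"])
            w.writerows(enumerate(losses))
    return model, losses


def predict_dataset(model: WaveletFusionViT, images: list[np.ndarray],
                    batch_size: int = 32) -> np.ndarray:
    """Softmax scores for a list of ``H x W`` images."""
    out = []
    for start in range(0, len(images), batch_size):
        batch = np.stack(images[start : start + batch_size])[:, None]
        out.append(model.forward(batch).softmax(axis=-1).data)
    return np.concatenate(out, axis=0) if out else np.zeros((0, model.cfg.n_classes))
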