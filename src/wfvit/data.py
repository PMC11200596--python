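"""Image ingestion, resizing, stochastic augmentation and stratified folds.

All images are single-channel float grids in ``[0, 1]``.  Every stochastic
operation takes an explicit seed (or ``numpy.random.Generator``) so two runs
with equal seeds are bit-identical.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "DataError",
    "Dataset",
    "FoldSplit",
    "AugmentConfig",
    "load_dataset",
    "load_image",
    "resize",
    "augment",
    "hist_equalize",
    "weak_augment",
    "strong_augment",
    "expected_augmented_count",
    "stratified_kfold",
    "export_splits",
    "load_splits",
]


class DataError(ValueError):
    """Raised for unusable data: empty classes, missing files, bad folds."""


@dataclass
class Dataset:
    """In-memory image collection: ``(image, label, source_path)`` triples."""

    items: list[tuple[np.ndarray, int, str]]
    class_names: list[str]

    def __post_init__(self) -> None:
        n = len(self.class_names)
        for _, label, path in self.items:
            if not 0 <= label < n:
                raise DataError(f"label {label} out of range for {path}")

    def __len__(self) -> int:
        return len(self.items)

    def images(self) -> list[np.ndarray]:
        return [im for im, _, _ in self.items]

    def labels(self) -> np.ndarray:
        return np.array([lab for _, lab, _ in self.items], dtype=int)

    def subset(self, indices) -> "Dataset":
        return Dataset([self.items[i] for i in indices], self.class_names)

    def resized(self, size: int) -> "Dataset":
        return Dataset(
            [(resize(im, size), lab, p) for im, lab, p in self.items],
            self.class_names,
        )


@dataclass
class FoldSplit:
    fold_index: int  # 1-based
    train_idx: np.ndarray
    val_idx: np.ndarray


def _to_unit_float(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    arr = arr.astype(np.float64)
    m = arr.max()
    return arr / m if m > 1.0 else arr


def load_image(path: str | Path) -> np.ndarray:
    """Decode one image file to a grayscale ``H x W`` grid in ``[0, 1]``."""
    with Image.open(path) as im:
        if im.mode in ("I;16", "I"):
            arr = np.asarray(im)
        else:
            arr = np.asarray(im.convert("L"))
    return _to_unit_float(arr)


def load_dataset(root: str | Path) -> Dataset:
    """Load a directory-per-class tree or a ``path,label`` CSV manifest.

    Undecodable files are excluded with an itemized warning; an empty class
    (or empty root) is an error.
    """
    root = Path(root)
    if root.is_file():
        return _load_manifest(root)
    if not root.is_dir():
        raise DataError(f"dataset root {root} does not exist")
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not class_dirs:
        raise DataError(f"no class subdirectories under {root}")
    class_names = [d.name for d in class_dirs]
    items: list[tuple[np.ndarray, int, str]] = []
    for label, d in enumerate(class_dirs):
        files = sorted(p for p in d.iterdir() if p.suffix.lower() in (".png", ".jpg", ".jpeg"))
        count = 0
        for p in files:
            try:
                items.append((load_image(p), label, str(p)))
                count += 1
            except Exception as exc:  # decode failure: exclude, keep going
                warnings.warn(f"excluding unreadable image {p}: {exc}")
        if count == 0:
            raise DataError(f"class directory {d} contains no decodable images")
    return Dataset(items, class_names)


def _load_manifest(path: Path) -> Dataset:
    rows = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"path", "label"} <= set(reader.fieldnames):
            raise DataError(f"manifest {path} must have 'path' and 'label' columns")
        rows = list(reader)
    if not rows:
        raise DataError(f"manifest {path} is empty")
    class_names = sorted({r["label"] for r in rows})
    name_to_id = {n: i for i, n in enumerate(class_names)}
    items = []
    for r in rows:
        p = Path(r["path"])
        if not p.is_absolute():
            p = path.parent / p
        try:
            items.append((load_image(p), name_to_id[r["label"]], str(p)))
        except Exception as exc:
            warnings.warn(f"excluding unreadable image {p}: {exc}")
    if not items:
        raise DataError(f"manifest {path} yielded no decodable images")
    return Dataset(items, class_names)


# ---------------------------------------------------------------------------
# geometry / intensity ops


def resize(x: np.ndarray, size: int) -> np.ndarray:
    """Bilinear resize of an ``H x W`` grid to ``size x size``."""
    if size <= 0:
        raise ValueError(f"target size must be positive, got {size}")
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise ValueError("cannot resize an empty image")
    if x.shape == (size, size):
        return x.copy()
    im = Image.fromarray(x.astype(np.float32), mode="F")
    out = np.asarray(im.resize((size, size), Image.BILINEAR), dtype=np.float64)
    return np.clip(out, 0.0, 1.0)


def hist_equalize(x: np.ndarray, bins: int = 256) -> np.ndarray:
    """Global histogram equalization on quantized intensities.

    A constant image maps to itself.
    """
    x = np.asarray(x, dtype=np.float64)
    q = np.clip((x * (bins - 1)).astype(int), 0, bins - 1)
    hist = np.bincount(q.ravel(), minlength=bins)
    cdf = np.cumsum(hist).astype(np.float64)
    cdf /= cdf[-1]
    cdf_min = cdf[np.nonzero(hist)[0][0]]
    if cdf_min >= 1.0:  # constant image
        return x.copy()
    lut = (cdf - cdf_min) / (1.0 - cdf_min)
    return np.clip(lut[q], 0.0, 1.0)


@dataclass
class AugmentConfig:
    flip_prob: float = 0.5
    rotate_range: float = 15.0     # degrees, uniform in +-range
    crop_scale: tuple[float, float] = (0.8, 1.0)
    hist_eq_prob: float = 0.5
    jitter: float = 0.0            # multiplicative/additive intensity jitter


WEAK_AUGMENT = AugmentConfig(flip_prob=0.5, rotate_range=0.0, crop_scale=(0.9, 1.0),
                             hist_eq_prob=0.0)
STRONG_AUGMENT = AugmentConfig(flip_prob=0.5, rotate_range=15.0, crop_scale=(0.8, 1.0),
                               hist_eq_prob=0.5, jitter=0.1)


def _apply_ops(x: np.ndarray, rng: np.random.Generator, cfg: AugmentConfig) -> np.ndarray:
    h, w = x.shape
    if rng.random() < cfg.flip_prob:
        x = x[:, ::-1].copy()
    if cfg.rotate_range > 0:
        angle = rng.uniform(-cfg.rotate_range, cfg.rotate_range)
        x = ndimage.rotate(x, angle, reshape=False, order=1, mode="nearest")
    lo, hi = cfg.crop_scale
    if hi > lo or hi < 1.0:
        scale = rng.uniform(lo, hi)
        ch, cw = max(2, int(round(h * scale))), max(2, int(round(w * scale)))
        top = rng.integers(0, h - ch + 1)
        left = rng.integers(0, w - cw + 1)
        x = x[top : top + ch, left : left + cw]
        im = Image.fromarray(x.astype(np.float32), mode="F")
        x = np.asarray(im.resize((w, h), Image.BILINEAR), dtype=np.float64)
    if rng.random() < cfg.hist_eq_prob:
        x = hist_equalize(x)
    if cfg.jitter > 0:
        gain = 1.0 + rng.uniform(-cfg.jitter, cfg.jitter)
        bias = rng.uniform(-cfg.jitter, cfg.jitter)
        x = x * gain + bias
    return np.clip(x, 0.0, 1.0)


def augment(
    x: np.ndarray,
    p: float,
    seed: int | np.random.Generator,
    cfg: AugmentConfig | None = None,
) -> np.ndarray:
    """With probability ``p`` apply the stochastic augmentation sequence."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"augmentation probability must lie in [0, 1], got {p}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.asarray(x, dtype=np.float64)
    if rng.random() >= p:
        return x.copy()
    return _apply_ops(x, rng, cfg or AugmentConfig())


def weak_augment(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return _apply_ops(np.asarray(x, dtype=np.float64), rng, WEAK_AUGMENT)


def strong_augment(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return _apply_ops(np.asarray(x, dtype=np.float64), rng, STRONG_AUGMENT)


def expected_augmented_count(n_train: int, epochs: int, p: float) -> int:
    """Expected number of augmented images produced over a whole training run."""
    if n_train < 0 or epochs < 0 or not 0.0 <= p <= 1.0:
        raise ValueError("inputs must be nonnegative with p in [0, 1]")
    return int(round(n_train * epochs * p))


# ---------------------------------------------------------------------------
# cross-validation folds


def stratified_kfold(labels, k: int, seed: int) -> list[FoldSplit]:
    """Deterministic stratified k-fold partition of ``labels``.

    Accepts a label sequence or a :class:`Dataset`; per-class validation
    counts stay within one of the proportional share.
    """
    if isinstance(labels, Dataset):
        labels = labels.labels()
    labels = np.asarray(labels, dtype=int)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    counts = np.bincount(labels)
    for cls, c in enumerate(counts):
        if 0 < c < k:
            raise DataError(f"class {cls} has only {c} members, fewer than k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        FoldSplit(fold_index=i + 1, train_idx=tr, val_idx=va)
        for i, (tr, va) in enumerate(skf.split(np.zeros(len(labels)), labels))
    ]


def export_splits(splits: list[FoldSplit], path: str | Path) -> None:
    payload = [
        {
            "fold_index": s.fold_index,
            "train_idx": [int(i) for i in s.train_idx],
            "val_idx": [int(i) for i in s.val_idx],
        }
        for s in splits
    ]
    Path(path).write_text(json.dumps(payload))


def load_splits(path: str | Path) -> list[FoldSplit]:
    payload = json.loads(Path(path).read_text())
    return [
        FoldSplit(
            fold_index=d["fold_index"],
            train_idx=np.array(d["train_idx"], dtype=int),
            val_idx=np.array(d["val_idx"], dtype=int),
        )
        for d in payload
    ]
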