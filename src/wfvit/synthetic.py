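"""Seeded generator of jaw-like grayscale phantoms in four classes.

Classes mimic the imaging phenotypes of the clinical categories:

* ``healthy`` — background only (bright horizontal arch band, no lesion);
* ``am``      — 2-4 overlapping dark locules with sharp borders;
* ``pc``      — one small round dark locule with a sharp border at the
  arch margin;
* ``cso``     — one large irregular dark region with heavily blurred
  (ill-defined) borders and bright sclerotic speckle inside.

Geometry is built from smoothed unions of discs: the goal is separable,
reproducible structure for testing the training stack, not anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .data import Dataset

CLASS_NAMES = ["healthy", "am", "pc", "cso"]


@dataclass
class SyntheticSpec:
    """Parameter supports for the generator (pixel units at size 128)."""

    image_size: int = 128
    # background
    base_level: float = 0.25
    gradient_strength: float = 0.15
    band_brightness: float = 0.45
    band_center_frac: float = 0.55
    band_width_frac: float = 0.16
    arch_curvature: float = 0.10
    noise_amplitude: float = 0.02
    noise_sigma: float = 2.5
    # ameloblastoma-like: multilocular, well defined
    # (contrasts/radii tuned so tiny models separate the classes in minutes)
    am_locules: tuple[int, int] = (2, 4)
    am_radius: tuple[float, float] = (9.0, 14.0)
    am_blur: tuple[float, float] = (0.4, 0.9)
    am_contrast: tuple[float, float] = (0.45, 0.60)
    # periapical-cyst-like: single round, well defined, small, at arch margin
    pc_radius: tuple[float, float] = (5.0, 9.0)
    pc_blur: tuple[float, float] = (0.4, 0.9)
    pc_contrast: tuple[float, float] = (0.45, 0.60)
    # osteomyelitis-like: irregular, ill defined, mixed lucent/sclerotic
    cso_radius: tuple[float, float] = (13.0, 19.0)
    cso_blur: tuple[float, float] = (3.0, 5.0)
    cso_contrast: tuple[float, float] = (0.30, 0.45)
    cso_speckle_density: tuple[float, float] = (0.05, 0.15)

    @property
    def scale(self) -> float:
        return self.image_size / 128.0


def _band_center(spec: SyntheticSpec, xs: np.ndarray) -> np.ndarray:
    s = spec.image_size
    # gentle arch: band rises toward the image edges
    return spec.band_center_frac * s - spec.arch_curvature * s * (
        ((xs - s / 2) / (s / 2)) ** 2 - 0.5
    )


def generate_background(
    size: int, spec: SyntheticSpec | None = None, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Smooth jaw-like band (bright arch on a darker field) plus noise."""
    spec = spec or SyntheticSpec(image_size=size)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ys, xs = np.mgrid[0:size, 0:size].astype(np.float64)
    center = _band_center(spec, xs)
    width = spec.band_width_frac * size
    img = spec.base_level + spec.gradient_strength * (1.0 - ys / size)
    img += spec.band_brightness * np.exp(-(((ys - center) / width) ** 2))
    if spec.noise_amplitude > 0:
        noise = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (size, size)),
                                        spec.noise_sigma)
        peak = np.abs(noise).max()
        if peak > 0:
            img += spec.noise_amplitude * noise / peak
    return np.clip(img, 0.0, 1.0)


def _disc(size: int, cy: float, cx: float, r: float) -> np.ndarray:
    ys, xs = np.mgrid[0:size, 0:size].astype(np.float64)
    return ((ys - cy) ** 2 + (xs - cx) ** 2 <= r * r).astype(np.float64)


def _uniform(rng: np.random.Generator, support: tuple[float, float]) -> float:
    return float(rng.uniform(*support))


def sample_params(class_id: int, spec: SyntheticSpec, seed: int) -> dict:
    """Deterministic class-conditional parameter draw (shared with rendering)."""
    if not 0 <= class_id <= 3:
        raise ValueError(f"class_id must be in 0..3, got {class_id}")
    rng = np.random.default_rng(seed)
    s = spec.image_size
    sc = spec.scale
    params: dict = {"class_id": class_id, "bg_seed": int(rng.integers(2 ** 31))}
    xs = np.array([rng.uniform(0.25 * s, 0.75 * s)])
    cy = float(_band_center(spec, xs)[0])
    cx = float(xs[0])
    if class_id == 0:
        return params
    if class_id == 1:  # multilocular, sharp
        n_loc = int(rng.integers(spec.am_locules[0], spec.am_locules[1] + 1))
        radius = _uniform(rng, spec.am_radius) * sc
        centers = [(cy, cx)]
        for _ in range(n_loc - 1):
            ang = rng.uniform(0, 2 * np.pi)
            step = radius * rng.uniform(0.8, 1.2)
            centers.append((centers[-1][0] + step * np.sin(ang) * 0.5,
                            centers[-1][1] + step * np.cos(ang)))
        params.update(
            locules=n_loc, radius=radius, centers=centers,
            blur=_uniform(rng, spec.am_blur) * sc,
            contrast=_uniform(rng, spec.am_contrast),
        )
    elif class_id == 2:  # single round, sharp, at arch margin
        radius = _uniform(rng, spec.pc_radius) * sc
        margin_cy = cy + spec.band_width_frac * s * rng.choice([-1.0, 1.0])
        params.update(
            radius=radius, center=(float(margin_cy), cx),
            blur=_uniform(rng, spec.pc_blur) * sc,
            contrast=_uniform(rng, spec.pc_contrast),
        )
    else:  # irregular, ill defined, speckled
        params.update(
            radius=_uniform(rng, spec.cso_radius) * sc,
            center=(cy, cx),
            blur=_uniform(rng, spec.cso_blur) * sc,
            contrast=_uniform(rng, spec.cso_contrast),
            speckle_density=_uniform(rng, spec.cso_speckle_density),
            shape_seed=int(rng.integers(2 ** 31)),
        )
    return params


def _render(params: dict, spec: SyntheticSpec) -> np.ndarray:
    s = spec.image_size
    img = generate_background(s, spec, params["bg_seed"])
    cid = params["class_id"]
    if cid == 0:
        return img
    if cid == 1:
        mask = np.zeros((s, s))
        for cy, cx in params["centers"]:
            mask = np.maximum(mask, _disc(s, cy, cx, params["radius"]))
        soft = ndimage.gaussian_filter(mask, params["blur"])
    elif cid == 2:
        mask = _disc(s, *params["center"], params["radius"])
        soft = ndimage.gaussian_filter(mask, params["blur"])
    else:
        rng = np.random.default_rng(params["shape_seed"])
        base = _disc(s, *params["center"], params["radius"])
        wobble = ndimage.gaussian_filter(rng.normal(0, 1, (s, s)), 4.0)
        wobble = wobble / (np.abs(wobble).max() + 1e-12)
        irregular = (base + 0.6 * wobble * base > 0.5).astype(np.float64)
        if irregular.sum() == 0:
            irregular = base
        soft = ndimage.gaussian_filter(irregular, params["blur"])
        # sclerotic speckle: bright dots inside the lesion footprint
        inside = np.flatnonzero(irregular.ravel())
        k = int(round(params["speckle_density"] * inside.size))
        if k > 0:
            pick = rng.choice(inside, size=k, replace=False)
            speckle = np.zeros(s * s)
            speckle[pick] = 1.0
            speckle = ndimage.gaussian_filter(speckle.reshape(s, s), 0.7)
            peak = speckle.max()
            if peak > 0:
                img = img + 0.35 * speckle / peak
    img = img - params["contrast"] * soft
    return np.clip(img, 0.0, 1.0)


def generate_sample(
    class_id: int, spec: SyntheticSpec | None = None, seed: int = 0
) -> tuple[np.ndarray, int]:
    """One seeded phantom of the requested class."""
    spec = spec or SyntheticSpec()
    params = sample_params(class_id, spec, seed)
    return _render(params, spec), class_id


def generate_dataset(
    n_per_class: int, spec: SyntheticSpec | None = None, seed: int = 0
) -> Dataset:
    """Balanced, deterministically shuffled phantom dataset (4 classes)."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(seed)
    items = []
    for cid in range(4):
        for i in range(n_per_class):
            sample_seed = int(rng.integers(2 ** 31))
            img, lab = generate_sample(cid, spec, sample_seed)
            items.append((img, lab, f"synthetic://{CLASS_NAMES[cid]}/{i}"))
    order = rng.permutation(len(items))
    return Dataset([items[i] for i in order], list(CLASS_NAMES))


# ---------------------------------------------------------------------------
# crude per-image statistics used to sanity-check class separability


def baseline_features(img: np.ndarray) -> np.ndarray:
    """Five hand-crafted features: lesion area fraction, minimum intensity,
    mean border gradient, bright-speckle count, connected dark components."""
    img = np.asarray(img, dtype=np.float64)
    med = np.median(img)
    dark = img < med - 0.15
    area = float(dark.mean())
    gy, gx = np.gradient(img)
    gmag = np.hypot(gy, gx)
    border = ndimage.binary_dilation(dark) & ~ndimage.binary_erosion(dark)
    border_grad = float(gmag[border].mean()) if border.any() else 0.0
    region = ndimage.binary_dilation(dark, iterations=3)
    bright = (img > med + 0.18) & region
    n_components = int(ndimage.label(dark)[1])
    return np.array([area, float(img.min()), border_grad, float(bright.sum()),
                     float(n_components)])


def export_png_tree(dataset: Dataset, out_dir: str | Path) -> Path:
    """Write a directory-per-class PNG tree plus a ``manifest.csv``."""
    from PIL import Image

    out_dir = Path(out_dir)
    rows = []
    counters = [0] * len(dataset.class_names)
    for img, lab, _ in dataset.items:
        cls = dataset.class_names[lab]
        d = out_dir / cls
        d.mkdir(parents=True, exist_ok=True)
        name = f"{cls}_{counters[lab]:05d}.png"
        counters[lab] += 1
        arr = np.clip(np.round(img * 255), 0, 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(d / name)
        rows.append((f"{cls}/{name}", cls))
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w") as fh:
        fh.write("path,label\n")
        for p, lab in rows:
            fh.write(f"{p},{lab}\n")
    return manifest
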