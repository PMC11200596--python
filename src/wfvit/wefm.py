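"""Wavelet extraction and fusion: sub-band decomposition, per-band
convolutional fusion, and inverse reconstruction.

The transform is the single-level orthonormal 2-D Haar DWT.  Convention
(kept in lockstep with the brute-force oracle in the test-suite): the
separable low-pass filter is ``(u + v)/sqrt(2)`` and the high-pass is
``(u - v)/sqrt(2)``; ``lh`` is the vertical-detail band (low-pass over
columns, high-pass over rows) and ``hl`` the horizontal-detail band.

Because the transform is orthonormal, the adjoint of the decomposition is
the reconstruction, which makes both directions cheap to differentiate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, parameter

BAND_NAMES = ("ll", "lh", "hl", "hh")


class ConfigurationError(ValueError):
    """Raised when fusion weights are incompatible with their input."""


# ---------------------------------------------------------------------------
# raw Haar kernels (numpy, shared by the forward op and its adjoint)


def _check_even(shape: tuple[int, ...]) -> None:
    h, w = shape[-2], shape[-1]
    if h % 2 != 0:
        raise ValueError(f"height {h} is odd; even spatial dimensions required")
    if w % 2 != 0:
        raise ValueError(f"width {w} is odd; even spatial dimensions required")


def _haar_split(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    a = x[..., 0::2, 0::2]
    b = x[..., 0::2, 1::2]
    c = x[..., 1::2, 0::2]
    d = x[..., 1::2, 1::2]
    ll = (a + b + c + d) / 2.0
    lh = (a + b - c - d) / 2.0
    hl = (a - b + c - d) / 2.0
    hh = (a - b - c + d) / 2.0
    return ll, lh, hl, hh


def _haar_merge(
    ll: np.ndarray, lh: np.ndarray, hl: np.ndarray, hh: np.ndarray
) -> np.ndarray:
    a = (ll + lh + hl + hh) / 2.0
    b = (ll + lh - hl - hh) / 2.0
    c = (ll - lh + hl - hh) / 2.0
    d = (ll - lh - hl + hh) / 2.0
    out_shape = ll.shape[:-2] + (2 * ll.shape[-2], 2 * ll.shape[-1])
    out = np.empty(out_shape, dtype=ll.dtype)
    out[..., 0::2, 0::2] = a
    out[..., 0::2, 1::2] = b
    out[..., 1::2, 0::2] = c
    out[..., 1::2, 1::2] = d
    return out


# ---------------------------------------------------------------------------
# public numpy API


@dataclass
class SubBandSet:
    """The four half-resolution coefficient planes of one decomposition."""

    ll: np.ndarray
    lh: np.ndarray
    hl: np.ndarray
    hh: np.ndarray

    def __post_init__(self) -> None:
        shapes = {np.asarray(getattr(self, n)).shape for n in BAND_NAMES}
        if len(shapes) != 1:
            raise ValueError(f"sub-band planes have mismatched shapes: {sorted(shapes)}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.ll.shape

    def energy(self) -> float:
        return float(sum(np.sum(getattr(self, n) ** 2) for n in BAND_NAMES))

    def bands(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        return self.ll, self.lh, self.hl, self.hh


class FusedSubBandSet(SubBandSet):
    """Sub-bands after per-band convolutional fusion (same shape contract)."""


def dwt_decompose(x: np.ndarray) -> SubBandSet:
    """Single-level orthonormal Haar decomposition of a ``C x H x W`` grid.

    Raises
    ------
    ValueError
        If a spatial dimension is odd (the offending axis is named).
    """
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("input grid contains non-finite values")
    _check_even(x.shape)
    return SubBandSet(*_haar_split(x))


def idwt_reconstruct(s: SubBandSet) -> np.ndarray:
    """Exact inverse of :func:`dwt_decompose`."""
    return _haar_merge(*s.bands())


# ---------------------------------------------------------------------------
# differentiable ops (used inside the classifier forward pass)


def dwt_t(x: Tensor) -> tuple[Tensor, Tensor, Tensor, Tensor]:
    """Differentiable Haar decomposition of a ``(..., H, W)`` tensor."""
    _check_even(x.shape)
    planes = _haar_split(x.data)
    outs = []
    for i, plane in enumerate(planes):
        out = Tensor(plane, parents=(x,))

        def bwd(g: np.ndarray, i=i) -> None:
            # adjoint of band extraction = reconstruction from that band alone
            zeros = [np.zeros_like(g)] * 4
            zeros[i] = g
            x._accumulate(_haar_merge(*zeros))

        out._backward = bwd
        outs.append(out)
    return tuple(outs)


def idwt_t(ll: Tensor, lh: Tensor, hl: Tensor, hh: Tensor) -> Tensor:
    """Differentiable Haar reconstruction."""
    bands = (ll, lh, hl, hh)
    shapes = {b.shape for b in bands}
    if len(shapes) != 1:
        raise ValueError(f"sub-band planes have mismatched shapes: {sorted(shapes)}")
    out = Tensor(_haar_merge(*(b.data for b in bands)), parents=bands)

    def bwd(g: np.ndarray) -> None:
        grads = _haar_split(g)
        for band, gb in zip(bands, grads):
            if band.requires_grad:
                band._accumulate(gb)

    out._backward = bwd
    return out


def _pad2d(x: Tensor, p: int) -> Tensor:
    width = [(0, 0)] * (x.ndim - 2) + [(p, p), (p, p)]
    out = Tensor(np.pad(x.data, width), parents=(x,))
    out._backward = lambda g: x._accumulate(g[..., p:-p, p:-p])
    return out


def conv3x3(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padding 3x3 convolution on ``(B, C, H, W)`` input.

    ``w`` has shape ``(out, in, 3, 3)``; implemented as nine shifted
    matrix products so it stays inside the autodiff primitive set.
    """
    if x.shape[1] != w.shape[1]:
        raise ConfigurationError(
            f"channel mismatch: input has {x.shape[1]} channels, "
            f"kernel expects {w.shape[1]}"
        )
    bsz, _, h, wid = x.shape
    o = w.shape[0]
    xp = _pad2d(x, 1)
    out = None
    for ky in range(3):
        for kx in range(3):
            patch = xp[:, :, ky : ky + h, kx : kx + wid]          # (B, C, H, W)
            flat = patch.transpose(0, 2, 3, 1).reshape(bsz * h * wid, -1)
            wk = w[:, :, ky, kx].transpose(1, 0)                  # (C, O)
            term = flat @ wk
            out = term if out is None else out + term
    out = out.reshape(bsz, h, wid, o).transpose(0, 3, 1, 2)
    return out + b.reshape(1, o, 1, 1)


# ---------------------------------------------------------------------------
# fusion stacks


@dataclass
class FusionWeights:
    """Four independent spatial-size-preserving conv stacks, one per band.

    ``stacks[name]`` is a list of ``{"w": Tensor, "b": Tensor}`` layers.
    A nonlinearity is applied between layers; the final layer is linear.
    """

    stacks: dict = field(default_factory=dict)
    activation: str = "relu"

    @classmethod
    def random(
        cls,
        channels: int,
        depth: int = 4,
        hidden: int | None = None,
        activation: str = "relu",
        rng: np.random.Generator | None = None,
    ) -> "FusionWeights":
        if depth < 1:
            raise ConfigurationError("fusion depth must be >= 1")
        rng = rng or np.random.default_rng(0)
        hidden = hidden or channels
        stacks = {}
        for name in BAND_NAMES:
            layers = []
            cin = channels
            for li in range(depth):
                cout = channels if li == depth - 1 else hidden
                scale = np.sqrt(2.0 / (cin * 9))
                layers.append(
                    {
                        "w": parameter(rng.normal(0.0, scale, size=(cout, cin, 3, 3))),
                        "b": parameter(np.zeros(cout)),
                    }
                )
                cin = cout
            stacks[name] = layers
        return cls(stacks=stacks, activation=activation)

    @classmethod
    def identity(cls, channels: int, depth: int = 4) -> "FusionWeights":
        """Centre-tap-1 kernels, zero bias, linear activation: exact identity."""
        stacks = {}
        for name in BAND_NAMES:
            layers = []
            for _ in range(depth):
                w = np.zeros((channels, channels, 3, 3))
                for c in range(channels):
                    w[c, c, 1, 1] = 1.0
                layers.append({"w": parameter(w), "b": parameter(np.zeros(channels))})
            stacks[name] = layers
        return cls(stacks=stacks, activation="identity")

    def params(self) -> dict:
        return {
            name: {str(i): layer for i, layer in enumerate(layers)}
            for name, layers in self.stacks.items()
        }


def _apply_stack(x: Tensor, layers: list, activation: str) -> Tensor:
    for i, layer in enumerate(layers):
        x = conv3x3(x, layer["w"], layer["b"])
        if i < len(layers) - 1 and activation != "identity":
            x = x.relu() if activation == "relu" else x.gelu()
    return x


def fuse_subbands_t(
    bands: tuple[Tensor, Tensor, Tensor, Tensor], weights: FusionWeights
) -> tuple[Tensor, ...]:
    return tuple(
        _apply_stack(band, weights.stacks[name], weights.activation)
        for name, band in zip(BAND_NAMES, bands)
    )


def fuse_subbands(s: SubBandSet, weights: FusionWeights) -> FusedSubBandSet:
    """Numpy-facing fusion: each band through its own conv stack."""
    bands = tuple(Tensor(np.asarray(getattr(s, n))[None]) for n in BAND_NAMES)
    fused = fuse_subbands_t(bands, weights)
    return FusedSubBandSet(*(f.data[0] for f in fused))


def wefm_forward_t(x: Tensor, weights: FusionWeights) -> Tensor:
    """Differentiable decompose -> fuse -> reconstruct on ``(B, C, H, W)``."""
    bands = dwt_t(x)
    fused = fuse_subbands_t(bands, weights)
    return idwt_t(*fused)


def wefm_forward(x: np.ndarray, weights: FusionWeights) -> np.ndarray:
    """Decompose a ``C x H x W`` grid, fuse each band, reconstruct."""
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("input grid contains non-finite values")
    _check_even(x.shape)
    return wefm_forward_t(Tensor(x[None]), weights).data[0]
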