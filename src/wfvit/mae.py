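"""Masked-reconstruction pre-training for domain adaptation.

Random patches of each image are hidden and an encoder/decoder pair is
trained to regress the missing pixels; only the encoder survives and is
transplanted into the classifier.  Default mask ratio is 0.75.
"""

from __future__ import annotations

import csv
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .autodiff import AdamW, Tensor, concat, flatten_params, parameter
from .data import DataError
from .model import (
    Block,
    Encoder,
    LayerNorm,
    Linear,
    ModelConfig,
    load_checkpoint,
    patchify,
    save_checkpoint,
    unpatchify,
)


@dataclass
class MaskSpec:
    """Boolean patch mask; ``True`` marks a hidden patch."""

    mask: np.ndarray
    ratio: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        expected = int(np.floor(self.ratio * self.mask.size + 0.5))
        if int(self.mask.sum()) != expected:
            raise ValueError(
                f"mask cardinality {int(self.mask.sum())} != round(ratio*N) = {expected}"
            )

    @property
    def masked_idx(self) -> np.ndarray:
        return np.flatnonzero(self.mask)

    @property
    def visible_idx(self) -> np.ndarray:
        return np.flatnonzero(~self.mask)


def random_mask(n_patches: int, ratio: float, seed: int | np.random.Generator) -> MaskSpec:
    """Mask exactly ``round(ratio * n_patches)`` patches uniformly at random.

    Rounding is half-up so the count is reproducible across platforms.
    """
    if not 0.0 <= ratio <= 1.0:
        raise ValueError(f"mask ratio must lie in [0, 1], got {ratio}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = int(np.floor(ratio * n_patches + 0.5))
    mask = np.zeros(n_patches, dtype=bool)
    mask[rng.permutation(n_patches)[:k]] = True
    return MaskSpec(mask=mask, ratio=ratio)


def mae_loss(pred: np.ndarray, target: np.ndarray, mask: MaskSpec) -> float:
    """Mean squared error over masked patches only."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"pred shape {pred.shape} != target shape {target.shape}")
    if pred.shape[-2] != mask.mask.size:
        raise ValueError(
            f"patch axis {pred.shape[-2]} != mask length {mask.mask.size}"
        )
    idx = mask.masked_idx
    if idx.size == 0:
        return 0.0
    diff = pred[..., idx, :] - target[..., idx, :]
    return float(np.mean(diff ** 2))


@dataclass
class MAEConfig:
    decoder_dim: int = 32
    decoder_depth: int = 1
    decoder_heads: int = 4
    mask_ratio: float = 0.75
    norm_pix: bool = False
    lr: float = 1.5e-3
    weight_decay: float = 0.01
    batch_size: int = 16


class MAEPretrainer:
    """Encoder (shared geometry with the classifier) + shallow decoder."""

    def __init__(self, cfg: ModelConfig, mae_cfg: MAEConfig | None = None, seed: int = 0):
        self.cfg = cfg
        self.mae_cfg = mae_cfg or MAEConfig()
        rng = np.random.default_rng(seed)
        self.encoder = Encoder(cfg, rng)
        d, dd = cfg.embed_dim, self.mae_cfg.decoder_dim
        self.dec_embed = Linear(d, dd, rng)
        self.mask_token = parameter(rng.normal(0.0, 0.02, size=(1, 1, dd)))
        self.dec_pos = parameter(rng.normal(0.0, 0.02, size=(1, cfg.n_patches, dd)))
        self.dec_blocks = [
            Block(dd, self.mae_cfg.decoder_heads, cfg.mlp_ratio, rng)
            for _ in range(self.mae_cfg.decoder_depth)
        ]
        self.dec_norm = LayerNorm(dd)
        self.dec_out = Linear(dd, cfg.patch_dim, rng)

    def params(self) -> dict:
        return {
            "encoder": self.encoder.params(),
            "decoder": {
                "embed": self.dec_embed.params(),
                "mask_token": self.mask_token,
                "pos": self.dec_pos,
                "blocks": {str(i): b.params() for i, b in enumerate(self.dec_blocks)},
                "norm": self.dec_norm.params(),
                "out": self.dec_out.params(),
            },
        }

    def flat_params(self) -> dict[str, Tensor]:
        return flatten_params(self.params())

    # ------------------------------------------------------------- forward
    def forward(self, images: np.ndarray, mask: MaskSpec) -> tuple[Tensor, np.ndarray]:
        """Return (loss tensor, per-patch predictions) for a batch."""
        patches = patchify(Tensor(np.asarray(images, dtype=np.float64)),
                           self.cfg.patch_size).data
        target = patches
        if self.mae_cfg.norm_pix:
            mu = target.mean(axis=-1, keepdims=True)
            sd = target.std(axis=-1, keepdims=True) + 1e-6
            target = (target - mu) / sd
        vis, hid = mask.visible_idx, mask.masked_idx
        normed, _ = self.encoder.forward_tokens(Tensor(patches[:, vis, :]), visible=vis)
        dec_tok = self.dec_embed(normed[:, 1:, :])  # drop class token
        b = dec_tok.shape[0]
        mask_tok = self.mask_token + Tensor(np.zeros((b, hid.size, self.mae_cfg.decoder_dim)))
        seq = concat([dec_tok, mask_tok], axis=1)
        order = np.argsort(np.concatenate([vis, hid]))
        seq = seq[:, order, :] + self.dec_pos
        for blk in self.dec_blocks:
            seq = blk(seq)
        pred = self.dec_out(self.dec_norm(seq))
        diff = pred[:, hid, :] - Tensor(target[:, hid, :])
        loss = (diff * diff).mean() if hid.size else Tensor(0.0)
        return loss, pred.data

    def reconstruct(self, image: np.ndarray, seed: int = 0) -> dict[str, np.ndarray]:
        """Masked input / reconstruction / original triptych (one image)."""
        img = np.asarray(image, dtype=np.float64)
        if img.ndim == 2:
            img = img[None]
        mask = random_mask(self.cfg.n_patches, self.mae_cfg.mask_ratio, seed)
        _, pred = self.forward(img[None], mask)
        patches = patchify(Tensor(img[None]), self.cfg.patch_size).data
        masked_patches = patches.copy()
        masked_patches[:, mask.masked_idx, :] = 0.0
        recon_patches = patches.copy()
        recon_patches[:, mask.masked_idx, :] = pred[:, mask.masked_idx, :]
        p, c, s = self.cfg.patch_size, self.cfg.channels, self.cfg.image_size
        return {
            "masked": unpatchify(masked_patches, p, c, s)[0],
            "reconstruction": unpatchify(recon_patches, p, c, s)[0],
            "original": img,
        }

    def save(self, path: str | Path) -> None:
        meta = {"config": asdict(self.cfg), "mae_config": asdict(self.mae_cfg)}
        save_checkpoint(path, self.flat_params(), meta)

    @classmethod
    def load(cls, path: str | Path) -> "MAEPretrainer":
        arrays, meta = load_checkpoint(path)
        obj = cls(ModelConfig(**meta["config"]), MAEConfig(**meta["mae_config"]))
        flat = obj.flat_params()
        for name, arr in arrays.items():
            flat[name].data = arr.astype(np.float64)
        return obj


def pretrain(
    images: list[np.ndarray],
    cfg: ModelConfig,
    mae_cfg: MAEConfig | None = None,
    epochs: int = 5,
    seed: int = 0,
    log_path: str | Path | None = None,
) -> tuple[MAEPretrainer, list[float]]:
    """Train the masked-reconstruction network on healthy images.

    Returns the trained network and the per-epoch mean loss log.
    ``epochs=0`` returns the freshly initialized network untouched.
    """
    if len(images) == 0:
        raise DataError("pre-training dataset is empty")
    mae_cfg = mae_cfg or MAEConfig()
    trainer = MAEPretrainer(cfg, mae_cfg, seed=seed)
    opt = AdamW(trainer.flat_params(), lr=mae_cfg.lr, weight_decay=mae_cfg.weight_decay)
    rng = np.random.default_rng(seed)
    stack = np.stack([np.asarray(im, dtype=np.float64)[None] if np.asarray(im).ndim == 2
                      else np.asarray(im, dtype=np.float64) for im in images])
    losses: list[float] = []
    bs = mae_cfg.batch_size
    for _epoch in range(epochs):
        order = rng.permutation(len(stack))
        epoch_losses = []
        for start in range(0, len(stack), bs):
            batch = stack[order[start : start + bs]]
            mask = random_mask(cfg.n_patches, mae_cfg.mask_ratio, rng)
            loss, _ = trainer.forward(batch, mask)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        losses.append(float(np.mean(epoch_losses)))
    if log_path is not None:
        with open(log_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "loss"])
            for i, l in enumerate(losses):
                writer.writerow([i, l])
    return trainer, losses
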