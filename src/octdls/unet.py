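"""Convolutional encoder-decoder baseline (U-Net) for the same 3-class task.

A classic symmetric U-Net: repeated (3x3 conv, ReLU) x2 blocks with 2x2 max
pooling on the way down, nearest-neighbour upsampling plus skip-connection
concatenation on the way up, and a 1x1 convolution to class logits.  Inputs
are single-channel images rescaled to a square side and normalised to
[0, 1].  Training uses Adam with a per-update learning-rate decay
(lr_t = lr0 / (1 + d*t) with d = lr0 / epochs), cross-entropy loss, spatial
dropout (whole feature maps), and shift / horizontal-flip / rotation
augmentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import rotate, shift

from . import autodiff as ad
from .preprocess import IGNORE_LABEL

__all__ = ["UNetConfig", "UNet", "unet_train"]


@dataclass(frozen=True)
class UNetConfig:
    depth: int = 4
    base_filters: int = 32
    spatial_dropout_rate: float = 0.1
    input_size_px: int = 512
    n_classes: int = 3
    lr: float = 1e-4
    epochs: int = 64
    batch_size: int = 8
    rotation_deg: float = 10.0
    shift_frac: float = 0.05
    hflip_prob: float = 0.5
    augment: bool = True
    lesion_reweight: bool = False  # inverse-frequency pixel weights (off = plain CE)
    seed: int = 0

    def __post_init__(self):
        if self.input_size_px % (2**self.depth):
            raise ValueError("input size must be divisible by 2**depth")
        if not 0.0 <= self.spatial_dropout_rate < 1.0:
            raise ValueError("spatial dropout rate must lie in [0, 1)")

    @classmethod
    def desk(cls, **kw) -> "UNetConfig":
        kw.setdefault("input_size_px", 128)
        kw.setdefault("depth", 3)
        kw.setdefault("base_filters", 8)
        return cls(**kw)


def _he(rng: np.random.Generator, shape) -> np.ndarray:
    fan_in = int(np.prod(shape[1:]))
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class UNet:
    """Parameter container + forward pass; layout NCHW with 1 input channel."""

    def __init__(self, config: UNetConfig, seed: int = 0, dtype=np.float32):
        self.config = config
        self.training = False
        self.dtype = np.dtype(dtype)
        self._drop_rng = np.random.default_rng(seed + 7)
        rng = np.random.default_rng(seed)
        p: dict[str, ad.Tensor] = {}
        ch_in = 1
        enc_ch = []
        for lvl in range(config.depth + 1):  # last level is the bottleneck
            ch_out = config.base_filters * 2**lvl
            p[f"e{lvl}c1_w"] = ad.parameter(_he(rng, (ch_out, ch_in, 3, 3)))
            p[f"e{lvl}c1_b"] = ad.parameter(np.zeros(ch_out))
            p[f"e{lvl}c2_w"] = ad.parameter(_he(rng, (ch_out, ch_out, 3, 3)))
            p[f"e{lvl}c2_b"] = ad.parameter(np.zeros(ch_out))
            enc_ch.append(ch_out)
            ch_in = ch_out
        for lvl in reversed(range(config.depth)):
            ch_out = enc_ch[lvl]
            p[f"d{lvl}up_w"] = ad.parameter(_he(rng, (ch_out, ch_in, 3, 3)))
            p[f"d{lvl}up_b"] = ad.parameter(np.zeros(ch_out))
            p[f"d{lvl}c1_w"] = ad.parameter(_he(rng, (ch_out, 2 * ch_out, 3, 3)))
            p[f"d{lvl}c1_b"] = ad.parameter(np.zeros(ch_out))
            p[f"d{lvl}c2_w"] = ad.parameter(_he(rng, (ch_out, ch_out, 3, 3)))
            p[f"d{lvl}c2_b"] = ad.parameter(np.zeros(ch_out))
            ch_in = ch_out
        # zero-init head -> exactly uniform class probabilities at start
        p["head_w"] = ad.parameter(np.zeros((config.n_classes, ch_in, 1, 1)))
        p["head_b"] = ad.parameter(np.zeros(config.n_classes))
        self.params = {k: ad.parameter(v.data.astype(self.dtype)) for k, v in p.items()}

    def parameters(self) -> list[ad.Tensor]:
        return list(self.params.values())

    def _block(self, x: ad.Tensor, prefix: str) -> ad.Tensor:
        p = self.params
        x = ad.relu(ad.conv2d(x, p[f"{prefix}c1_w"], p[f"{prefix}c1_b"]))
        x = ad.relu(ad.conv2d(x, p[f"{prefix}c2_w"], p[f"{prefix}c2_b"]))
        return ad.spatial_dropout(
            x, self.config.spatial_dropout_rate, self._drop_rng, self.training
        )

    def forward_logits(self, images: np.ndarray) -> ad.Tensor:
        """(B, S, S) grayscale in [0, 1] -> (B, S, S, C) class logits."""
        images = np.asarray(images, dtype=self.dtype)
        if images.ndim == 2:
            images = images[None]
        s = self.config.input_size_px
        if images.shape[1:] != (s, s):
            raise ValueError(f"expected {s}x{s} input, got {images.shape[1:]}")
        x = ad.constant(images[:, None])  # (B, 1, S, S)
        skips = []
        for lvl in range(self.config.depth):
            x = self._block(x, f"e{lvl}")
            skips.append(x)
            x = ad.max_pool2(x)
        x = self._block(x, f"e{self.config.depth}")
        for lvl in reversed(range(self.config.depth)):
            x = ad.upsample2_nearest(x)
            x = ad.relu(ad.conv2d(x, self.params[f"d{lvl}up_w"], self.params[f"d{lvl}up_b"]))
            x = ad.concat_channels(skips[lvl], x)
            x = self._block(x, f"d{lvl}")
        logits = ad.conv2d(x, self.params["head_w"], self.params["head_b"], padding=0)
        return ad.transpose(logits, (0, 2, 3, 1))

    def forward_proba(self, images: np.ndarray) -> np.ndarray:
        """Per-pixel class probabilities; dropout is inactive outside training."""
        return ad.softmax(self.forward_logits(images)).data

    def predict_mask(self, image: np.ndarray) -> np.ndarray:
        return np.argmax(self.forward_proba(image[None])[0], axis=-1).astype(np.uint8)


def _augment_pair(
    image: np.ndarray, mask: np.ndarray, cfg: UNetConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    if rng.random() < cfg.hflip_prob:
        image, mask = image[:, ::-1], mask[:, ::-1]
    angle = rng.uniform(-cfg.rotation_deg, cfg.rotation_deg)
    if abs(angle) > 1e-3:
        image = rotate(image, angle, reshape=False, order=1, mode="constant")
        mask = rotate(mask, angle, reshape=False, order=0, mode="constant", cval=IGNORE_LABEL)
    dy, dx = rng.uniform(-cfg.shift_frac, cfg.shift_frac, size=2) * image.shape[0]
    if abs(dy) + abs(dx) > 0.5:
        image = shift(image, (dy, dx), order=1, mode="constant")
        mask = shift(mask, (dy, dx), order=0, mode="constant", cval=IGNORE_LABEL)
    return np.clip(image, 0.0, 1.0), mask


def unet_train(
    dataset: list[tuple[np.ndarray, np.ndarray]],
    config: UNetConfig,
) -> tuple[UNet, list[dict]]:
    """Train the baseline; deterministic given config.seed.

    `dataset` holds (grayscale image in [0, 1], mask) pairs at the configured
    square side.  Returns the model and a per-epoch log.
    """
    if not dataset:
        raise ValueError("empty training dataset")
    for _, m in dataset:
        bad = np.setdiff1d(np.unique(m), [0, 1, 2, IGNORE_LABEL])
        if bad.size:
            raise ValueError(f"mask labels outside alphabet: {bad.tolist()}")
    model = UNet(config, seed=config.seed)
    model.training = True
    rng = np.random.default_rng(config.seed + 1)
    opt = ad.Adam(model.parameters())
    decay = config.lr / config.epochs
    n, bs = len(dataset), config.batch_size
    log: list[dict] = []
    t = 0
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            imgs, msks = [], []
            for i in idx:
                im, mk = dataset[i]
                if config.augment:
                    im, mk = _augment_pair(im, mk, config, rng)
                imgs.append(im)
                msks.append(mk)
            batch_masks = np.stack(msks)
            weights = None
            if config.lesion_reweight:
                valid = batch_masks != IGNORE_LABEL
                freq = np.bincount(batch_masks[valid].ravel(), minlength=config.n_classes)
                inv = np.zeros(config.n_classes)
                inv[freq > 0] = 1.0 / np.sqrt(freq[freq > 0])
                weights = np.ones(batch_masks.shape)
                weights[valid] = inv[batch_masks[valid]]
            logits = model.forward_logits(np.stack(imgs))
            loss = ad.cross_entropy_logits(logits, batch_masks, IGNORE_LABEL, weights)
            opt.zero_grad()
            loss.backward()
            lr = config.lr / (1.0 + decay * t)
            opt.step(lr)
            t += 1
            losses.append(float(loss.data))
        log.append({"epoch": epoch, "loss": float(np.mean(losses)), "lr": config.lr / (1.0 + decay * t)})
    model.training = False
    return model, log
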