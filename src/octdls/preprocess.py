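"""B-scan conditioning: retina-centred cropping, channel triplication,
normalisation and training-time augmentation.

The training recipe crops each B-scan to half its axial extent so the retina
sits at the centre, triplicates the grayscale image into three identical
channels, normalises with mean 0.5 / std 0.5 per channel, and augments with
random resizing (ratio 0.5-2.0), random horizontal flipping, and random
cropping / padding to a fixed square input.  Padding on masks uses an
ignore label (255) that is excluded from the loss.  The deterministic
inference path is centre-crop then resize to the input size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

__all__ = [
    "IGNORE_LABEL",
    "PreprocessConfig",
    "center_crop_retina",
    "to_three_channel",
    "normalize",
    "denormalize",
    "augment",
    "prepare_inference",
]

IGNORE_LABEL = 255

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    crop_height_px: int = 768
    input_size_px: int = 512
    resize_ratio_range: tuple[float, float] = (0.5, 2.0)
    hflip_prob: float = 0.5
    normalize_mean: float = 0.5
    normalize_std: float = 0.5

    def __post_init__(self):
        if self.crop_height_px <= 0:
            raise ValueError("crop_height_px must be positive")
        if self.resize_ratio_range[0] > self.resize_ratio_range[1]:
            raise ValueError("resize ratio range must be ordered")
        if self.normalize_std <= 0:
            raise ValueError("normalize_std must be positive")
        if not 0.0 <= self.hflip_prob <= 1.0:
            raise ValueError("hflip_prob must lie in [0, 1]")

    @classmethod
    def desk(cls, **kw) -> "PreprocessConfig":
        kw.setdefault("crop_height_px", 128)
        kw.setdefault("input_size_px", 128)
        return cls(**kw)


def crop_window(bscan: np.ndarray, crop_height_px: int) -> tuple[int, int]:
    """Axial crop window [top, top+crop) centred on the brightest band.

    The centre is the intensity-weighted axial centroid of the rows whose
    smoothed mean brightness reaches half the profile maximum — on OCT the
    RPE band, so the retina lands mid-crop.  A featureless (all-equal) image
    falls back to the central window.
    """
    depth = bscan.shape[0]
    if crop_height_px > depth:
        raise ValueError(f"crop height {crop_height_px} exceeds image height {depth}")
    profile = bscan.mean(axis=1)
    from scipy.ndimage import gaussian_filter1d

    profile = gaussian_filter1d(profile.astype(np.float64), sigma=max(1.0, depth / 256))
    lo, hi = profile.min(), profile.max()
    if hi - lo <= 1e-12:
        logger.warning("featureless B-scan: falling back to central crop")
        center = depth / 2
    else:
        band = profile - lo
        band[band < 0.5 * (hi - lo)] = 0.0
        center = float((np.arange(depth) * band).sum() / band.sum())
    top = int(round(center - crop_height_px / 2))
    top = min(max(top, 0), depth - crop_height_px)
    return top, top + crop_height_px


def center_crop_retina(
    bscan: np.ndarray,
    crop_height_px: int,
    mask: np.ndarray | None = None,
):
    """Crop a B-scan (and optionally its aligned mask) around the retina.

    Returns ``(cropped, top)`` or ``(cropped, cropped_mask, top)``; ``top``
    is the first retained row, needed to map predictions back to native
    geometry.
    """
    top, bottom = crop_window(bscan, crop_height_px)
    if mask is None:
        return bscan[top:bottom], top
    if mask.shape != bscan.shape:
        raise ValueError("mask must match the B-scan shape")
    return bscan[top:bottom], mask[top:bottom], top


def to_three_channel(bscan: np.ndarray) -> np.ndarray:
    """Duplicate a single-channel image into three identical channels (H, W, 3)."""
    if bscan.ndim != 2:
        raise ValueError("expected a single-channel (H, W) image")
    return np.repeat(bscan[:, :, None], 3, axis=2)


def normalize(image3: np.ndarray, mean: float = 0.5, std: float = 0.5) -> np.ndarray:
    """(x - mean) / std per channel; [0, 1] input maps to [-1, 1] at defaults."""
    if std == 0:
        raise ValueError("std must be nonzero")
    return (np.asarray(image3, dtype=np.float64) - mean) / std


def denormalize(image3: np.ndarray, mean: float = 0.5, std: float = 0.5) -> np.ndarray:
    return np.asarray(image3, dtype=np.float64) * std + mean


def _resize_pair(image3: np.ndarray, mask: np.ndarray, out_hw: tuple[int, int]):
    img = resize(image3, out_hw + (image3.shape[2],), order=1, anti_aliasing=False,
                 preserve_range=True)
    msk = resize(mask, out_hw, order=0, anti_aliasing=False, preserve_range=True)
    return img, msk.astype(mask.dtype)


def augment(
    image3: np.ndarray,
    mask: np.ndarray,
    config: PreprocessConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Joint random resize / horizontal flip / crop-or-pad to the input size.

    The image is resampled bilinearly, the mask with nearest neighbour (so no
    new labels are invented); padded mask pixels get the ignore label.
    """
    if image3.shape[:2] != mask.shape:
        raise ValueError("image and mask must be aligned")
    size = config.input_size_px
    ratio = rng.uniform(*config.resize_ratio_range)
    h, w = image3.shape[:2]
    new_hw = (max(1, round(h * ratio)), max(1, round(w * ratio)))
    if new_hw != (h, w):
        image3, mask = _resize_pair(image3, mask, new_hw)
    if rng.random() < config.hflip_prob:
        image3 = image3[:, ::-1]
        mask = mask[:, ::-1]

    h, w = image3.shape[:2]
    # random crop along any axis that is too large
    top = int(rng.integers(0, h - size + 1)) if h > size else 0
    left = int(rng.integers(0, w - size + 1)) if w > size else 0
    image3 = image3[top : top + min(h, size), left : left + min(w, size)]
    mask = mask[top : top + min(h, size), left : left + min(w, size)]
    # symmetric zero-pad (ignore-label pad on the mask) along any short axis
    h, w = image3.shape[:2]
    if h < size or w < size:
        pt, pl = (size - h) // 2, (size - w) // 2
        pads = ((pt, size - h - pt), (pl, size - w - pl))
        image3 = np.pad(image3, pads + ((0, 0),))
        mask = np.pad(mask, pads, constant_values=IGNORE_LABEL)
    return np.ascontiguousarray(image3), np.ascontiguousarray(mask)


def prepare_inference(
    bscan: np.ndarray,
    config: PreprocessConfig,
) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Deterministic inference path: centre-crop, resize to the square input
    size, triplicate channels and normalise.

    Returns the model-ready image and ``(top, crop_h, crop_w)`` describing
    the native window the prediction corresponds to.
    """
    cropped, top = center_crop_retina(bscan, min(config.crop_height_px, bscan.shape[0]))
    ch, cw = cropped.shape
    size = config.input_size_px
    if (ch, cw) != (size, size):
        cropped = resize(cropped, (size, size), order=1, anti_aliasing=False,
                         preserve_range=True)
    img3 = normalize(to_three_channel(cropped), config.normalize_mean, config.normalize_std)
    return img3, (top, ch, cw)
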