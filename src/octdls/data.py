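"""Assembling segmentation training sets from phantom (or loaded) eyes.

A training pair is one preprocessed B-scan and its aligned mask.  B-scans
containing lesions are preferentially sampled (most B-scans in a volume are
lesion-free and teach the model nothing), with a configurable number of
background-only scans mixed in so the model also sees healthy anatomy.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize

from .phantom import EyeRecord, PhantomConfig, generate_cohort
from .preprocess import (
    PreprocessConfig,
    augment,
    center_crop_retina,
    normalize,
    to_three_channel,
)

__all__ = ["bscan_pairs", "easy_desk_cohort", "training_set_from_eyes"]


def bscan_pairs(
    eye: EyeRecord,
    pre_config: PreprocessConfig,
    rng: np.random.Generator,
    max_lesion_scans: int = 6,
    n_background_scans: int = 1,
    min_lesion_px: int = 30,
    use_augment: bool = False,
):
    """Sample preprocessed (image3, mask, gray) training pairs from one eye.

    `image3` is the normalised 3-channel input for the transformer, `gray`
    the [0, 1] single-channel version for the convolutional baseline; both
    share `mask`.
    """
    lesion_px = (eye.masks.labels > 0).sum(axis=(1, 2))
    lesion_idx = np.flatnonzero(lesion_px >= min_lesion_px)
    bg_idx = np.flatnonzero(lesion_px == 0)
    chosen = []
    if lesion_idx.size:
        take = min(max_lesion_scans, lesion_idx.size)
        chosen.extend(rng.choice(lesion_idx, size=take, replace=False))
    if bg_idx.size and n_background_scans:
        take = min(n_background_scans, bg_idx.size)
        chosen.extend(rng.choice(bg_idx, size=take, replace=False))

    size = pre_config.input_size_px
    pairs = []
    for b in sorted(int(i) for i in chosen):
        img = eye.volume.voxels[b].astype(np.float64)
        msk = eye.masks.labels[b]
        crop_h = min(pre_config.crop_height_px, img.shape[0])
        img, msk, _ = center_crop_retina(img, crop_h, msk)
        if img.shape != (size, size):
            img = resize(img, (size, size), order=1, anti_aliasing=False, preserve_range=True)
            msk = resize(msk, (size, size), order=0, anti_aliasing=False,
                         preserve_range=True).astype(msk.dtype)
        img3 = to_three_channel(np.clip(img, 0.0, 1.0))
        if use_augment:
            img3, msk = augment(img3, msk, pre_config, rng)
        gray = img3[:, :, 0].copy()
        img3 = normalize(img3, pre_config.normalize_mean, pre_config.normalize_std)
        pairs.append((img3, np.ascontiguousarray(msk), gray))
    return pairs


def easy_desk_cohort(n_mnv: int, n_control: int, seed: int) -> list[EyeRecord]:
    """High-contrast, speckle-free desk-scale phantom cohort."""
    cfg = PhantomConfig.desk(seed=seed, easy=True)
    return generate_cohort(n_mnv, n_control, config=cfg)


def training_set_from_eyes(
    eyes: list[EyeRecord],
    pre_config: PreprocessConfig,
    seed: int = 0,
    use_augment: bool = False,
    **kw,
):
    """Pooled (image3, mask) and (gray, mask) lists over a list of eyes."""
    rng = np.random.default_rng(seed)
    vit_set, unet_set = [], []
    for eye in eyes:
        for img3, msk, gray in bscan_pairs(eye, pre_config, rng, use_augment=use_augment, **kw):
            vit_set.append((img3, msk))
            unet_set.append((gray, msk))
    return vit_set, unet_set
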