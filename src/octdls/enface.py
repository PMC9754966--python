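"""Eye-level classification from en-face projections of prediction masks.

Per-B-scan prediction masks are collapsed along depth into an en-face label
map (B-scan index x A-scan index): a column is DLS if it contains any DLS
voxel, else drusen if it contains any drusen voxel, else background (DLS
takes precedence).  The map is rescaled to a small square (128 x 128 at
native scan geometry) by a majority-fraction block rule to suppress
single-pixel noise, the connected DLS blobs are extracted (8-connectivity
by default) and the eye is called MNV-positive when the largest blob
strictly exceeds a pixel threshold (65 at the 128 x 128 scale).  The
threshold itself comes from sweeping a labelled validation cohort and
taking the floor midpoint of the widest minimal-error interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .phantom import BScanVolume, LabelMaskVolume, BACKGROUND, DLS, DRUSEN

__all__ = [
    "EnFaceMap",
    "Blob",
    "BlobSet",
    "EyeClassification",
    "ThresholdSweepResult",
    "project_enface",
    "rescale_enface",
    "extract_blobs",
    "classify_eye",
    "threshold_sweep",
    "predict_mask_volume",
    "run_eye",
]


@dataclass
class EnFaceMap:
    """2-D label map over (B-scan index, A-scan index); values {0, 1, 2}."""

    grid: np.ndarray
    eye_id: str = ""
    model_id: str = ""

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ValueError("en-face grid must be 2-D")
        if not np.isin(self.grid, (BACKGROUND, DLS, DRUSEN)).all():
            raise ValueError("en-face values must be in {0, 1, 2}")


@dataclass(frozen=True)
class Blob:
    size_px: int
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col)


@dataclass
class BlobSet:
    blobs: list[Blob]
    connectivity: int = 8

    @property
    def largest(self) -> int:
        return max((b.size_px for b in self.blobs), default=0)


@dataclass
class EyeClassification:
    largest_dls_px: int
    threshold_px: int
    call: bool
    truth: bool | None = None
    eye_id: str = ""

    def __post_init__(self):
        if self.call != (self.largest_dls_px > self.threshold_px):
            raise ValueError("call must equal largest_dls_px > threshold_px")


@dataclass
class ThresholdSweepResult:
    thresholds: np.ndarray
    errors: np.ndarray
    minimal_interval: tuple[int, int]
    selected: int


def project_enface(masks: LabelMaskVolume | np.ndarray, eye_id: str = "", model_id: str = "") -> EnFaceMap:
    """Collapse a (B, depth, A) mask volume along depth, DLS taking precedence."""
    labels = masks.labels if isinstance(masks, LabelMaskVolume) else np.asarray(masks)
    if labels.ndim != 3:
        raise ValueError("mask volume must be 3-D (b-scan, depth, a-scan)")
    has_dls = (labels == DLS).any(axis=1)
    has_drusen = (labels == DRUSEN).any(axis=1)
    grid = np.where(has_dls, DLS, np.where(has_drusen, DRUSEN, BACKGROUND)).astype(np.uint8)
    return EnFaceMap(grid, eye_id=eye_id, model_id=model_id)


def _area_fraction_downsample(indicator: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Exact mean of a binary map over each (possibly fractional) target block.

    Source pixels are unit squares; target pixel (i, j) covers the axis-
    aligned block [i*H/out_h, (i+1)*H/out_h) x [j*W/out_w, (j+1)*W/out_w).
    Implemented with linearly interpolated cumulative sums, which is exact
    for piecewise-constant densities.
    """

    def reduce_axis(arr: np.ndarray, n_out: int) -> np.ndarray:
        n_in = arr.shape[0]
        cum = np.concatenate([np.zeros((1,) + arr.shape[1:]), np.cumsum(arr, axis=0)])
        edges = np.arange(n_out + 1) * (n_in / n_out)
        i0 = np.clip(edges.astype(int), 0, n_in)
        frac = edges - i0
        vals = cum[i0] + frac.reshape(-1, *([1] * (arr.ndim - 1))) * (
            cum[np.minimum(i0 + 1, n_in)] - cum[i0]
        )
        return (vals[1:] - vals[:-1]) / (n_in / n_out)

    return reduce_axis(reduce_axis(indicator.astype(np.float64), out_h).T, out_w).T


def rescale_enface(emap: EnFaceMap, side: int = 128, method: str = "majority") -> EnFaceMap:
    """Downsample an en-face map to side x side.

    ``majority`` (default): a target pixel is DLS if the DLS area fraction of
    its source block is >= 0.5, else drusen by the same rule, else
    background — this is the noise-suppressing semantics the 128 x 128
    rescale exists for.  ``nearest`` is available for comparison.
    """
    if side < 1:
        raise ValueError("side must be >= 1")
    h, w = emap.grid.shape
    if side > h or side > w:
        raise ValueError(f"cannot upscale en-face map {h}x{w} to {side}x{side}")
    if (h, w) == (side, side):
        return EnFaceMap(emap.grid.copy(), emap.eye_id, emap.model_id)
    if method == "nearest":
        rows = (np.arange(side) + 0.5) * h / side
        cols = (np.arange(side) + 0.5) * w / side
        grid = emap.grid[rows.astype(int)][:, cols.astype(int)]
        return EnFaceMap(grid.copy(), emap.eye_id, emap.model_id)
    if method != "majority":
        raise ValueError(f"unknown rescale method {method!r}")
    f_dls = _area_fraction_downsample(emap.grid == DLS, side, side)
    f_dru = _area_fraction_downsample(emap.grid == DRUSEN, side, side)
    grid = np.where(f_dls >= 0.5, DLS, np.where(f_dru >= 0.5, DRUSEN, BACKGROUND))
    return EnFaceMap(grid.astype(np.uint8), emap.eye_id, emap.model_id)


def extract_blobs(emap: EnFaceMap, connectivity: int = 8) -> BlobSet:
    """Connected components of the DLS class (8-connectivity by default)."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    lab = cc_label(emap.grid == DLS, connectivity=2 if connectivity == 8 else 1)
    blobs = [Blob(size_px=int(r.area), bbox=tuple(r.bbox)) for r in regionprops(lab)]
    return BlobSet(blobs=blobs, connectivity=connectivity)


def classify_eye(
    blobs: BlobSet,
    threshold_px: int = 65,
    truth: bool | None = None,
    eye_id: str = "",
) -> EyeClassification:
    """MNV-positive iff the largest DLS blob strictly exceeds the threshold."""
    if threshold_px < 0:
        raise ValueError("threshold must be nonnegative")
    largest = blobs.largest
    return EyeClassification(
        largest_dls_px=largest,
        threshold_px=threshold_px,
        call=largest > threshold_px,
        truth=truth,
        eye_id=eye_id,
    )


def threshold_sweep(
    scores: np.ndarray,
    truth: np.ndarray,
    thresholds: np.ndarray | range | None = None,
) -> ThresholdSweepResult:
    """Select the classification threshold from a labelled validation cohort.

    `scores` are largest-blob sizes, `truth` the eye labels.  For every
    integer threshold t the misclassification count of the rule
    ``score > t`` is computed; the selected threshold is the floor midpoint
    of the widest contiguous run of minimal error.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if scores.shape != truth.shape or scores.ndim != 1:
        raise ValueError("scores and truth must be equal-length 1-D arrays")
    if truth.all() or not truth.any():
        raise ValueError("sweep needs at least one positive and one negative eye")
    if thresholds is None:
        thresholds = np.arange(0, int(scores.max()) + 2)
    thresholds = np.asarray(list(thresholds), dtype=int)
    if thresholds.size == 0:
        raise ValueError("empty threshold range")
    calls = scores[None, :] > thresholds[:, None]
    errors = (calls != truth[None, :]).sum(axis=1)
    emin = errors.min()
    best_lo = best_hi = None
    lo = None
    for i, e in enumerate(errors):
        if e == emin and lo is None:
            lo = i
        if (e != emin or i == len(errors) - 1) and lo is not None:
            hi = i if e == emin else i - 1
            if best_lo is None or (hi - lo) > (best_hi - best_lo):
                best_lo, best_hi = lo, hi
            lo = None
    interval = (int(thresholds[best_lo]), int(thresholds[best_hi]))
    selected = (interval[0] + interval[1]) // 2
    return ThresholdSweepResult(
        thresholds=thresholds, errors=errors, minimal_interval=interval, selected=selected
    )


def predict_mask_volume(volume: BScanVolume, model, pre_config) -> LabelMaskVolume:
    """Run the segmenter over every B-scan, mapping predictions back to native
    geometry (nearest-neighbour inverse of the inference resize, background
    outside the crop window)."""
    from .preprocess import prepare_inference

    nb, depth, na = volume.shape
    out = np.zeros((nb, depth, na), dtype=np.uint8)
    size = pre_config.input_size_px
    for b in range(nb):
        img3, (top, ch, cw) = prepare_inference(volume.voxels[b].astype(np.float64), pre_config)
        pred = model.predict_mask(img3)
        if (ch, cw) != (size, size):
            rows = ((np.arange(ch) + 0.5) * size / ch).astype(int)
            cols = ((np.arange(cw) + 0.5) * size / cw).astype(int)
            pred = pred[rows][:, cols]
        out[b, top : top + ch, :] = pred
    return LabelMaskVolume(out)


def run_eye(
    volume: BScanVolume,
    model,
    pre_config,
    enface_side: int = 128,
    threshold_px: int = 65,
    connectivity: int = 8,
    truth: bool | None = None,
    intermediates: dict | None = None,
) -> EyeClassification:
    """Full pipeline for one eye: segment every B-scan, project en face,
    rescale, extract DLS blobs and classify.

    Pass a dict as `intermediates` to capture the per-stage products
    (prediction volume, native and rescaled en-face maps, blob set).
    """
    try:
        pred = predict_mask_volume(volume, model, pre_config)
        native = project_enface(pred, eye_id=volume.eye_id)
        rescaled = rescale_enface(native, side=enface_side)
        blobs = extract_blobs(rescaled, connectivity=connectivity)
        result = classify_eye(blobs, threshold_px=threshold_px, truth=truth, eye_id=volume.eye_id)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed for eye {volume.eye_id!r}: {exc}") from exc
    if intermediates is not None:
        intermediates.update(
            {"pred_masks": pred, "enface_native": native, "enface_rescaled": rescaled, "blobs": blobs}
        )
    return result
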