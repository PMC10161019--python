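"""Whole-volume inference and segmentation metrics.

Inference mirrors training: each axial slice of the liver ROI crop is resized
to the network input size, passed through the net, and the probability map is
resized back onto the volume grid; probabilities are thresholded at 0.5 and
zeroed outside the liver mask.

Metrics are the Dice similarity coefficient DSC = 2|A∩B| / (|A| + |B|),
sensitivity tp/(tp+fn) and specificity tn/(tn+fp), with the confusion counts
restricted to an explicit evaluation region — by default the liver ROI
bounding box. Specificity over a whole CT volume saturates near 1 because
almost every voxel is background; restricting the count to the ROI keeps the
number informative, and the region used is recorded in the report.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from skimage.transform import resize as _sk_resize

from .io_volumes import BinaryMask3D, Volume3D, crop, liver_roi_box
from .patches import normalize_patch, resize_patch
from .resdense_unet import UNet

__all__ = [
    "SegMetrics",
    "predict_volume",
    "dsc",
    "sensitivity",
    "specificity",
    "evaluate",
]


@dataclasses.dataclass
class SegMetrics:
    tp: int
    fp: int
    fn: int
    tn: int
    dsc: float
    sensitivity: float
    specificity: float
    region: str = "liver ROI bounding box"
    empty_denominator: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def predict_volume(
    model: UNet,
    vol: Volume3D,
    liver_mask: BinaryMask3D,
    threshold: float = 0.5,
    margin_vox: int = 8,
    already_cropped: bool = False,
    normalize: bool = True,
    batch_size: int = 16,
    mode: str = "resize",
) -> BinaryMask3D:
    """Slice-wise segmentation of a volume, restricted to the liver ROI.

    ``vol`` must have been produced by the same enhancement pipeline used in
    training. With ``already_cropped`` the volume is treated as the ROI crop
    itself (the liver mask then shares its grid).

    ``mode="resize"`` (default) resizes each slice's liver bounding box to
    the network input, z-scores it like a training patch, and resizes the
    probabilities back. ``mode="tiled"`` instead covers the bounding box
    with native-resolution, half-overlapping tiles and averages the
    probabilities where tiles overlap; with small networks the reduced
    spatial context per tile usually loses more than the avoided resampling
    gains.
    """
    if mode not in ("tiled", "resize"):
        raise ValueError(f"unknown inference mode {mode!r}")
    size = model.config.input_size
    if already_cropped:
        roi_vol, roi_mask = vol, liver_mask
        box = None
    else:
        box = liver_roi_box(liver_mask, margin_vox)
        roi_vol = crop(vol, box)
        roi_mask = crop(liver_mask, box)

    nz, ny, nx = roi_vol.data.shape
    probs = np.zeros((nz, ny, nx), dtype=np.float32)
    weight = np.zeros((nz, ny, nx), dtype=np.float32)
    # per-slice liver bounding boxes: inference sees the same distribution
    # the sampler produced (crops inside the slice's liver region, z-scored)
    jobs = []
    for k in range(nz):
        rows, cols = np.nonzero(roi_mask.data[k])
        if rows.size == 0:
            continue
        r0, r1 = int(rows.min()), int(rows.max()) + 1
        c0, c1 = int(cols.min()), int(cols.max()) + 1
        if mode == "resize":
            patch = roi_vol.data[k, r0:r1, c0:c1].astype(np.float32)
            patch = resize_patch(patch, size, "linear")
            if normalize:
                patch = normalize_patch(patch)
            jobs.append((k, r0, r1, c0, c1, patch))
            continue
        # tile origins with stride size/2, clamped so tiles stay inside the
        # padded bbox (the bbox is grown to the tile size when smaller)
        def starts(lo, hi, n_total):
            ext = hi - lo
            if ext <= size:
                s = max(0, min(lo, n_total - size))
                return [s]
            out, s = [], lo
            while True:
                s = min(s, n_total - size, hi - size)
                out.append(s)
                if s + size >= hi:
                    return sorted(set(out))
                s += size // 2
        for ti in starts(r0, r1, ny):
            for tj in starts(c0, c1, nx):
                patch = roi_vol.data[k, ti : ti + size, tj : tj + size].astype(np.float32)
                if normalize:
                    patch = normalize_patch(patch)
                jobs.append((k, ti, ti + size, tj, tj + size, patch))
    for i in range(0, len(jobs), batch_size):
        chunk = jobs[i : i + batch_size]
        stack = np.stack([j[-1] for j in chunk])[:, None]
        out = model.forward(stack, train=False)
        for (k, r0, r1, c0, c1, _), prob in zip(chunk, out[:, 0]):
            if mode == "resize":
                probs[k, r0:r1, c0:c1] = _sk_resize(
                    prob, (r1 - r0, c1 - c0), order=1, mode="edge",
                    anti_aliasing=False, preserve_range=True)
                weight[k, r0:r1, c0:c1] = 1.0
            else:
                probs[k, r0:r1, c0:c1] += prob
                weight[k, r0:r1, c0:c1] += 1.0
    np.divide(probs, weight, out=probs, where=weight > 0)
    pred = (probs > threshold).astype(np.uint8)
    pred *= roi_mask.data

    if already_cropped:
        return BinaryMask3D(pred, roi_vol.spacing, roi_vol.affine)
    full = np.zeros(vol.data.shape, dtype=np.uint8)
    full[box.slices()] = pred
    return BinaryMask3D(full, vol.spacing, vol.affine)


def _counts(pred: np.ndarray, truth: np.ndarray, region: np.ndarray):
    p = pred.astype(bool) & region
    t = truth.astype(bool) & region
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t & region))
    tn = int(np.count_nonzero(~p & ~t & region))
    return tp, fp, fn, tn


def dsc(a: BinaryMask3D | np.ndarray, b: BinaryMask3D | np.ndarray) -> float:
    """Dice similarity 2|A∩B|/(|A|+|B|); 1.0 when both masks are empty."""
    a = (a.data if isinstance(a, BinaryMask3D) else np.asarray(a)).astype(bool)
    b = (b.data if isinstance(b, BinaryMask3D) else np.asarray(b)).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.count_nonzero(a & b)) / denom


def sensitivity(pred, truth) -> float:
    """tp / (tp + fn); 1.0 when the truth has no foreground."""
    pred = (pred.data if isinstance(pred, BinaryMask3D) else np.asarray(pred)).astype(bool)
    truth = (truth.data if isinstance(truth, BinaryMask3D) else np.asarray(truth)).astype(bool)
    tp = int(np.count_nonzero(pred & truth))
    denom = int(truth.sum())
    return 1.0 if denom == 0 else tp / denom


def specificity(pred, truth, region=None) -> float:
    """tn / (tn + fp) inside ``region`` (everything, when omitted)."""
    pred = (pred.data if isinstance(pred, BinaryMask3D) else np.asarray(pred)).astype(bool)
    truth = (truth.data if isinstance(truth, BinaryMask3D) else np.asarray(truth)).astype(bool)
    if region is None:
        region = np.ones(pred.shape, dtype=bool)
    else:
        region = (region.data if isinstance(region, BinaryMask3D) else np.asarray(region)).astype(bool)
    tn = int(np.count_nonzero(~pred & ~truth & region))
    fp = int(np.count_nonzero(pred & ~truth & region))
    return 1.0 if tn + fp == 0 else tn / (tn + fp)


def evaluate(
    pred: BinaryMask3D,
    truth: BinaryMask3D,
    region: BinaryMask3D | np.ndarray | None = None,
    liver_mask: BinaryMask3D | None = None,
    margin_vox: int = 8,
) -> SegMetrics:
    """Confusion counts and metrics within an explicit evaluation region.

    When ``region`` is omitted it defaults to the bounding box of
    ``liver_mask`` (dilated by ``margin_vox``), or the whole volume if no
    liver mask is given either.
    """
    p = pred.data.astype(bool)
    t = truth.data.astype(bool)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    if region is not None:
        r = (region.data if isinstance(region, BinaryMask3D) else np.asarray(region)).astype(bool)
        region_name = "user-supplied region"
    elif liver_mask is not None:
        box = liver_roi_box(liver_mask, margin_vox)
        r = np.zeros(p.shape, dtype=bool)
        r[box.slices()] = True
        region_name = f"liver ROI bounding box (margin {margin_vox})"
    else:
        r = np.ones(p.shape, dtype=bool)
        region_name = "whole volume"

    tp, fp, fn, tn = _counts(p, t, r)
    empty = False
    d = 1.0 if (2 * tp + fp + fn) == 0 else 2 * tp / (2 * tp + fp + fn)
    if tp + fn == 0:
        sens, empty = 1.0, True
    else:
        sens = tp / (tp + fn)
    if tn + fp == 0:
        spec, empty = 1.0, True
    else:
        spec = tn / (tn + fp)
    return SegMetrics(tp, fp, fn, tn, d, sens, spec, region_name, empty)
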