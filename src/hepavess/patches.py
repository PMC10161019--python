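"""Vessel-biased training-patch extraction.

Whole CT slices are overwhelmingly background, so training on full slices
biases the network toward predicting "no vessel". The sampler counteracts
that: it draws square crops of varying size, only from axial slices that
contain vessels, only inside the liver ROI, and rejects crops without a
single annotated vessel voxel. Crops are resized to the network input size
and z-scored per patch (zero mean, unit variance).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage.transform import resize as _sk_resize

from .io_volumes import BinaryMask3D, Volume3D

__all__ = [
    "PatchItem",
    "PatchSet",
    "eligible_slices",
    "sample_patches",
    "resize_patch",
    "normalize_patch",
    "split_by_volume",
    "save_patchset",
    "load_patchset",
]


@dataclasses.dataclass
class PatchItem:
    image: np.ndarray  # (H, W) float32, normalized unless stated otherwise
    mask: np.ndarray  # (H, W) uint8 in {0, 1}
    provenance: dict  # volume id, slice index, crop box, original size


@dataclasses.dataclass
class PatchSet:
    items: list[PatchItem]
    target_size: int = 256
    rng_seed: int = 0

    def __len__(self) -> int:
        return len(self.items)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Stack into (N, 1, H, W) image and mask arrays for training."""
        x = np.stack([it.image for it in self.items])[:, None].astype(np.float32)
        y = np.stack([it.mask for it in self.items])[:, None].astype(np.float32)
        return x, y

    def extend(self, other: "PatchSet") -> None:
        if other.target_size != self.target_size:
            raise ValueError("cannot merge PatchSets with different target sizes")
        self.items.extend(other.items)


def eligible_slices(vessel_mask: BinaryMask3D, liver_mask: BinaryMask3D) -> list[int]:
    """Axial (first-axis) slice indices where vessels are present inside the liver."""
    if vessel_mask.data.shape != liver_mask.data.shape:
        raise ValueError(
            f"mask shapes differ: {vessel_mask.data.shape} vs {liver_mask.data.shape}"
        )
    joint = (vessel_mask.data.astype(bool) & liver_mask.data.astype(bool))
    return [int(i) for i in np.nonzero(joint.any(axis=(1, 2)))[0]]


def resize_patch(patch: np.ndarray, target: int, interp: str = "linear") -> np.ndarray:
    """Resize a 2-D patch to ``target x target``; ``nearest`` keeps masks binary."""
    if target <= 0:
        raise ValueError("target must be positive")
    patch = np.asarray(patch)
    if patch.shape == (target, target):
        return patch.copy()
    order = 0 if interp == "nearest" else 1
    out = _sk_resize(
        patch.astype(np.float32),
        (target, target),
        order=order,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    if interp == "nearest":
        return (out > 0.5).astype(patch.dtype) if patch.dtype == np.uint8 else out
    return out.astype(np.float32)


def normalize_patch(patch: np.ndarray) -> np.ndarray:
    """Zero-mean unit-variance; a constant patch maps to all zeros."""
    patch = np.asarray(patch, dtype=np.float64)
    std = patch.std()
    if std == 0:
        return np.zeros_like(patch, dtype=np.float32)
    return ((patch - patch.mean()) / std).astype(np.float32)


def _slice_roi_bbox(liver_slice: np.ndarray) -> tuple[int, int, int, int] | None:
    idx = np.nonzero(liver_slice)
    if idx[0].size == 0:
        return None
    return int(idx[0].min()), int(idx[0].max()) + 1, int(idx[1].min()), int(idx[1].max()) + 1


def sample_patches(
    enhanced: Volume3D,
    vessel_mask: BinaryMask3D,
    liver_mask: BinaryMask3D,
    n: int,
    size_range: tuple[int, int] = (96, 384),
    seed: int = 0,
    target_size: int = 256,
    volume_id: str = "vol",
    normalize: bool = True,
) -> PatchSet:
    """Draw ``n`` vessel-containing square crops and resize them to
    ``target_size``.

    Slices are drawn uniformly from the eligible set, the square side
    uniformly from ``size_range`` (clipped to the slice's liver bounding box),
    and the position uniformly over placements inside that box. Crops without
    a vessel voxel are rejected and redrawn; if rejection stalls, the crop is
    re-centered on a random vessel voxel so the postcondition always holds.
    Fully reproducible for a given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    elig = eligible_slices(vessel_mask, liver_mask)
    if not elig:
        raise ValueError("no eligible slices: vessel mask empty inside liver")
    rng = np.random.default_rng(seed)
    smin, smax = int(size_range[0]), int(size_range[1])
    if smin < 2 or smin > smax:
        raise ValueError(f"bad size_range {size_range}")

    items: list[PatchItem] = []
    while len(items) < n:
        k = int(rng.choice(elig))
        img2 = enhanced.data[k]
        ves2 = vessel_mask.data[k]
        liv2 = liver_mask.data[k]
        bbox = _slice_roi_bbox(liv2)
        if bbox is None:
            continue
        r0, r1, c0, c1 = bbox
        side = int(rng.integers(smin, smax + 1))
        side = min(side, r1 - r0, c1 - c0)
        if side < 2:
            continue
        placed = False
        for attempt in range(60):
            if attempt < 50:
                i = int(rng.integers(r0, r1 - side + 1))
                j = int(rng.integers(c0, c1 - side + 1))
            else:  # recenter on a vessel voxel inside the box
                vi, vj = np.nonzero(ves2[r0:r1, c0:c1])
                if vi.size == 0:
                    break
                pick = int(rng.integers(vi.size))
                i = int(np.clip(vi[pick] + r0 - side // 2, r0, r1 - side))
                j = int(np.clip(vj[pick] + c0 - side // 2, c0, c1 - side))
            m = ves2[i : i + side, j : j + side]
            if m.any():
                placed = True
                break
        if not placed:
            continue
        img = resize_patch(img2[i : i + side, j : j + side].astype(np.float32),
                           target_size, "linear")
        msk = resize_patch(m.astype(np.uint8), target_size, "nearest")
        if not msk.any():  # nearest downsampling can drop a 1-voxel vessel
            continue
        if normalize:
            img = normalize_patch(img)
        items.append(
            PatchItem(
                image=img.astype(np.float32),
                mask=msk.astype(np.uint8),
                provenance={
                    "volume_id": volume_id,
                    "slice": k,
                    "box": [i, j, i + side, j + side],
                    "original_size": side,
                },
            )
        )
    return PatchSet(items, target_size=target_size, rng_seed=seed)


def split_by_volume(
    volume_ids: Sequence[str], seed: int = 0, fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
) -> dict[str, list[str]]:
    """Shuffle volume ids and split into train/val/test groups by volume, so
    no volume contributes patches to more than one split."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    ids = list(volume_ids)
    rng = np.random.default_rng(seed)
    rng.shuffle(ids)
    n = len(ids)
    n_train = max(1, int(round(fractions[0] * n))) if n > 2 else max(1, n - 2)
    n_val = max(1, int(round(fractions[1] * n))) if n - n_train >= 2 else max(0, n - n_train - 1)
    n_train = min(n_train, n - min(2, n - 1))
    train = ids[:n_train]
    val = ids[n_train : n_train + max(1, n_val)] if n > 1 else []
    test = ids[n_train + len(val) :]
    return {"train": train, "val": val, "test": test}


def save_patchset(ps: PatchSet, directory: str | Path) -> None:
    """Serialize to ``patches.npz`` plus ``patchset.json`` with provenance."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    x, y = ps.arrays()
    np.savez_compressed(directory / "patches.npz", images=x, masks=y)
    manifest = {
        "target_size": ps.target_size,
        "rng_seed": ps.rng_seed,
        "n": len(ps),
        "items": [it.provenance for it in ps.items],
    }
    (directory / "patchset.json").write_text(json.dumps(manifest, indent=2))


def load_patchset(directory: str | Path) -> PatchSet:
    directory = Path(directory)
    manifest = json.loads((directory / "patchset.json").read_text())
    arr = np.load(directory / "patches.npz")
    items = [
        PatchItem(image=img[0], mask=msk[0].astype(np.uint8), provenance=prov)
        for img, msk, prov in zip(arr["images"], arr["masks"], manifest["items"])
    ]
    return PatchSet(items, target_size=manifest["target_size"], rng_seed=manifest["rng_seed"])
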