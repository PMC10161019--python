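"""Canned phantom experiments.

These functions bundle the pipeline into the two desk-scale studies the test
suite and the reproduction script run:

* :func:`enhancement_ablation` — trains the same small network on enhanced
  versus raw input over several seeded phantoms and compares held-out DSC,
  the phantom-scale analogue of the with/without-enhancement comparison.
* :func:`end_to_end_segmentation` — the full pipeline (phantoms ->
  enhancement -> patches -> training -> volume inference -> metrics) on a
  small phantom set.

Problem sizes (96^3 phantoms, 2-3 level 8-channel networks, 64x64 patches) are
chosen so each study runs in minutes on a single CPU while preserving the
statistical structure the method assumes: tubular foreground, matched-contrast
blob/plate distractors, Gaussian noise, heavy class imbalance.
"""

from __future__ import annotations

import numpy as np

from .ced import CEDParams, enhance
from .frangi import VesselnessParams
from .io_volumes import crop
from .patches import PatchSet, sample_patches
from .phantom import PhantomSpec, make_phantom
from .predictor_metrics import evaluate, predict_volume
from .resdense_unet import NetworkConfig, build_unet
from .trainer import TrainConfig, train

__all__ = ["enhancement_ablation", "end_to_end_segmentation"]


def _prepared_case(seed: int, vp=None, cp=None, skip_vesselness: bool = False,
                   skip_ced: bool = False, margin: int = 8):
    """Phantom -> (input ROI volume, liver ROI mask, vessel ROI mask).

    With both skip flags the input is the raw cropped CT, so both ablation
    arms train and evaluate on identically shaped inputs.
    """
    vol, liver, vessels = make_phantom(PhantomSpec(seed=seed))
    out, box = enhance(vol, liver, vp, cp, margin_vox=margin,
                       skip_vesselness=skip_vesselness, skip_ced=skip_ced)
    return out, crop(liver, box), crop(vessels, box)


def _patchify(case, n, seed, target=64, size_range=(32, 80), volume_id="vol"):
    enhanced, liver_roi, vessels_roi = case
    return sample_patches(enhanced, vessels_roi, liver_roi, n=n,
                          size_range=size_range, seed=seed, target_size=target,
                          volume_id=volume_id)


def enhancement_ablation(
    n_replicates: int = 5,
    seed: int = 17,
    n_train_patches: int = 200,
    n_val_patches: int = 50,
    max_epochs: int = 12,
    lr: float = 2e-3,
    base_channels: int = 8,
    vessel_params: VesselnessParams | None = None,
    ced_params: CEDParams | None = None,
) -> dict:
    """Train the same 2-level network on enhanced vs raw phantoms.

    Each replicate trains on patches from its own phantom; all replicates
    share one validation phantom (plateau/early-stop monitoring) and one test
    phantom (held-out DSC), each kept volume-disjoint from training. Both
    arms see identical phantoms, patch boxes, network init and schedule —
    only the input representation differs.

    Returns per-replicate and mean DSC for both arms.
    """
    results: dict = {"enhanced": [], "raw": [], "seed": seed}
    for arm in ("enhanced", "raw"):
        skip = arm == "raw"
        val_case = _prepared_case(seed + 900, vessel_params, ced_params, skip, skip)
        test_case = _prepared_case(seed + 901, vessel_params, ced_params, skip, skip)
        val_set = _patchify(val_case, n_val_patches, seed + 70, volume_id="val")
        for r in range(n_replicates):
            train_case = _prepared_case(seed + r, vessel_params, ced_params,
                                        skip, skip)
            train_set = _patchify(train_case, n_train_patches, seed + 80 + r,
                                  volume_id=f"train{r}")
            cfg = NetworkConfig(levels=2, base_channels=base_channels, input_size=64)
            model = build_unet(cfg, seed=seed)
            model, _ = train(model, train_set, val_set,
                             TrainConfig(max_epochs=max_epochs, lr_init=lr,
                                         seed=seed))
            pred = predict_volume(model, test_case[0], test_case[1],
                                  already_cropped=True)
            m = evaluate(pred, test_case[2],
                         region=np.ones(pred.data.shape, dtype=bool))
            results[arm].append(m.dsc)
    results["mean_enhanced"] = float(np.mean(results["enhanced"]))
    results["mean_raw"] = float(np.mean(results["raw"]))
    return results


def end_to_end_segmentation(
    seed: int = 17,
    n_train_volumes: int = 3,
    patches_per_volume: int = 250,
    max_epochs: int = 25,
    lr: float = 2e-3,
    levels: int = 3,
    base_channels: int = 8,
    skip_vesselness: bool = False,
    skip_ced: bool = False,
) -> dict:
    """Full pipeline on a phantom set; returns held-out metrics.

    ``n_train_volumes`` phantoms feed the training patches, one further
    phantom provides validation patches and one more is the held-out test
    volume (split by volume throughout).
    """
    train_set: PatchSet | None = None
    for i in range(n_train_volumes):
        case = _prepared_case(seed + i, None, None, skip_vesselness, skip_ced)
        ps = _patchify(case, patches_per_volume, seed + 80 + i,
                       volume_id=f"train{i}")
        train_set = ps if train_set is None else (train_set.extend(ps) or train_set)
    val_case = _prepared_case(seed + 900, None, None, skip_vesselness, skip_ced)
    test_case = _prepared_case(seed + 901, None, None, skip_vesselness, skip_ced)
    val_set = _patchify(val_case, max(30, patches_per_volume // 3), seed + 70,
                        volume_id="val")

    cfg = NetworkConfig(levels=levels, base_channels=base_channels, input_size=64)
    model = build_unet(cfg, seed=seed)
    model, history = train(model, train_set, val_set,
                           TrainConfig(max_epochs=max_epochs, lr_init=lr,
                                       seed=seed))
    pred = predict_volume(model, test_case[0], test_case[1], already_cropped=True)
    metrics = evaluate(pred, test_case[2],
                       region=np.ones(pred.data.shape, dtype=bool))
    return {
        "dsc": metrics.dsc,
        "sensitivity": metrics.sensitivity,
        "specificity": metrics.specificity,
        "epochs_run": len(history.val_loss),
        "stop_reason": history.stop_reason,
        "metrics": metrics,
        "model": model,
    }
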