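"""scikit-learn style estimators over the pipeline stages.

`FrangiVesselness` and `CoherenceEnhancingDiffusion` are stateless
transformers over volumes (fit is a no-op that validates parameters);
`VesselEnhancer` composes them into the two-stage preprocessing;
`ResDenseUNetSegmenter` is a fit/predict estimator over (patches, masks).
All follow the get_params/set_params contract so they compose with sklearn
pipelines and model selection; fitted state carries a trailing underscore.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import ced as _ced
from . import frangi as _frangi
from .io_volumes import BinaryMask3D, Volume3D
from .resdense_unet import NetworkConfig, build_unet
from .trainer import TrainConfig, soft_dice_loss, train

__all__ = [
    "FrangiVesselness",
    "CoherenceEnhancingDiffusion",
    "VesselEnhancer",
    "ResDenseUNetSegmenter",
]


def _as_volume(x) -> Volume3D:
    return x if isinstance(x, Volume3D) else Volume3D(np.asarray(x, dtype=np.float32))


def _as_mask(x) -> BinaryMask3D | None:
    if x is None or isinstance(x, BinaryMask3D):
        return x
    return BinaryMask3D(np.asarray(x))


class FrangiVesselness(TransformerMixin, BaseEstimator):
    """Multi-scale Hessian vesselness as a volume transformer.

    ``transform(volume)`` returns the [0, 1] vesselness response; an optional
    liver mask zeroes the response outside the ROI.
    """

    def __init__(self, scales=(4.0, 5.0, 6.0, 7.0, 8.0), alpha=0.5, beta=0.5,
                 c=None, bright_on_dark=True):
        self.scales = scales
        self.alpha = alpha
        self.beta = beta
        self.c = c
        self.bright_on_dark = bright_on_dark

    def _params(self) -> _frangi.VesselnessParams:
        return _frangi.VesselnessParams(
            scales=tuple(self.scales), alpha=self.alpha, beta=self.beta,
            c=self.c, bright_on_dark=self.bright_on_dark,
        )

    def fit(self, X=None, y=None):
        self._params()  # validate
        self.n_features_in_ = 0
        return self

    def transform(self, X, mask: BinaryMask3D | np.ndarray | None = None) -> Volume3D:
        vmap = _frangi.multiscale_vesselness(_as_volume(X), _as_mask(mask), self._params())
        self.resolved_c_ = vmap.params.c
        return vmap.data


class CoherenceEnhancingDiffusion(TransformerMixin, BaseEstimator):
    """Structure-tensor driven anisotropic diffusion as a volume transformer."""

    def __init__(self, sigma=1.0, rho=2.0, alpha_reg=0.001, C=1.0, tau=0.1,
                 n_iter=10, eps_ratio=1e-10):
        self.sigma = sigma
        self.rho = rho
        self.alpha_reg = alpha_reg
        self.C = C
        self.tau = tau
        self.n_iter = n_iter
        self.eps_ratio = eps_ratio

    def _params(self) -> _ced.CEDParams:
        return _ced.CEDParams(sigma=self.sigma, rho=self.rho, alpha_reg=self.alpha_reg,
                              C=self.C, tau=self.tau, n_iter=self.n_iter,
                              eps_ratio=self.eps_ratio)

    def fit(self, X=None, y=None):
        self._params()
        self.n_features_in_ = 0
        return self

    def transform(self, X) -> Volume3D:
        return _ced.ced_filter(_as_volume(X), self._params())


class VesselEnhancer(TransformerMixin, BaseEstimator):
    """Crop to the liver ROI, vesselness, then CED — the full preprocessing.

    ``transform(volume, liver_mask=...)`` returns the enhanced ROI volume;
    the crop box is stored as ``box_``.
    """

    def __init__(self, vesselness: FrangiVesselness | None = None,
                 diffusion: CoherenceEnhancingDiffusion | None = None,
                 margin_vox: int = 8, skip_vesselness: bool = False,
                 skip_ced: bool = False):
        self.vesselness = vesselness
        self.diffusion = diffusion
        self.margin_vox = margin_vox
        self.skip_vesselness = skip_vesselness
        self.skip_ced = skip_ced

    def fit(self, X=None, y=None):
        self.n_features_in_ = 0
        return self

    def transform(self, X, liver_mask=None) -> Volume3D:
        if liver_mask is None:
            raise ValueError("liver_mask is required")
        vp = (self.vesselness or FrangiVesselness())._params()
        cp = (self.diffusion or CoherenceEnhancingDiffusion())._params()
        out, box = _ced.enhance(
            _as_volume(X), _as_mask(liver_mask), vp, cp,
            margin_vox=self.margin_vox, skip_vesselness=self.skip_vesselness,
            skip_ced=self.skip_ced,
        )
        self.box_ = box
        return out


class ResDenseUNetSegmenter(BaseEstimator):
    """Patch-level fit/predict wrapper around the ResDense U-net.

    ``fit(X, y)`` takes normalized image patches ``(N, H, W)`` (or
    ``(N, 1, H, W)``) and binary masks of the same shape, holds out
    ``val_fraction`` of them for the plateau/early-stop monitors unless an
    explicit validation pair is given, and trains with Adam + soft Dice.
    ``predict(X)`` returns binary masks; ``predict_proba(X)`` the probability
    maps. The trained network is ``model_``; training curves are ``history_``.
    """

    def __init__(self, levels=5, base_channels=32, block="resdense",
                 blocks_per_level=1, input_size=256, lr_init=1e-4, batch_size=32,
                 plateau_factor=0.2, plateau_patience=2, early_stop_patience=4,
                 max_epochs=100, smooth=1.0, val_fraction=0.1, threshold=0.5,
                 random_state=0):
        self.levels = levels
        self.base_channels = base_channels
        self.block = block
        self.blocks_per_level = blocks_per_level
        self.input_size = input_size
        self.lr_init = lr_init
        self.batch_size = batch_size
        self.plateau_factor = plateau_factor
        self.plateau_patience = plateau_patience
        self.early_stop_patience = early_stop_patience
        self.max_epochs = max_epochs
        self.smooth = smooth
        self.val_fraction = val_fraction
        self.threshold = threshold
        self.random_state = random_state

    @staticmethod
    def _check_xy(X, y):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 3:
            X = X[:, None]
        if X.ndim != 4:
            raise ValueError(f"expected (N, H, W) or (N, 1, H, W), got {X.shape}")
        if y is not None:
            y = np.asarray(y, dtype=np.float32)
            if y.ndim == 3:
                y = y[:, None]
            if y.shape != X.shape:
                raise ValueError(f"X/y shape mismatch: {X.shape} vs {y.shape}")
        return X, y

    def fit(self, X, y, X_val=None, y_val=None):
        X, y = self._check_xy(X, y)
        size = X.shape[-1]
        cfg = NetworkConfig(levels=self.levels, base_channels=self.base_channels,
                            block=self.block, blocks_per_level=self.blocks_per_level,
                            input_size=size)
        self.model_ = build_unet(cfg, seed=self.random_state)
        if X_val is None:
            rng = np.random.default_rng(self.random_state)
            order = rng.permutation(len(X))
            n_val = max(1, int(round(self.val_fraction * len(X))))
            val_idx, tr_idx = order[:n_val], order[n_val:]
            if len(tr_idx) == 0:
                raise ValueError("not enough patches to split off a validation set")
            X_val, y_val = X[val_idx], y[val_idx]
            X, y = X[tr_idx], y[tr_idx]
        else:
            X_val, y_val = self._check_xy(X_val, y_val)
        tcfg = TrainConfig(lr_init=self.lr_init, batch_size=self.batch_size,
                           plateau_factor=self.plateau_factor,
                           plateau_patience=self.plateau_patience,
                           early_stop_patience=self.early_stop_patience,
                           max_epochs=self.max_epochs, smooth=self.smooth,
                           seed=self.random_state)
        self.model_, history = train(self.model_, (X, y), (X_val, y_val), tcfg)
        self.history_ = history
        self.n_features_in_ = X.shape[-1] * X.shape[-2]
        return self

    def predict_proba(self, X) -> np.ndarray:
        X, _ = self._check_xy(X, None)
        out = [self.model_.forward(X[i : i + self.batch_size], train=False)
               for i in range(0, len(X), self.batch_size)]
        return np.concatenate(out, axis=0)

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) > self.threshold).astype(np.uint8)

    def score(self, X, y) -> float:
        """Mean soft Dice (1 - loss) on the given patches; higher is better."""
        X, y = self._check_xy(X, y)
        return 1.0 - soft_dice_loss(self.predict_proba(X), y, self.smooth)
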