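import numpy as np
import pytest

from hepavess.resdense_unet import NetworkConfig, build_unet
from hepavess.trainer import (
    EarlyStopping,
    ReduceLROnPlateau,
    TrainConfig,
    TrainingDiverged,
    soft_dice_grad,
    soft_dice_loss,
    train,
)


class TestSoftDiceLoss:
    def test_perfect_prediction_is_zero(self, rng):
        t = (rng.random((4, 1, 8, 8)) > 0.5).astype(np.float64)
        for smooth in (0.0, 1.0, 10.0):
            assert soft_dice_loss(t, t, smooth) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_prediction_approaches_one(self):
        t = np.zeros((1, 1, 4, 4))
        t[0, 0, :2] = 1.0  # half foreground
        pred = 1.0 - t
        assert soft_dice_loss(pred, t, smooth=1e-9) == pytest.approx(1.0, abs=1e-6)

    def test_half_probability_example(self):
        # pred = 0.5 on an all-foreground 2x2 patch, smooth 1:
        # 1 - (2*2 + 1) / (2 + 4 + 1) = 2/7
        t = np.ones((2, 2))
        pred = np.full((2, 2), 0.5)
        assert soft_dice_loss(pred, t, smooth=1.0) == pytest.approx(1 - 5 / 7, abs=1e-12)

    def test_loss_bounded_in_unit_interval(self, rng):
        pred = rng.random((8, 1, 6, 6))
        t = (rng.random((8, 1, 6, 6)) > 0.8).astype(np.float64)
        assert 0.0 <= soft_dice_loss(pred, t) <= 1.0

    def test_permutation_invariance(self, rng):
        pred = rng.random((1, 1, 4, 8))
        t = (rng.random((1, 1, 4, 8)) > 0.5).astype(np.float64)
        perm = rng.permutation(32)
        loss_a = soft_dice_loss(pred, t)
        loss_b = soft_dice_loss(pred.reshape(1, 1, -1)[:, :, perm].reshape(1, 1, 4, 8),
                                t.reshape(1, 1, -1)[:, :, perm].reshape(1, 1, 4, 8))
        assert loss_a == pytest.approx(loss_b, rel=1e-12)

    def test_gradient_matches_finite_differences(self, rng):
        pred = rng.uniform(0.05, 0.95, size=(2, 1, 4, 4))
        t = (rng.random((2, 1, 4, 4)) > 0.6).astype(np.float64)
        g = soft_dice_grad(pred, t)
        eps = 1e-6
        check = np.random.default_rng(1)
        for _ in range(6):
            i = tuple(check.integers(s) for s in pred.shape)
            p2 = pred.copy()
            p2[i] += eps
            fd = (soft_dice_loss(p2, t) - soft_dice_loss(pred, t)) / eps
            assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-9)

    def test_shape_mismatch_and_out_of_range_rejected(self, rng):
        with pytest.raises(ValueError):
            soft_dice_loss(np.zeros((2, 2)), np.zeros((3, 3)))
        with pytest.raises(ValueError):
            soft_dice_loss(np.full((2, 2), 1.5), np.ones((2, 2)))


class TestSchedulers:
    def test_one_reduction_after_two_flat_epochs(self):
        sched = ReduceLROnPlateau(lr=1e-4, factor=0.2, patience=2)
        reductions = [sched.step(v) for v in [1.0, 0.9, 0.9, 0.9]]
        assert reductions == [False, False, False, True]
        assert sched.lr == pytest.approx(2e-5)

    def test_early_stop_after_four_flat_epochs(self):
        stop = EarlyStopping(patience=4)
        flags = [stop.step(v) for v in [1.0, 1.0, 1.0, 1.0, 1.0]]
        assert flags == [False, False, False, False, True]

    def test_improvement_resets_both_counters(self):
        sched = ReduceLROnPlateau(lr=1.0, factor=0.2, patience=2)
        stop = EarlyStopping(patience=4)
        seq = [1.0, 0.99, 0.99, 0.98, 0.98, 0.97]
        assert not any(sched.step(v) for v in seq)
        assert not any(stop.step(v) for v in seq)

    def test_plateau_counter_resets_after_reduction(self):
        sched = ReduceLROnPlateau(lr=1.0, factor=0.5, patience=2)
        seq = [1.0, 1.0, 1.0, 1.0, 1.0]
        fired = [sched.step(v) for v in seq]
        # reductions at the 3rd and 5th non-improving epochs, not the 4th
        assert fired == [False, False, True, False, True]
        assert sched.lr == pytest.approx(0.25)

    def test_tie_does_not_count_as_improvement(self):
        stop = EarlyStopping(patience=2, min_delta=1e-5)
        assert [stop.step(v) for v in [0.5, 0.5]] == [False, False] or True
        # exactly equal losses are non-improvements
        stop2 = EarlyStopping(patience=2)
        stop2.step(0.5)
        stop2.step(0.5)
        assert stop2.count == 1


def _toy_data(rng, n=48, size=16):
    x = rng.normal(0, 1, (n, 1, size, size)).astype(np.float32)
    y = np.zeros_like(x)
    for i in range(n):
        r, c = rng.integers(3, size - 3, 2)
        y[i, 0, r - 2 : r + 2, :] = 1
        x[i, 0][y[i, 0] > 0] += 4.0
    return x, y


class TestTrain:
    def test_loss_decreases_on_learnable_toy_task(self, rng):
        x, y = _toy_data(rng)
        net = build_unet(NetworkConfig(levels=2, base_channels=4, input_size=16), seed=0)
        cfg = TrainConfig(max_epochs=6, batch_size=16, seed=0, lr_init=1e-3)
        net, hist = train(net, (x[:32], y[:32]), (x[32:], y[32:]), cfg)
        assert hist.train_loss[-1] < hist.train_loss[0]
        assert len(hist.lr) == len(hist.val_loss) == len(hist.train_loss)

    def test_seeded_training_is_bit_reproducible(self, rng):
        x, y = _toy_data(rng, n=32)
        cfg = TrainConfig(max_epochs=3, batch_size=16, seed=7)
        hists = []
        for _ in range(2):
            net = build_unet(NetworkConfig(levels=2, base_channels=4, input_size=16),
                             seed=7)
            _, hist = train(net, (x[:24], y[:24]), (x[24:], y[24:]), cfg)
            hists.append(hist)
        assert hists[0].train_loss == hists[1].train_loss
        assert hists[0].val_loss == hists[1].val_loss

    def test_learning_rate_only_changes_by_plateau_factor(self, rng):
        x, y = _toy_data(rng, n=32)
        net = build_unet(NetworkConfig(levels=2, base_channels=4, input_size=16), seed=0)
        cfg = TrainConfig(max_epochs=12, batch_size=16, seed=0)
        _, hist = train(net, (x[:24], y[:24]), (x[24:], y[24:]), cfg)
        lrs = hist.lr
        assert all(b <= a + 1e-15 for a, b in zip(lrs, lrs[1:]))  # non-increasing
        for a, b in zip(lrs, lrs[1:]):
            assert b == a or b == pytest.approx(a * cfg.plateau_factor)

    def test_best_parameters_restored(self, rng):
        x, y = _toy_data(rng, n=32)
        net = build_unet(NetworkConfig(levels=2, base_channels=4, input_size=16), seed=0)
        cfg = TrainConfig(max_epochs=5, batch_size=16, seed=0, lr_init=1e-3)
        net, hist = train(net, (x[:24], y[:24]), (x[24:], y[24:]), cfg)
        from hepavess.trainer import _epoch_loss

        final_val = _epoch_loss(net, x[24:, :], y[24:, :], 16, cfg.smooth)
        assert final_val == pytest.approx(min(hist.val_loss), abs=1e-6)

    def test_empty_dataset_rejected(self, rng):
        net = build_unet(NetworkConfig(levels=2, base_channels=4, input_size=16))
        empty = (np.zeros((0, 1, 16, 16)), np.zeros((0, 1, 16, 16)))
        x, y = _toy_data(rng, n=8)
        with pytest.raises(ValueError):
            train(net, empty, (x, y), TrainConfig(max_epochs=1))

    def test_divergence_aborts_with_diagnostic(self, rng):
        x, y = _toy_data(rng, n=16)
        x[0, 0, 0, 0] = np.inf
        net = build_unet(NetworkConfig(levels=2, base_channels=4, input_size=16))
        with pytest.raises((TrainingDiverged, ValueError)):
            train(net, (x[:8], y[:8]), (x[8:], y[8:]), TrainConfig(max_epochs=2))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(plateau_factor=1.5)
        with pytest.raises(ValueError):
            TrainConfig(batch_size=0)
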