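"""Weighted loss, training loop, early stopping, fine-tuning and prediction."""

import numpy as np
import pytest

from conftest import make_trip
from divetrace.features import NormStats, WindowSet
from divetrace.networks import ARCHITECTURES, build, forward
from divetrace.training import (
    TrainConfig,
    fine_tune,
    predict_trip,
    train,
    weighted_bce,
)


class TestWeightedBCE:
    def test_positive_miss_scales_with_weight(self):
        assert weighted_bce(np.array([0.5]), np.array([1.0]), 30.0) == pytest.approx(30 * np.log(2))

    def test_negative_miss_ignores_weight(self):
        for w in (1.0, 5.0, 30.0):
            assert weighted_bce(np.array([0.5]), np.array([0.0]), w) == pytest.approx(np.log(2))

    def test_unit_weight_reduces_to_plain_bce(self):
        rng = np.random.default_rng(0)
        p = rng.random(100)
        y = (rng.random(100) < 0.5).astype(float)
        plain = np.mean(-(y * np.log(np.clip(p, 1e-7, 1 - 1e-7)) + (1 - y) * np.log(np.clip(1 - p, 1e-7, 1))))
        assert weighted_bce(p, y, 1.0) == pytest.approx(plain, rel=1e-9)

    def test_perfect_prediction_near_zero(self):
        assert weighted_bce(np.array([1.0, 0.0]), np.array([1.0, 0.0]), 30.0) < 1e-5

    def test_monotone_in_weight(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.1, 0.9, 50)
        y = (rng.random(50) < 0.3).astype(float)
        losses = [weighted_bce(p, y, w) for w in (1, 5, 30)]
        assert losses[0] < losses[1] < losses[2]

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            weighted_bce(np.zeros(3), np.zeros(4), 1.0)


def _separable_windows(n, seed, label_rate=0.3):
    """Toy windows where the speed channel alone determines the label."""
    rng = np.random.default_rng(seed)
    y = rng.random((n, 20)) < label_rate
    x = np.zeros((n, 3, 20))
    x[:, 0, :] = np.where(y, -1.0, 1.0) + rng.normal(0, 0.05, (n, 20))
    x[:, 2, :] = 1.0
    return WindowSet(x=x, y=y, trip_id=np.array(["t"] * n, object), start_index=np.zeros(n, int))


@pytest.mark.parametrize("kind", ARCHITECTURES)
def test_separable_toy_problem_is_learned(kind):
    """Any architecture cuts its initial loss by 10x on separable data."""
    tr = _separable_windows(128, 0)
    va = _separable_windows(32, 1)
    bundle = build(kind, 0)
    initial = weighted_bce(forward(bundle, tr.x), tr.y, 5.0)
    cfg = TrainConfig(class_weight=5.0, max_epochs=50, patience=50, seed=0)
    fitted, hist = train(bundle, tr, va, cfg)
    assert min(hist.train_loss) < 0.1 * initial


def test_training_is_deterministic():
    tr = _separable_windows(64, 2)
    va = _separable_windows(16, 3)
    cfg = TrainConfig(class_weight=5.0, max_epochs=5, patience=5, seed=1)
    _, h1 = train(build("CNNET", 1), tr, va, cfg)
    _, h2 = train(build("CNNET", 1), tr, va, cfg)
    assert h1.train_loss == h2.train_loss
    assert h1.validation_loss == h2.validation_loss


def test_early_stopping_returns_best_epoch_weights():
    tr = _separable_windows(64, 4)
    va = _separable_windows(16, 5)
    cfg = TrainConfig(class_weight=5.0, max_epochs=30, patience=1, seed=0)
    fitted, hist = train(build("CNNET", 0), tr, va, cfg)
    best = min(hist.validation_loss)
    got = weighted_bce(forward(fitted, va.x), va.y, 5.0)
    assert got == pytest.approx(best, rel=1e-9)
    assert hist.stopped_epoch <= cfg.max_epochs


def test_empty_window_set_rejected():
    tr = _separable_windows(8, 0)
    empty = WindowSet(np.empty((0, 3, 20)), np.empty((0, 20), bool), np.empty(0, object), np.empty(0, int))
    with pytest.raises(ValueError):
        train(build("CNNET", 0), empty, tr, TrainConfig())


def test_fine_tune_zero_epochs_is_noop():
    pre = build("CNNET", 7)
    tr = _separable_windows(8, 0)
    cfg = TrainConfig(max_epochs=0)
    tuned, hist = fine_tune(pre, tr, tr, cfg)
    for k in pre.params:
        np.testing.assert_array_equal(tuned.params[k], pre.params[k])
    assert hist.stopped_epoch == 0


def test_fine_tune_refits_norm_stats_and_stays_probabilistic():
    pre = build("CNNET", 7)
    pre.norm_stats = NormStats(1.0, 1.0, "source")
    tr = _separable_windows(64, 6)
    va = _separable_windows(16, 7)
    new_norm = NormStats(2.0, 0.5, "target")
    tuned, _ = fine_tune(pre, tr, va, TrainConfig(max_epochs=3, patience=3), norm_stats=new_norm)
    assert tuned.norm_stats == new_norm
    p = forward(tuned, tr.x)
    assert np.all((p > 0) & (p < 1))


class TestPredictTrip:
    def _trip(self, n=60):
        rng = np.random.default_rng(0)
        lon = np.cumsum(rng.normal(0, 1e-4, n))
        return make_trip(lon, np.zeros(n))

    def _constant_bundle(self, value=0.5):
        b = build("CNNET", 0)
        for k in b.params:
            b.params[k][:] = 0.0
        b.norm_stats = NormStats(0.0, 1.0)
        return b  # all-zero weights -> sigmoid(0) = 0.5 everywhere

    def test_constant_network_gives_constant_series(self):
        series = predict_trip(self._constant_bundle(), self._trip())
        np.testing.assert_allclose(series.p, 0.5, atol=1e-12)

    def test_batch_partition_invariance(self):
        b = build("UNET", 3)
        b.norm_stats = NormStats(0.0, 1.0)
        trip = self._trip(80)
        a = predict_trip(b, trip, batch=7)
        c = predict_trip(b, trip, batch=512)
        np.testing.assert_allclose(a.p, c.p, atol=1e-12)

    def test_window_mean_combinatorics(self):
        """Position i of a long trip is covered by min(i+1, 20, n-i)
        stride-1 windows; the mean over two overlapping values is their
        average."""
        assert (0.2 + 0.4) / 2 == pytest.approx(0.3)
        trip = self._trip(50)
        b = self._constant_bundle()
        ws_counts = np.zeros(50)
        for s in range(50 - 20 + 1):
            ws_counts[s : s + 20] += 1
        assert ws_counts[0] == 1 and ws_counts[19] == 20
        series = predict_trip(b, trip)
        assert len(series) == 50

    def test_short_trip_rejected(self):
        with pytest.raises(ValueError):
            predict_trip(self._constant_bundle(), self._trip(10))
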