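"""Discrete-time survival core: grid, label encoding, likelihood, network,
curves and the model/results interface."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from renalprog import survival as sv


class TestTimeGrid:
    def test_division_of_horizon(self, grid15):
        assert grid15.width == 200.0
        assert grid15.n_intervals == 15
        assert np.allclose(grid15.boundaries, np.arange(0, 3001, 200))

    def test_single_interval(self):
        g = sv.make_time_grid(10.0, 1)
        assert g.n_intervals == 1 and g.t_max == 10.0

    @pytest.mark.parametrize("maxd,n", [(3000.0, 0), (0.0, 15), (-5.0, 3)])
    def test_invalid_inputs(self, maxd, n):
        with pytest.raises(ValueError):
            sv.make_time_grid(maxd, n)


class TestEncodeLabels:
    def test_death_at_grid_maximum_lands_in_last_interval(self, grid15):
        survs, survf = sv.encode_labels(3000.0, 1, grid15)
        assert survf[-1] == 1 and survf.sum() == 1
        assert survs[-1] == 0 and survs[:-1].all()

    def test_duration_beyond_grid_clamped_with_warning(self, grid15):
        with pytest.warns(UserWarning, match="clamping"):
            survs, _ = sv.encode_labels(3500.0, 0, grid15)
        assert survs.all()

    def test_negative_duration_rejected(self, grid15):
        with pytest.raises(ValueError):
            sv.encode_labels(-1.0, 1, grid15)

    def test_censored_below_first_midpoint_is_uninformative(self, grid15):
        survs, survf = sv.encode_labels(50.0, 0, grid15)
        assert not survs.any() and not survf.any()
        # such a record contributes exactly zero to the loss
        pred = np.random.default_rng(0).uniform(0.1, 0.9, (1, 15))
        assert sv.survival_loss(pred, survs[None], survf[None]) == 0.0

    @given(duration=st.floats(0.0, 3000.0), event=st.integers(0, 1))
    @settings(max_examples=200, deadline=None)
    def test_encoding_invariants(self, duration, event):
        grid = sv.make_time_grid(3000.0, 15)
        survs, survf = sv.encode_labels(duration, event, grid)
        # survs is a prefix of ones
        ones = np.flatnonzero(survs)
        assert ones.size == 0 or (ones == np.arange(ones.size)).all()
        # survf: at most one 1, zero for censored, never overlapping survs
        assert survf.sum() <= 1
        if event == 0:
            assert not survf.any()
        else:
            assert survf.sum() == 1
        assert not (survs & survf).any()
        # an uncensored death interval directly follows the survived prefix
        if event == 1:
            assert np.flatnonzero(survf)[0] == ones.size


class TestSurvivalLoss:
    def test_worked_example(self):
        pred = np.array([[0.5, 0.5, 0.5]])
        loss = sv.survival_loss(pred, np.array([[1, 0, 0]]), np.array([[0, 1, 0]]))
        assert loss == pytest.approx(-2 * np.log(0.5), rel=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sv.survival_loss(np.ones((2, 3)) * 0.5, np.zeros((2, 4)), np.zeros((2, 3)))

    def test_clamping_keeps_loss_finite(self):
        pred = np.array([[0.0, 1.0]])
        loss = sv.survival_loss(pred, np.array([[1, 0]]), np.array([[0, 1]]))
        assert np.isfinite(loss)


class TestSurvivalNet:
    def test_architecture_contract(self):
        net = sv.build_survival_net(2560, seed=0)
        out = net.forward(np.random.default_rng(0).normal(size=(1, 2560)))
        assert out.shape == (1, 15)
        assert ((out > 0) & (out < 1)).all()

    def test_inference_is_deterministic_despite_dropout(self, rng):
        net = sv.build_survival_net(32, n_intervals=10, seed=1)
        x = rng.normal(size=(4, 32))
        a = net.forward(x, train=False)
        b = net.forward(x, train=False)
        assert np.array_equal(a, b)
        assert not np.array_equal(net.forward(x, train=True),
                                  net.forward(x, train=True))

    def test_invalid_dims_rejected(self):
        with pytest.raises(ValueError):
            sv.build_survival_net(0)


class TestTraining:
    def _toy(self, rng, n=40):
        x = rng.normal(size=(n, 8)).astype(np.float32)
        grid = sv.make_time_grid(100.0, 5)
        dur = rng.uniform(1, 100, n)
        ev = rng.integers(0, 2, n)
        survs, survf = sv.encode_dataset(dur, ev, grid)
        return x, survs, survf

    def test_zero_lr_leaves_parameters_unchanged(self, rng):
        # trainable weights must not move; batch-norm running statistics may
        x, survs, survf = self._toy(rng)
        net = sv.build_survival_net(8, n_intervals=5, seed=0)
        before = [p.value.copy() for p in net.params()]
        net, log = sv.train_survival_net(net, x[:30], survs[:30], survf[:30],
                                         x[30:], survs[30:], survf[30:],
                                         lr=0.0, max_epochs=5, patience=10)
        for p, b in zip(net.params(), before):
            assert np.array_equal(p.value, b)

    def test_patience_zero_stops_at_first_non_improvement(self, rng, monkeypatch):
        x, survs, survf = self._toy(rng)
        net = sv.build_survival_net(8, n_intervals=5, seed=0)
        # scripted losses: the loop sees train then val once per (full-batch)
        # epoch; validation worsens immediately after epoch 0
        calls = {"n": 0}

        def scripted_loss(pred, s, f):
            calls["n"] += 1
            is_val = calls["n"] % 2 == 0
            epoch = (calls["n"] - 1) // 2
            return float(5.0 + epoch) if is_val else 1.0

        monkeypatch.setattr(sv, "survival_loss", scripted_loss)
        net, log = sv.train_survival_net(net, x[:30], survs[:30], survf[:30],
                                         x[30:], survs[30:], survf[30:],
                                         lr=1e-3, max_epochs=50, patience=0)
        # epoch 0 sets the best (val 5.0); epoch 1 (val 6.0) triggers the stop
        assert len(log) == 2

    def test_all_zero_labels_rejected(self, rng):
        x = rng.normal(size=(10, 4)).astype(np.float32)
        z = np.zeros((10, 5), dtype=np.int8)
        net = sv.build_survival_net(4, n_intervals=5)
        with pytest.raises(ValueError, match="all zero"):
            sv.train_survival_net(net, x, z, z, x, z, z)


class TestCurves:
    def test_cumulative_is_product_of_conditionals(self, grid15):
        curve = sv.SurvivalCurve(sv.make_time_grid(400.0, 2), np.array([0.9, 0.8]))
        assert np.allclose(curve.cumulative, [0.9, 0.72])

    def test_all_ones_certain_survival(self):
        curve = sv.SurvivalCurve(sv.make_time_grid(30.0, 3), np.ones(3))
        assert (curve.cumulative == 1.0).all()

    def test_curve_non_increasing_for_any_net_output(self, rng):
        net = sv.build_survival_net(6, n_intervals=15, seed=3)
        grid = sv.make_time_grid(3000.0, 15)
        for _ in range(5):
            c = sv.predict_survival_curve(net, rng.normal(size=6), grid)
            assert (np.diff(c.cumulative) <= 1e-12).all()

    def test_interpolation_hits_knots_and_midpoints(self):
        grid = sv.make_time_grid(400.0, 2)
        curve = sv.SurvivalCurve(grid, np.array([0.8, 0.5]))
        assert curve.survival_at(0.0) == 1.0
        assert curve.survival_at(200.0) == pytest.approx(0.8)
        assert curve.survival_at(100.0) == pytest.approx(0.9)  # linear in [0, 200)
        out = sv.interpolate_curve(curve, n_points=40)
        assert out.knots.shape == (40, 2)
        assert (np.diff(out.knots[:, 1]) <= 1e-12).all()  # monotone

    def test_too_few_points_rejected(self):
        curve = sv.SurvivalCurve(sv.make_time_grid(10.0, 1), np.array([0.5]))
        with pytest.raises(ValueError):
            sv.interpolate_curve(curve, n_points=1)


class TestModelResults:
    def _fit(self, seed=0):
        rng = np.random.default_rng(seed)
        n = 120
        x = rng.normal(size=(n, 6))
        risk = x[:, 0]
        dur = np.clip(rng.exponential(800 * np.exp(-risk)), 1, 3000)
        ev = (rng.random(n) < 0.6).astype(int)
        model = sv.DiscreteTimeSurvival(x, dur, ev, n_intervals=15)
        return model, model.fit(seed=seed, max_epochs=60), x, dur, ev

    def test_fit_reduces_validation_loss(self):
        _, res, *_ = self._fit()
        hist = res.history
        assert hist["val_loss"].min() < hist["val_loss"].iloc[0]

    def test_predictions_reproducible_and_monotone(self):
        model, res, x, _, _ = self._fit()
        c1 = res.predict_curves(x[:5])
        c2 = res.predict_curves(x[:5])
        for a, b in zip(c1, c2):
            assert np.array_equal(a.conditional, b.conditional)
            assert (np.diff(a.cumulative) <= 1e-12).all()

    def test_summary_mentions_architecture(self):
        _, res, *_ = self._fit()
        text = res.summary()
        assert "logistic hazard" in text
        assert "32" in text and "15" in text

    def test_from_dataframe_joins_on_patient_id(self):
        feats = pd.DataFrame({"patient_id": ["a", "b", "c"],
                              "f0": [0.1, 0.2, 0.3], "f1": [1.0, 2.0, 3.0]})
        clin = pd.DataFrame({"patient_id": ["c", "a", "b"],
                             "duration_days": [10.0, 20.0, 30.0],
                             "event": [1, 0, 1]})
        m = sv.DiscreteTimeSurvival.from_dataframe(feats, clin, n_intervals=3)
        assert m.features.shape == (3, 2)
        assert m.durations[m.patient_ids.index("c")] == 10.0

    def test_all_censored_cannot_fit(self):
        x = np.zeros((10, 2))
        m = sv.DiscreteTimeSurvival(x, np.arange(1.0, 11.0), np.zeros(10, int))
        with pytest.raises(ValueError, match="uncensored"):
            m.fit()
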