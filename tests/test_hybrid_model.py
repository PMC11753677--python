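"""Hybrid model training: gradients, losses, selection, and fit quality."""

import numpy as np
import pytest

from hybridsindy import (
    HybridODERegressor,
    KnownPart,
    NoiseSpec,
    SimulationGrid,
    ValidationError,
    apply_noise,
    grid_search_nn,
    make_dataset,
    simulate,
    validation_loss,
    window_loss,
)
from hybridsindy._nn import MLP
from hybridsindy.hybrid_model import NetworkSpec, _window_backward, _window_forward
from hybridsindy.preprocessing import sliding_windows

from conftest import LV_PARAMS, LV_X0


def _zeroed(net: MLP) -> MLP:
    net.set_weights([np.zeros_like(w) for w in net.weights])
    return net


class TestBackpropThroughSolver:
    def test_gradients_match_finite_differences(self):
        """Discretize-then-optimize gradients are exact for the discrete loss."""
        rng = np.random.default_rng(0)
        d = 2
        net = MLP([d, 5, d], seed=1)
        # make all layers (incl. zero-initialized output) nontrivial
        net.set_weights([w + 0.05 * rng.standard_normal(w.shape) for w in net.weights])
        known = KnownPart.linear([1.3, -1.8])
        obs = rng.normal(1.0, 0.3, size=(3, 4, d))
        x0 = obs[:, 0].copy()
        dt, substeps = 0.1, 2

        def fun(x):
            return known.f(x) + net.forward(x)

        def loss():
            preds, _ = _window_forward(fun, x0, dt, obs.shape[1] - 1, substeps)
            return np.mean((preds - obs) ** 2)

        preds, tape = _window_forward(fun, x0, dt, obs.shape[1] - 1, substeps)
        grads = net.zero_grads()

        def vjp(x, v):
            out, cache = net.forward(x, need_cache=True)
            dx, gs = net.backward(cache, v)
            for acc, g in zip(grads, gs):
                acc += g
            return dx + known.vjp(x, v)

        _window_backward(vjp, 2 * (preds - obs) / obs.size, tape, dt, obs.shape[1] - 1, substeps)

        eps = 1e-6
        for wi, W in enumerate(net.weights):
            flat = W.reshape(-1)
            for idx in range(0, flat.size, max(1, flat.size // 5)):  # spot-check entries
                old = flat[idx]
                flat[idx] = old + eps
                lp = loss()
                flat[idx] = old - eps
                lm = loss()
                flat[idx] = old
                fd = (lp - lm) / (2 * eps)
                assert grads[wi].reshape(-1)[idx] == pytest.approx(fd, rel=1e-5, abs=1e-10)


class TestWindowLoss:
    def test_true_model_on_noisefree_window_is_zero(self, lv_system, lv_known, lv_truth):
        known_true = KnownPart(d=2, f=lv_system.rhs, vjp=lambda x, v: v, terms=lv_system.terms)
        net = _zeroed(MLP([2, 8, 2], seed=0))
        seg = sliding_windows(lv_truth, 5)[10]
        assert window_loss(known_true, net, seg, substeps=4) < 1e-8

    def test_zero_model_gives_constant_prediction_loss(self, lv_truth):
        """g = 0, NN = 0: prediction is constant at the first row."""
        known = KnownPart.zero(2)
        net = _zeroed(MLP([2, 8, 2], seed=0))
        seg = sliding_windows(lv_truth, 5)[0]
        expected = np.mean((seg.states - seg.states[0]) ** 2)
        assert window_loss(known, net, seg) == pytest.approx(expected, rel=1e-12)

    def test_batch_loss_is_mean_of_window_losses(self, lv_system, lv_truth):
        known = KnownPart.linear([LV_PARAMS["alpha"], -LV_PARAMS["delta"]])
        net = MLP([2, 8, 2], seed=3)
        segs = sliding_windows(lv_truth, 5)[:4]
        individual = [window_loss(known, net, s) for s in segs]

        def fun(x):
            return known.f(x) + net.forward(x)

        obs = np.stack([s.states for s in segs])
        preds, _ = _window_forward(fun, obs[:, 0].copy(), 0.1, 4, 2)
        batch = np.mean((preds - obs) ** 2)
        assert batch == pytest.approx(np.mean(individual), rel=1e-12)


class TestValidationLoss:
    def test_perfect_model_noisefree_validation(self, lv_system, lv_truth):
        assert validation_loss(lv_system.rhs, [lv_truth], substeps=4) < 1e-8

    def test_identical_samples_leave_mean_unchanged(self, lv_system, lv_truth):
        noisy = apply_noise(lv_truth, NoiseSpec("additive", 0.05), 0)
        one = validation_loss(lv_system.rhs, [noisy])
        two = validation_loss(lv_system.rhs, [noisy, noisy])
        assert one == pytest.approx(two, rel=1e-12)

    def test_empty_validation_rejected(self, lv_system):
        with pytest.raises(ValidationError):
            validation_loss(lv_system.rhs, [])

    def test_noise_floor_with_true_dynamics(self, lv_system, lv_truth):
        """With the exact right-hand side, the loss is the irreducible noise floor.

        Validation samples keep their exact first observation so simulation
        error does not confound the check; expected MSE is the average
        per-entry noise variance over the remaining rows.
        """
        eps, n_samples = 0.05, 50
        rng = np.random.default_rng(11)
        samples = []
        for _ in range(n_samples):
            noisy = apply_noise(lv_truth, NoiseSpec("additive", eps), rng)
            noisy.states[0] = lv_truth.states[0]
            samples.append(noisy)
        loss = validation_loss(lv_system.rhs, samples, substeps=4)
        T, d = lv_truth.states.shape
        scale = eps * lv_truth.states.mean(axis=0)
        expected = (T - 1) / (T * d) * np.sum(scale**2)
        assert loss == pytest.approx(expected, rel=0.2)


class TestTraining:
    def _tiny_dataset(self, lv_system, seed=0, n_train=8, level=0.01):
        return make_dataset(
            lv_system, LV_X0, SimulationGrid(0, 4, 0.1), SimulationGrid(0, 20, 0.1),
            NoiseSpec("additive", level), n_train=n_train, n_val=5, n_test=2, seed=seed,
        )

    def test_reproducible_given_seeds(self, lv_system, lv_known):
        ds = self._tiny_dataset(lv_system)
        fit = lambda: HybridODERegressor(
            known=lv_known, window=5, batch_size=5, lr=0.01, epochs=2,
            init_seed=5, shuffle_seed=5,
        ).fit(ds)
        a, b = fit(), fit()
        for wa, wb in zip(a.network_.weights, b.network_.weights):
            np.testing.assert_array_equal(wa, wb)
        assert a.validation_loss_ == b.validation_loss_

    def test_zero_noise_with_true_known_part_stays_near_zero(self, lv_system):
        """g = true rhs and noise-free data: the initial model is already
        (numerically) perfect and training does not degrade it."""
        known_true = KnownPart(d=2, f=lv_system.rhs, vjp=lambda x, v: v * 0.0,
                               terms=lv_system.terms)
        ds = self._tiny_dataset(lv_system, level=0.0, n_train=4)
        model = HybridODERegressor(
            known=known_true, window=5, batch_size=5, lr=0.001, epochs=2, init_seed=0,
        ).fit(ds)
        assert model.history_["validation_loss"].iloc[0] < 1e-6
        assert model.validation_loss_ < 1e-6

    def test_learning_rate_sensitivity(self, lv_system, lv_known):
        """Low learning rate with large windows underfits; the published good
        configuration attains a much lower validation loss."""
        ds = make_dataset(
            lv_system, LV_X0, SimulationGrid(0, 4, 0.1), SimulationGrid(0, 20, 0.1),
            NoiseSpec("additive", 0.01), n_train=30, n_val=20, n_test=2, seed=3,
        )
        underfit = HybridODERegressor(known=lv_known, window=10, batch_size=10,
                                      lr=0.001, epochs=10, init_seed=0).fit(ds)
        good = HybridODERegressor(known=lv_known, window=5, batch_size=5,
                                  lr=0.01, epochs=10, init_seed=0).fit(ds)
        assert good.validation_loss_ < 0.2 * underfit.validation_loss_

    def test_best_epoch_weights_returned(self, lv_system, lv_known):
        ds = self._tiny_dataset(lv_system)
        model = HybridODERegressor(known=lv_known, window=5, batch_size=5,
                                   lr=0.05, epochs=4, init_seed=1).fit(ds)
        hist = model.history_
        best_row = hist.loc[hist["validation_loss"].idxmin()]
        assert model.best_epoch_ == int(best_row["epoch"])
        assert model.validation_loss_ == pytest.approx(hist["validation_loss"].min())

    def test_grid_search_cardinality_and_best(self, lv_system, lv_known):
        ds = self._tiny_dataset(lv_system, n_train=6)
        grid = {"w": [5], "b": [5, 10], "lr": [0.01, 0.05]}
        best, table = grid_search_nn(
            ds, lv_known, NetworkSpec(), grid=grid, epochs=2,
        )
        assert len(table) == 4
        assert best.validation_loss_ == pytest.approx(table["validation_loss"].min())

    def test_single_combination_equals_train_hybrid(self, lv_system, lv_known):
        from hybridsindy import TrainConfig, train_hybrid

        ds = self._tiny_dataset(lv_system, n_train=6)
        best, table = grid_search_nn(
            ds, lv_known, NetworkSpec(), grid={"w": [5], "b": [5], "lr": [0.01]}, epochs=2,
        )
        direct = train_hybrid(ds, lv_known, NetworkSpec(), w=5, b=5,
                              cfg=TrainConfig(lr=0.01, epochs=2))
        assert len(table) == 1
        for wa, wb in zip(best.network_.weights, direct.network_.weights):
            np.testing.assert_array_equal(wa, wb)


class TestFittedFieldAccuracy:
    def test_network_approximates_missing_interaction_terms(self, lv_hybrid_runs):
        """The fitted NN reproduces the missing interaction terms over the
        observed state range (normalized by the interaction magnitude, which
        avoids division blow-up where the true term crosses zero)."""
        ds, model, _ = lv_hybrid_runs[0]
        X = ds.truth_train.states
        nn = model.nn(X)
        true = np.stack([
            -LV_PARAMS["beta"] * X[:, 0] * X[:, 1],
            LV_PARAMS["gamma"] * X[:, 0] * X[:, 1],
        ], axis=1)
        rms = np.sqrt(np.mean(true**2, axis=0))
        norm_err = np.abs(nn - true) / rms[None, :]
        # accurate across the observed range; deviations are confined to the
        # extreme corner states at the trajectory ends
        assert np.quantile(norm_err, 0.95) < 0.10
        assert np.median(norm_err) < 0.05
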