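"""Basis libraries, STLSQ behavior, regression data, model assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hybridsindy import (
    STLSQ,
    KnownPart,
    SimulationGrid,
    ValidationError,
    build_library,
    make_dataset,
    NoiseSpec,
    simulate_regression_data,
    stlsq,
)
from hybridsindy.sparse_regression import CoefficientMatrix, assemble_model

from conftest import LV_PARAMS


class TestBuildLibrary:
    def test_poly_max_2_ordering_d2(self):
        lib = build_library("poly_max_2", 2)
        assert lib.labels == ["1", "x1", "x2", "x1^2", "x1*x2", "x2^2"]

    @pytest.mark.parametrize("name,d,size", [
        ("poly_max_2", 2, 6),
        ("poly_2_3", 2, 7),
        ("poly_1_2", 3, 9),
        ("hill_3", 3, 3),
        ("hill_max_3", 3, 9),
        ("hill_max_3_poly_1", 3, 12),
        ("hill_3_poly_1", 3, 6),
        ("hill_2_poly_xy", 3, 9),
        ("hill_3_poly_1_2", 3, 12),
    ])
    def test_library_sizes(self, name, d, size):
        assert build_library(name, d).size == size

    def test_hill_values(self):
        lib = build_library("hill_3", 3)
        x = np.array([1.0, 2.0, 0.5])
        np.testing.assert_allclose(
            lib.transform(x), [1 / 2, 1 / 9, 1 / (1 + 0.125)], rtol=1e-12
        )

    def test_monomial_values_and_vectorization(self):
        lib = build_library("poly_max_2", 2)
        X = np.array([[2.0, 3.0], [1.0, 0.5]])
        np.testing.assert_allclose(
            lib.transform(X),
            [[1, 2, 3, 4, 6, 9], [1, 1, 0.5, 1, 0.5, 0.25]],
        )

    def test_unknown_name_rejected(self):
        with pytest.raises(ValidationError):
            build_library("fourier_3", 2)


class TestSTLSQ:
    def _problem(self, seed=0, n=200, m=6, noise=0.0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, m))
        true = np.zeros(m)
        true[1], true[4] = 2.0, -1.5
        y = X @ true + noise * rng.normal(size=n)
        return X, y, true

    def test_noiseless_identifiable_exact_recovery(self):
        X, y, true = self._problem()
        est = STLSQ(threshold=0.5, alpha=0.0).fit(X, y)
        np.testing.assert_allclose(est.coef_, true, atol=1e-8)

    def test_reduces_to_ols_at_zero_alpha_and_threshold(self):
        X, y, _ = self._problem(noise=0.3)
        est = STLSQ(threshold=0.0, alpha=0.0).fit(X, y)
        expected = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(est.coef_, expected, rtol=1e-10)

    def test_ridge_matches_normal_equations_oracle(self):
        X, y, _ = self._problem(noise=0.3)
        alpha = 0.7
        est = STLSQ(threshold=0.0, alpha=alpha).fit(X, y)
        oracle = np.linalg.solve(X.T @ X + alpha * np.eye(X.shape[1]), X.T @ y)
        np.testing.assert_allclose(est.coef_, oracle, rtol=1e-8)

    @given(seed=st.integers(0, 20), threshold=st.sampled_from([0.05, 0.1, 0.5, 1.0]),
           alpha=st.sampled_from([0.0, 0.05, 0.5]))
    @settings(max_examples=25, deadline=None)
    def test_fixed_point_and_threshold_invariants(self, seed, threshold, alpha):
        """All surviving coefficients exceed the threshold, and re-running the
        ridge solve on the returned active set changes nothing."""
        X, y, _ = self._problem(seed=seed, noise=0.5)
        est = STLSQ(threshold=threshold, alpha=alpha).fit(X, y)
        c = est.coef_
        nz = c != 0
        assert np.all(np.abs(c[nz]) >= threshold)
        if nz.any():
            resolve = STLSQ._ridge(X[:, nz], y, alpha)
            np.testing.assert_allclose(c[nz], resolve, rtol=1e-9)
            assert np.all(np.abs(resolve) >= threshold)

    def test_stacking_copies_leaves_solution_unchanged(self):
        X, y, _ = self._problem(noise=0.3)
        est1 = STLSQ(threshold=0.1, alpha=0.0).fit(X, y)
        est3 = STLSQ(threshold=0.1, alpha=0.0).fit(
            np.vstack([X] * 3), np.concatenate([y] * 3)
        )
        np.testing.assert_allclose(est1.coef_, est3.coef_, atol=1e-10)

    def test_all_thresholded_out_warns_and_zeros(self):
        X, y, _ = self._problem(noise=0.0)
        with pytest.warns(UserWarning, match="thresholded out"):
            est = STLSQ(threshold=100.0, alpha=0.0).fit(X, y)
        np.testing.assert_array_equal(est.coef_, np.zeros(X.shape[1]))

    def test_noise_free_lv_exact_derivative_recovery(self, lv_system, lv_truth):
        """Regression on exact derivatives recovers the true rate constants."""
        lib = build_library("poly_max_2", 2)
        theta = lib.transform(lv_truth.states)
        targets = lv_system.rhs(lv_truth.states)
        values = stlsq(theta, targets, alpha=0.0, threshold=0.1)
        expected = np.zeros((6, 2))
        expected[1, 0] = LV_PARAMS["alpha"]
        expected[4, 0] = -LV_PARAMS["beta"]
        expected[4, 1] = LV_PARAMS["gamma"]
        expected[2, 1] = -LV_PARAMS["delta"]
        np.testing.assert_allclose(values, expected, atol=1e-3)


class _TrueHybrid:
    """Stand-in for a fitted hybrid model backed by the exact dynamics."""

    def __init__(self, system, known):
        self._system = system
        self.known_ = known

    def rhs(self, x):
        return self._system.rhs(x)

    def nn(self, x):
        return self._system.rhs(x) - self.known_.f(x)


@pytest.fixture()
def lv_fake_fitted(lv_system, lv_known, lv_noisefree_dataset):
    return _TrueHybrid(lv_system, lv_known), lv_noisefree_dataset


class TestSimulateRegressionData:
    def test_matching_dt_reproduces_training_grid(self, lv_fake_fitted):
        model, ds = lv_fake_fitted
        reg = simulate_regression_data(model, ds, dt=0.1)
        np.testing.assert_allclose(reg.trajectories[0].times, ds.train_times)
        assert len(reg.trajectories) == len(ds.train)

    def test_halved_dt_doubles_resolution(self, lv_fake_fitted):
        model, ds = lv_fake_fitted
        reg = simulate_regression_data(model, ds, dt=0.05)
        assert reg.trajectories[0].n_points == 81  # 2 * 41 - 1 (shared endpoints)

    def test_targets_are_nn_evaluations(self, lv_fake_fitted):
        model, ds = lv_fake_fitted
        reg = simulate_regression_data(model, ds, dt=0.1)
        np.testing.assert_allclose(
            reg.targets[0], model.nn(reg.trajectories[0].states), rtol=1e-12
        )

    def test_invalid_dt_rejected(self, lv_fake_fitted):
        model, ds = lv_fake_fitted
        with pytest.raises(ValidationError):
            simulate_regression_data(model, ds, dt=-0.1)


class TestSymbolicModel:
    def _model(self, lv_known):
        lib = build_library("poly_max_2", 2)
        values = np.zeros((6, 2))
        values[4, 0] = -0.9  # x1*x2 in the prey equation
        values[4, 1] = 0.8
        return assemble_model(lv_known, CoefficientMatrix(values, lib))

    def test_rendered_equations(self, lv_known):
        text = self._model(lv_known).equations_text()
        assert text.splitlines() == [
            "x1' = 1.300*x1 - 0.900*x1*x2",
            "x2' = -1.800*x2 + 0.800*x1*x2",
        ]

    def test_rhs_matches_direct_evaluation(self, lv_known):
        model = self._model(lv_known)
        lib = model.coefficients.library
        x = np.array([1.7, 0.6])
        direct = lv_known.f(x) + lib.transform(x) @ model.coefficients.values
        np.testing.assert_allclose(model.rhs(x), direct, rtol=1e-12)

    def test_all_zero_coefficients_reduce_to_known_part(self, lv_known):
        lib = build_library("poly_max_2", 2)
        model = assemble_model(lv_known, CoefficientMatrix(np.zeros((6, 2)), lib))
        x = np.array([2.0, 1.0])
        np.testing.assert_allclose(model.rhs(x), lv_known.f(x))
        assert model.k == 0

    def test_hill_term_rendering(self):
        known = KnownPart.linear([-1.0, -1.0, -1.0])
        lib = build_library("hill_3", 3)
        values = np.zeros((3, 3))
        values[2, 0] = 10.0  # hill3(x3) in the first equation
        model = assemble_model(known, CoefficientMatrix(values, lib))
        assert model.equations_text().splitlines()[0] == "x1' = -1.000*x1 + 10.000/(1+x3^3)"

    def test_json_marks_fixed_terms(self, lv_known):
        data = self._model(lv_known).to_json_dict()
        eq1 = data["equations"][0]["terms"]
        assert {"label": "x1", "coefficient": 1.3, "fixed": True} in eq1
        assert any(t["label"] == "x1*x2" and not t["fixed"] for t in eq1)

    def test_simulatable_as_ode_system(self, lv_known, lv_system):
        ode = self._model(lv_known).to_ode_system()
        x = np.array([0.9, 2.1])
        np.testing.assert_allclose(ode.rhs(x), lv_system.rhs(x), rtol=1e-12)
        assert ode.terms is not None
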