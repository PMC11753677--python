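"""Comparison model-discovery methods sharing the stage-2 AICc machinery.

Four baselines against which the hybrid formulation is benchmarked:

* ``base_sindy`` — derivatives estimated per training sample by
  second-order finite differences, STLSQ on the stacked rows;
* ``base_known`` — as base SINDy, but with the known terms g(x) subtracted
  from the derivative estimates before regression; the inferred model is
  g plus the learned terms;
* ``weak_sindy`` — the regression is cast in weak form: for smooth
  compactly-supported test functions phi on random subwindows,
  ``-integral(phi' x) = integral(phi Theta(x)) Xi`` by parts, with
  trapezoidal quadrature on the data grid;
* ``pure_nn`` — the hybrid pipeline with g = 0 (the entire right-hand side
  learned by the network).

All four consume the same ``TrajectoryDataset`` and emit the same
``RankedModelReport`` as the hybrid pipeline, so comparisons are
apples-to-apples.  The finite-difference methods have no step-size
hyperparameter, as they do not interpolate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .hybrid_model import HybridODERegressor, KnownPart
from .model_selection import (
    Candidate,
    RankedModelReport,
    SelectionGrid,
    _safe_aicc,
    model_rss,
    rank_candidates,
    select_models,
)
from .ode_models import ODESystem, Trajectory, ValidationError
from .sparse_regression import SymbolicModel, build_library, stlsq
from .synthetic_data import TrajectoryDataset

__all__ = [
    "DerivativeEstimate",
    "finite_difference",
    "base_sindy",
    "base_known",
    "weak_sindy",
    "pure_nn",
]


@dataclass
class DerivativeEstimate:
    times: np.ndarray
    values: np.ndarray
    method: str


def finite_difference(traj: Trajectory) -> DerivativeEstimate:
    """Second-order centered differences (one-sided second-order at the ends).

    Exact for polynomial trajectories up to degree 2; requires a uniform
    grid of at least 3 points.
    """
    if traj.n_points < 3:
        raise ValidationError("finite differences need at least 3 time points")
    steps = np.diff(traj.times)
    if not np.allclose(steps, steps[0], rtol=1e-8):
        raise ValidationError("finite differences require a uniform grid")
    values = np.gradient(traj.states, float(steps[0]), axis=0, edge_order=2)
    return DerivativeEstimate(times=traj.times, values=values, method="finite_difference")


def _score_candidates(
    dataset: TrajectoryDataset,
    known: KnownPart,
    theta_by_lib,
    targets: np.ndarray,
    library_names: Sequence[str],
    alphas: Sequence[float],
    threshold: float,
    truth: ODESystem | None,
) -> RankedModelReport:
    from .model_selection import topology_correct

    n_val = len(dataset.validation)
    species = dataset.species_names or [f"x{i + 1}" for i in range(dataset.d)]
    candidates = []
    for lib_name in library_names:
        library, theta = theta_by_lib[lib_name]
        for alpha in alphas:
            coefs = stlsq(theta, targets, alpha=alpha, threshold=threshold, library=library)
            model = SymbolicModel(known=known, coefficients=coefs, species_names=species)
            rss = model_rss(model, dataset.validation)
            score = _safe_aicc(rss, n_val, model.k)
            candidates.append(
                Candidate(
                    model=model,
                    dt=None,
                    library_name=lib_name,
                    alpha=alpha,
                    k=model.k,
                    rss=rss,
                    aicc=score,
                    success=np.isfinite(score),
                    topology_correct=(
                        topology_correct(model, truth) if truth is not None else None
                    ),
                )
            )
    return rank_candidates(candidates)


def base_known(
    dataset: TrajectoryDataset,
    known: KnownPart,
    library_names: Sequence[str],
    alphas: Sequence[float],
    threshold: float,
    truth: ODESystem | None = None,
) -> RankedModelReport:
    """Finite-difference SINDy with the known terms subtracted from X'."""
    states = np.concatenate([t.states for t in dataset.train], axis=0)
    derivs = np.concatenate(
        [finite_difference(t).values for t in dataset.train], axis=0
    )
    targets = derivs - known.f(states)
    theta_by_lib = {}
    for name in library_names:
        lib = build_library(name, dataset.d)
        theta_by_lib[name] = (lib, lib.transform(states))
    return _score_candidates(
        dataset, known, theta_by_lib, targets, library_names, alphas, threshold, truth
    )


def base_sindy(
    dataset: TrajectoryDataset,
    library_names: Sequence[str],
    alphas: Sequence[float],
    threshold: float,
    truth: ODESystem | None = None,
) -> RankedModelReport:
    """Single-step SINDy: finite-difference derivatives, no prior knowledge."""
    return base_known(
        dataset, KnownPart.zero(dataset.d), library_names, alphas, threshold, truth
    )


# ---------------------------------------------------------------------------
# weak-form SINDy


def _test_function_windows(n_points: int, n_windows: int, min_length: int, rng):
    """Random subwindow index pairs (a, b) with b - a >= min_length."""
    pairs = []
    for _ in range(n_windows):
        a = int(rng.integers(0, n_points - min_length))
        b = int(rng.integers(a + min_length, n_points))
        pairs.append((a, b))
    return pairs


def weak_features(
    traj: Trajectory,
    library,
    windows: list[tuple[int, int]],
    poly_order: int = 3,
):
    """Weak-form feature rows for one sample.

    For each subwindow [t_a, t_b] and bump test function
    ``phi(t) = ((t - t_a)(t_b - t))^p`` (zero at and outside the ends,
    normalized to unit maximum), returns

        lhs_k = -integral(phi' x) dt      (the integrated left side)
        rhs_k = integral(phi Theta(x)) dt

    via trapezoidal quadrature on the data grid.
    """
    t = traj.times
    theta = library.transform(traj.states)
    lhs_rows, rhs_rows = [], []
    p = poly_order
    for a, b in windows:
        ta, tb = t[a], t[b]
        ts = t[a : b + 1]
        u = (ts - ta) * (tb - ts)
        norm = ((tb - ta) ** 2 / 4.0) ** p  # max of u^p at the midpoint
        phi = u**p / norm
        dphi = p * u ** (p - 1) * ((tb - ts) - (ts - ta)) / norm
        x_seg = traj.states[a : b + 1]
        th_seg = theta[a : b + 1]
        lhs_rows.append(-np.trapezoid(dphi[:, None] * x_seg, ts, axis=0))
        rhs_rows.append(np.trapezoid(phi[:, None, None] * th_seg[:, None, :], ts, axis=0)[0])
    return np.stack(lhs_rows), np.stack(rhs_rows)


def weak_sindy(
    dataset: TrajectoryDataset,
    library_names: Sequence[str],
    alphas: Sequence[float],
    threshold: float,
    n_windows: int = 100,
    poly_order: int = 3,
    min_length: int | None = None,
    seed: int = 0,
    truth: ODESystem | None = None,
) -> RankedModelReport:
    """SINDy on the weak formulation of the ODE system (no derivatives).

    ``n_windows`` random subwindows per training sample define the test
    functions; defaults are polynomial bumps of order 3 with a minimum
    subwindow length of a quarter of the trajectory.
    """
    n_points = dataset.train[0].n_points
    if min_length is None:
        min_length = max(4, n_points // 4)
    if min_length >= n_points:
        raise ValidationError("subwindow longer than trajectory")
    rng = np.random.default_rng(seed)
    theta_by_lib = {}
    lhs_all = None
    for name in library_names:
        lib = build_library(name, dataset.d)
        lhs_rows, rhs_rows = [], []
        rng_lib = np.random.default_rng(seed)  # same windows for every library
        for traj in dataset.train:
            wins = _test_function_windows(n_points, n_windows, min_length, rng_lib)
            lhs, rhs = weak_features(traj, lib, wins, poly_order)
            lhs_rows.append(lhs)
            rhs_rows.append(rhs)
        lhs_all = np.concatenate(lhs_rows, axis=0)
        theta_by_lib[name] = (lib, np.concatenate(rhs_rows, axis=0))
    known = KnownPart.zero(dataset.d)
    return _score_candidates(
        dataset, known, theta_by_lib, lhs_all, library_names, alphas, threshold, truth
    )


def pure_nn(
    dataset: TrajectoryDataset,
    selection_grid: SelectionGrid,
    hidden_layers: tuple[int, ...] = (8,),
    window: int = 5,
    batch_size: int = 5,
    lr: float = 0.01,
    epochs: int = 10,
    init_seed: int = 0,
    shuffle_seed: int = 0,
    truth: ODESystem | None = None,
) -> tuple[HybridODERegressor, RankedModelReport]:
    """The hybrid pipeline with g = 0: x' = NN(x), then stage-2 selection."""
    model = HybridODERegressor(
        known=KnownPart.zero(dataset.d),
        hidden_layers=hidden_layers,
        window=window,
        batch_size=batch_size,
        lr=lr,
        epochs=epochs,
        init_seed=init_seed,
        shuffle_seed=shuffle_seed,
    ).fit(dataset)
    report = select_models(model, dataset, selection_grid, truth=truth)
    return model, report
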