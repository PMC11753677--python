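"""Basis libraries, STLSQ sparse regression, and symbolic model assembly.

The discovered model has the form ``f(x) = g(x) + Theta(x) Xi`` where
``Theta`` is an ordered library of candidate basis functions (monomials
and/or Hill repression terms ``1/(1+x_i^n)``) and ``Xi`` is a sparse
coefficient matrix found by Sequentially Thresholded Least Squares:
alternating ridge regression on the active columns with hard thresholding
of coefficients smaller than ``threshold`` until the active set is stable.

Library names follow the field's compact convention:

``poly_max_2``
    all monomials of degree <= 2 (bias included);
``poly_2_3`` / ``poly_1_2``
    monomials of exactly those degrees (no bias);
``hill_n``
    ``1/(1+x_i^n)`` for every species, fixed order ``n``;
``hill_max_n``
    Hill terms of all orders 1..n;
``hill_<n>_poly_1`` / ``hill_<n>_poly_xy`` / ``hill_<n>_poly_1_2``
    Hill terms of order n (or up to n with ``hill_max_<n>_...``) plus
    linear terms / linear+pairwise products / degree-1-and-2 monomials.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from itertools import combinations, combinations_with_replacement
from typing import Callable

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from ._integrate import auto_substeps, rk4_path
from .ode_models import ODESystem, Trajectory, ValidationError
from .synthetic_data import TrajectoryDataset

__all__ = [
    "BasisLibrary",
    "CoefficientMatrix",
    "RegressionData",
    "SymbolicModel",
    "build_library",
    "STLSQ",
    "stlsq",
    "simulate_regression_data",
    "assemble_model",
]


# ---------------------------------------------------------------------------
# basis libraries


@dataclass
class BasisLibrary:
    """Ordered, labelled set of scalar candidate functions of the state."""

    name: str
    labels: list[str]
    functions: list[Callable[[np.ndarray], np.ndarray]]
    d: int

    def __post_init__(self):
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("basis labels must be unique")

    @property
    def size(self) -> int:
        return len(self.functions)

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Evaluate all basis functions: (..., d) -> (..., m)."""
        X = np.asarray(X, dtype=float)
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            cols = [f(X) for f in self.functions]
        return np.stack(cols, axis=-1)


def _monomial(exponents: tuple[int, ...]):
    idx = [i for i, e in enumerate(exponents) if e > 0]
    exp = [exponents[i] for i in idx]

    def f(X, idx=tuple(idx), exp=tuple(exp)):
        out = np.ones(X.shape[:-1])
        for i, e in zip(idx, exp):
            out = out * X[..., i] ** e
        return out

    if not idx:
        return "1", f
    label = "*".join(
        f"x{i + 1}" if e == 1 else f"x{i + 1}^{e}" for i, e in zip(idx, exp)
    )
    return label, f


def _poly_terms(d: int, degrees: list[int]):
    labels, funcs = [], []
    for deg in degrees:
        for combo in combinations_with_replacement(range(d), deg):
            exponents = tuple(combo.count(i) for i in range(d))
            label, f = _monomial(exponents)
            labels.append(label)
            funcs.append(f)
    return labels, funcs


def _hill_terms(d: int, orders: list[int]):
    labels, funcs = [], []
    for n in orders:
        for i in range(d):
            def f(X, i=i, n=n):
                return 1.0 / (1.0 + X[..., i] ** n)

            labels.append(f"hill{n}(x{i + 1})")
            funcs.append(f)
    return labels, funcs


def _xy_terms(d: int):
    labels, funcs = [], []
    for i, j in combinations(range(d), 2):
        exponents = tuple(1 if k in (i, j) else 0 for k in range(d))
        label, f = _monomial(exponents)
        labels.append(label)
        funcs.append(f)
    return labels, funcs


def build_library(name: str, d: int) -> BasisLibrary:
    """Construct a named basis library for a d-dimensional state."""
    if d < 1:
        raise ValidationError("d must be >= 1")
    labels: list[str] = []
    funcs: list[Callable] = []

    m = re.fullmatch(r"poly_max_(\d+)", name)
    if m:
        order = int(m.group(1))
        labels, funcs = _poly_terms(d, list(range(order + 1)))
        return BasisLibrary(name, labels, funcs, d)

    m = re.fullmatch(r"poly_(\d+)_(\d+)", name)
    if m:
        lo, hi = int(m.group(1)), int(m.group(2))
        if lo > hi:
            raise ValidationError(f"bad polynomial degree range in {name!r}")
        labels, funcs = _poly_terms(d, list(range(lo, hi + 1)))
        return BasisLibrary(name, labels, funcs, d)

    m = re.fullmatch(r"hill(_max)?_(\d+)(?:_poly_(1_2|xy|1))?", name)
    if m:
        max_flag, order, poly_part = m.group(1), int(m.group(2)), m.group(3)
        orders = list(range(1, order + 1)) if max_flag else [order]
        labels, funcs = _hill_terms(d, orders)
        if poly_part == "1":
            l2, f2 = _poly_terms(d, [1])
        elif poly_part == "xy":
            l1, f1 = _poly_terms(d, [1])
            lx, fx = _xy_terms(d)
            l2, f2 = l1 + lx, f1 + fx
        elif poly_part == "1_2":
            l2, f2 = _poly_terms(d, [1, 2])
        else:
            l2, f2 = [], []
        return BasisLibrary(name, labels + l2, funcs + f2, d)

    raise ValidationError(f"unknown basis library name {name!r}")


# ---------------------------------------------------------------------------
# STLSQ


class STLSQ(BaseEstimator, RegressorMixin):
    """Sequentially Thresholded Least Squares.

    Per target dimension: solve a ridge regression restricted to the active
    columns, zero every coefficient with ``|c| < threshold``, shrink the
    active set, and repeat until the active set is stable (or ``max_iter``).
    With ``alpha = threshold = 0`` this reduces to ordinary least squares.
    Ridge regularization is applied to the raw (unstandardized) columns, so
    thresholds are on natural coefficient scales.

    Attributes
    ----------
    coef_ : ndarray, shape (n_targets, n_features)
    n_iter_ : list of int, iterations per target dimension.
    """

    def __init__(self, threshold: float = 0.1, alpha: float = 0.05, max_iter: int = 20):
        self.threshold = threshold
        self.alpha = alpha
        self.max_iter = max_iter

    @staticmethod
    def _ridge(X: np.ndarray, y: np.ndarray, alpha: float) -> np.ndarray:
        if alpha > 0:
            m = X.shape[1]
            A = np.vstack([X, np.sqrt(alpha) * np.eye(m)])
            b = np.concatenate([y, np.zeros(m)])
        else:
            A, b = X, y
        return np.linalg.lstsq(A, b, rcond=None)[0]

    def fit(self, X: np.ndarray, y: np.ndarray) -> "STLSQ":
        if self.alpha < 0 or self.threshold < 0:
            raise ValidationError("alpha and threshold must be non-negative")
        X = np.asarray(X, dtype=float)
        Y = np.asarray(y, dtype=float)
        squeeze = Y.ndim == 1
        if squeeze:
            Y = Y[:, None]
        n, m = X.shape
        coef = np.zeros((Y.shape[1], m))
        n_iter = []
        for j in range(Y.shape[1]):
            active = np.ones(m, dtype=bool)
            it = 0
            c = np.zeros(m)
            while it < self.max_iter:
                it += 1
                c = np.zeros(m)
                c[active] = self._ridge(X[:, active], Y[:, j], self.alpha)
                keep = active & (np.abs(c) >= self.threshold)
                if not keep.any():
                    warnings.warn(
                        f"STLSQ: all coefficients thresholded out for target {j}"
                    )
                    c = np.zeros(m)
                    active = keep
                    break
                c[~keep] = 0.0
                if (keep == active).all():
                    break
                active = keep
            coef[j] = c
            n_iter.append(it)
        self.coef_ = coef[0] if squeeze else coef
        self.n_iter_ = n_iter
        self.n_features_in_ = m
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        coef = np.atleast_2d(self.coef_)
        out = np.asarray(X, dtype=float) @ coef.T
        return out[:, 0] if np.ndim(self.coef_) == 1 else out


@dataclass
class CoefficientMatrix:
    """Sparse coefficient matrix Xi (library size x d) with its library."""

    values: np.ndarray
    library: BasisLibrary

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != self.library.size:
            raise ValidationError("coefficient rows must match library size")

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.values))


def stlsq(
    theta: np.ndarray,
    targets: np.ndarray,
    alpha: float,
    threshold: float,
    max_iter: int = 20,
    library: BasisLibrary | None = None,
) -> np.ndarray | CoefficientMatrix:
    """Functional STLSQ on row-stacked data; returns the (m, d) matrix, or a
    :class:`CoefficientMatrix` when ``library`` is given."""
    est = STLSQ(threshold=threshold, alpha=alpha, max_iter=max_iter).fit(theta, targets)
    values = np.atleast_2d(est.coef_).T
    if library is not None:
        return CoefficientMatrix(values=values, library=library)
    return values


# ---------------------------------------------------------------------------
# regression data from a fitted hybrid model


@dataclass
class RegressionData:
    """Hybrid-model simulations and matching NN targets for sparse regression."""

    trajectories: list[Trajectory]
    targets: list[np.ndarray]
    dt: float

    @property
    def states_stacked(self) -> np.ndarray:
        return np.concatenate([t.states for t in self.trajectories], axis=0)

    @property
    def targets_stacked(self) -> np.ndarray:
        return np.concatenate(self.targets, axis=0)


def simulate_regression_data(
    model,
    dataset: TrajectoryDataset,
    dt: float,
    substeps: int | None = None,
    initial_conditions: np.ndarray | None = None,
) -> RegressionData:
    """Re-simulate the fitted hybrid model over the training span at step ``dt``.

    One trajectory per training-sample initial condition (the sample's first
    observation) by default; targets are NN(x) evaluated pointwise on the
    simulated states, which may be finer-resolved than the data.  Diverging
    initial conditions are dropped with a warning.
    """
    if dt <= 0:
        raise ValidationError("dt must be positive")
    t = dataset.train_times
    n_out = int(round((t[-1] - t[0]) / dt)) + 1
    times = t[0] + dt * np.arange(n_out)
    if initial_conditions is None:
        initial_conditions = np.stack([traj.states[0] for traj in dataset.train])
    substeps = substeps or auto_substeps(dt)
    paths = rk4_path(model.rhs, initial_conditions, times, substeps=substeps)
    trajectories, targets = [], []
    n_dropped = 0
    for i in range(paths.shape[0]):
        states = paths[i]
        if not np.all(np.isfinite(states)):
            n_dropped += 1
            continue
        trajectories.append(Trajectory(times=times, states=states))
        targets.append(model.nn(states))
    if n_dropped:
        warnings.warn(f"simulate_regression_data: dropped {n_dropped} diverging trajectories")
    if not trajectories:
        raise ValidationError("all regression trajectories diverged")
    return RegressionData(trajectories=trajectories, targets=targets, dt=dt)


# ---------------------------------------------------------------------------
# symbolic model assembly


_HILL_RE = re.compile(r"hill(\d+)\(x(\d+)\)")


def _render_term(coeff: float, label: str, first: bool) -> str:
    sign = "-" if coeff < 0 else ("" if first else "+")
    mag = abs(coeff)
    m = _HILL_RE.fullmatch(label)
    if m:
        body = f"{mag:.3f}/(1+x{m.group(2)}^{m.group(1)})"
    elif label == "1":
        body = f"{mag:.3f}"
    else:
        body = f"{mag:.3f}*{label}"
    return f"{sign}{body}" if first else f" {sign} {body}".replace("  ", " ")


@dataclass
class SymbolicModel:
    """Discovered ODE model f(x) = g(x) + Theta(x) Xi, printable and simulatable."""

    known: "KnownPart"
    coefficients: CoefficientMatrix
    species_names: list[str]

    def __post_init__(self):
        if self.coefficients.values.shape[1] != len(self.species_names):
            raise ValidationError("coefficient columns must match species count")

    @property
    def d(self) -> int:
        return len(self.species_names)

    @property
    def k(self) -> int:
        """Number of learned nonzero coefficients (known terms are free)."""
        return self.coefficients.n_nonzero

    def rhs(self, x: np.ndarray) -> np.ndarray:
        theta = self.coefficients.library.transform(x)
        return self.known.f(x) + theta @ self.coefficients.values

    def learned_terms(self) -> list[list[tuple[str, float]]]:
        lib = self.coefficients.library
        vals = self.coefficients.values
        out = []
        for j in range(self.d):
            nz = np.nonzero(vals[:, j])[0]
            out.append([(lib.labels[i], float(vals[i, j])) for i in nz])
        return out

    def net_terms(self) -> list[dict[str, float]]:
        """Known + learned terms combined per equation (coefficients summed)."""
        combined: list[dict[str, float]] = []
        learned = self.learned_terms()
        for j in range(self.d):
            acc: dict[str, float] = {}
            for label, c in list(self.known.terms[j]) + learned[j]:
                acc[label] = acc.get(label, 0.0) + c
            combined.append({k: v for k, v in acc.items() if abs(v) > 1e-12})
        return combined

    def term_signs(self) -> list[set[tuple[str, int]]]:
        """Per-equation sets of (label, sign) for topology comparison."""
        return [
            {(label, 1 if c > 0 else -1) for label, c in eq.items()}
            for eq in self.net_terms()
        ]

    def equations_text(self) -> str:
        lines = []
        learned = self.learned_terms()
        for j, name in enumerate(self.species_names):
            terms = list(self.known.terms[j]) + learned[j]
            if not terms:
                lines.append(f"{name}' = 0")
                continue
            parts = [_render_term(c, lab, i == 0) for i, (lab, c) in enumerate(terms)]
            lines.append(f"{name}' = " + "".join(parts))
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        learned = self.learned_terms()
        eqs = []
        for j, name in enumerate(self.species_names):
            eq = [
                {"label": lab, "coefficient": c, "fixed": True}
                for lab, c in self.known.terms[j]
            ] + [
                {"label": lab, "coefficient": c, "fixed": False} for lab, c in learned[j]
            ]
            eqs.append({"species": name, "terms": eq})
        return {"library": self.coefficients.library.name, "equations": eqs}

    def to_ode_system(self) -> ODESystem:
        terms = [
            [(label, c) for label, c in eq.items()] for eq in self.net_terms()
        ]
        return ODESystem(
            species_names=list(self.species_names),
            rhs=self.rhs,
            params={},
            d=self.d,
            name="discovered",
            terms=terms,
        )


def assemble_model(known, coefficients: CoefficientMatrix, species_names=None) -> SymbolicModel:
    """Combine the known part and a learned coefficient matrix into a model."""
    d = coefficients.values.shape[1]
    if species_names is None:
        species_names = [f"x{i + 1}" for i in range(d)]
    return SymbolicModel(known=known, coefficients=coefficients, species_names=list(species_names))
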