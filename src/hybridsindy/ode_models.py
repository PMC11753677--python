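"""Benchmark ODE systems and high-accuracy simulation.

This module defines the ground-truth dynamical systems used throughout the
package: the Lotka-Volterra predator-prey model and the repressilator (a
three-gene synthetic oscillator in which each protein represses the next in
a cycle).  Systems carry, alongside their vectorized right-hand side, a
symbolic term list (label, coefficient) per equation which serves as the
reference for topology-correctness checks of discovered models.

Term-label conventions (shared with :mod:`hybridsindy.sparse_regression`):

* monomials: ``"1"``, ``"x1"``, ``"x1^2"``, ``"x1*x2"`` (species indices
  ascending, 1-based);
* Hill repression terms ``1/(1+x_i^n)``: ``"hill{n}(x{i})"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "ValidationError",
    "IntegrationError",
    "SimulationGrid",
    "Trajectory",
    "ODESystem",
    "lotka_volterra",
    "repressilator",
    "simulate",
]


class ValidationError(ValueError):
    """Raised when inputs violate a documented precondition."""


class IntegrationError(RuntimeError):
    """Raised when an ODE solve fails (blow-up, step-count exhaustion).

    Attributes
    ----------
    last_valid_time : float
        The last time point the solver reached before failing.
    """

    def __init__(self, message: str, last_valid_time: float):
        super().__init__(message)
        self.last_valid_time = last_valid_time


@dataclass(frozen=True)
class SimulationGrid:
    """Uniform time grid on the closed interval ``[t_start, t_end]``.

    The number of points is ``round((t_end - t_start) / dt) + 1`` so both
    endpoints are included.  A degenerate grid with ``t_end == t_start`` is
    allowed and has a single point.
    """

    t_start: float
    t_end: float
    dt: float

    def __post_init__(self):
        if not self.dt > 0:
            raise ValidationError(f"dt must be positive, got {self.dt}")
        if self.t_end < self.t_start:
            raise ValidationError("t_end must be >= t_start")

    @property
    def n_points(self) -> int:
        return int(round((self.t_end - self.t_start) / self.dt)) + 1

    @property
    def times(self) -> np.ndarray:
        return self.t_start + self.dt * np.arange(self.n_points)


@dataclass
class Trajectory:
    """Sampled states of a single realization on a fixed time grid."""

    times: np.ndarray
    states: np.ndarray  # shape (n_points, d)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.ndim != 2 or self.states.shape[0] != self.times.shape[0]:
            raise ValidationError("states must be (len(times), d)")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValidationError("times must be strictly increasing")
        if not np.all(np.isfinite(self.states)):
            raise ValidationError("states must be finite")

    @property
    def n_points(self) -> int:
        return self.times.shape[0]

    @property
    def d(self) -> int:
        return self.states.shape[1]


@dataclass
class ODESystem:
    """Autonomous ODE system ``x' = rhs(x)`` with named species and parameters.

    ``rhs`` must be vectorized over leading axes: input shape ``(..., d)``,
    output shape ``(..., d)``.  ``terms`` optionally records the symbolic
    form of each equation as a list (per species) of ``(label, coefficient)``
    pairs; it is the ground truth for topology checks.
    """

    species_names: list[str]
    rhs: Callable[[np.ndarray], np.ndarray]
    params: dict[str, float]
    d: int
    name: str = ""
    terms: list[list[tuple[str, float]]] | None = field(default=None)

    def __post_init__(self):
        if len(self.species_names) != self.d:
            raise ValidationError("species_names length must equal d")
        for key, value in self.params.items():
            if not np.isfinite(value):
                raise ValidationError(f"parameter {key!r} is not finite")
        probe = self.rhs(np.ones(self.d))
        if np.shape(probe) != (self.d,):
            raise ValidationError("rhs output dimension must equal d")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.rhs(x)


def lotka_volterra(params: dict[str, float] | None = None, **kwargs) -> ODESystem:
    """Two-species predator-prey model.

    .. math::

        x_1' = \\alpha x_1 - \\beta x_1 x_2, \\qquad
        x_2' = \\gamma x_1 x_2 - \\delta x_2

    where ``x1`` is the prey and ``x2`` the predator population.  All four
    rates must be present and positive.
    """
    p = dict(params or {})
    p.update(kwargs)
    required = ("alpha", "beta", "gamma", "delta")
    for name in required:
        if name not in p:
            raise ValidationError(f"missing Lotka-Volterra parameter {name!r}")
        if not (np.isfinite(p[name]) and p[name] > 0):
            raise ValidationError(f"parameter {name!r} must be positive")
    a, b, g, d_ = (float(p[n]) for n in required)

    def rhs(x):
        x = np.asarray(x, dtype=float)
        x1, x2 = x[..., 0], x[..., 1]
        return np.stack([a * x1 - b * x1 * x2, g * x1 * x2 - d_ * x2], axis=-1)

    terms = [
        [("x1", a), ("x1*x2", -b)],
        [("x1*x2", g), ("x2", -d_)],
    ]
    return ODESystem(
        species_names=["x1", "x2"],
        rhs=rhs,
        params={n: float(p[n]) for n in required},
        d=2,
        name="lotka_volterra",
        terms=terms,
    )


def repressilator(
    beta: float | Sequence[float] = 10.0,
    n: int | Sequence[int] = 3,
    gamma: float = 1.0,
) -> ODESystem:
    """Three-gene cyclic repression oscillator.

    .. math::

        x_i' = \\frac{\\beta_i}{1 + x_{i-1}^{n_i}} - \\gamma x_i

    Species ``i`` is repressed by species ``i-1`` cyclically (x1 by x3,
    x2 by x1, x3 by x2).  The half-maximal constant is fixed at ``k = 1``
    and is not configurable.  ``beta`` and ``n`` may be scalars (symmetric
    system) or length-3 sequences (asymmetric system).
    """
    beta_vec = np.broadcast_to(np.asarray(beta, dtype=float), (3,)).copy()
    n_arr = np.broadcast_to(np.asarray(n), (3,)).copy()
    if not np.all(n_arr == np.floor(n_arr)):
        raise ValidationError("Hill order n must be a positive integer")
    n_vec = n_arr.astype(int)
    if np.any(n_vec < 1):
        raise ValidationError("Hill order n must be >= 1")
    if np.any(beta_vec <= 0) or gamma <= 0:
        raise ValidationError("beta and gamma must be positive")

    prev = np.array([2, 0, 1])  # repressor of each species

    def rhs(x):
        x = np.asarray(x, dtype=float)
        cols = [
            beta_vec[i] / (1.0 + x[..., prev[i]] ** n_vec[i]) - gamma * x[..., i]
            for i in range(3)
        ]
        return np.stack(cols, axis=-1)

    terms = [
        [(f"hill{n_vec[i]}(x{prev[i] + 1})", float(beta_vec[i])), (f"x{i + 1}", -float(gamma))]
        for i in range(3)
    ]
    params = {f"beta{i + 1}": float(beta_vec[i]) for i in range(3)}
    params.update({f"n{i + 1}": float(n_vec[i]) for i in range(3)})
    params["gamma"] = float(gamma)
    return ODESystem(
        species_names=["x1", "x2", "x3"],
        rhs=rhs,
        params=params,
        d=3,
        name="repressilator",
        terms=terms,
    )


def simulate(
    system: ODESystem,
    x0: Sequence[float],
    grid: SimulationGrid,
    rtol: float = 1e-8,
    atol: float = 1e-8,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate ``system`` from ``x0`` and sample it exactly on ``grid``.

    Uses an adaptive solver with stiffness handling (LSODA by default) at
    tight tolerances; ground-truth trajectories must be accurate enough
    that observation noise dominates integration error even at the 0.1%
    noise level.
    """
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (system.d,) or not np.all(np.isfinite(x0)):
        raise ValidationError("x0 must be a finite d-vector")
    for tol in (rtol, atol):
        if not (0 < tol < 1):
            raise ValidationError("tolerances must lie in (0, 1)")
    times = grid.times
    if times.size == 1:
        return Trajectory(times=times, states=x0[None, :])

    # Abort immediately on blow-up: adaptive solvers can otherwise spend
    # essentially unbounded time shrinking steps against a singularity.
    last_t = [float(times[0])]

    class _BlowUp(Exception):
        pass

    def fun(t, x):
        if not np.all(np.isfinite(x)) or np.max(np.abs(x)) > 1e12:
            raise _BlowUp
        last_t[0] = float(t)
        return system.rhs(x)

    try:
        sol = solve_ivp(
            fun,
            (times[0], times[-1]),
            x0,
            method=method,
            t_eval=times,
            rtol=rtol,
            atol=atol,
        )
    except _BlowUp:
        raise IntegrationError(
            "ODE solve failed: state blow-up", last_valid_time=last_t[0]
        ) from None
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else float(times[0])
        raise IntegrationError(f"ODE solve failed: {sol.message}", last_valid_time=last)
    states = sol.y.T
    if not np.all(np.isfinite(states)):
        raise IntegrationError("non-finite states in solution", last_valid_time=float(times[-1]))
    return Trajectory(times=times, states=states)
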