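"""Stage-2 model selection: AICc scoring and ranking of candidate models.

Every combination of (simulation step, basis library, ridge parameter) in
the selection grid yields one candidate symbolic model.  Each candidate is
simulated per validation sample over the training span (from the sample's
own first observation) and scored by the small-sample-corrected Akaike
information criterion

    AICc = n ln(RSS/n) + 2k + 2(k+1)(k+2)/(n-k-2),

where n is the number of validation samples, RSS the summed squared
residuals over all samples/time points/species, and k the number of learned
nonzero coefficients (known terms are free, since they are not estimated).
The candidate with the lowest AICc is the selected model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._integrate import auto_substeps, rk4_path
from .ode_models import ODESystem, Trajectory, ValidationError
from .sparse_regression import (
    SymbolicModel,
    build_library,
    simulate_regression_data,
    stlsq,
)
from .synthetic_data import TrajectoryDataset

__all__ = [
    "aicc",
    "model_rss",
    "SelectionGrid",
    "Candidate",
    "RankedModelReport",
    "rank_candidates",
    "select_models",
    "topology_correct",
]


def aicc(rss: float, n: int, k: int) -> float:
    """Akaike information criterion with small-sample correction.

    ``n`` is the number of validation samples.  Requires ``n > k + 2`` so
    the correction denominator is positive.  ``rss = 0`` returns ``-inf``
    with a warning (a perfect fit dominates any ranking).
    """
    if rss < 0:
        raise ValidationError("rss must be non-negative")
    if n <= k + 2:
        raise ValidationError(f"AICc undefined: need n > k + 2 (n={n}, k={k})")
    if rss == 0:
        warnings.warn("AICc: zero RSS, returning -inf")
        return -np.inf
    if not np.isfinite(rss):
        return np.inf
    return float(n * np.log(rss / n) + 2 * k + 2 * (k + 1) * (k + 2) / (n - k - 2))


def _safe_aicc(rss: float, n: int, k: int) -> float:
    """AICc for candidate scoring: +inf (ranked last) when the model has too
    many parameters for the validation budget or failed to simulate."""
    if not np.isfinite(rss) or n <= k + 2:
        return np.inf
    return aicc(rss, n, k)


def model_rss(
    model: SymbolicModel | ODESystem,
    validation: list[Trajectory],
    substeps: int | None = None,
) -> float:
    """Residual sum of squares of model-predicted dynamics on validation data.

    Each sample is simulated from its own first observation at the observed
    grid times; residuals are summed over samples, time points and species.
    A diverging simulation yields +inf (the candidate ranks last).
    """
    if not validation:
        raise ValidationError("validation set must be non-empty")
    times = validation[0].times
    dt = float(times[1] - times[0]) if times.size > 1 else 1.0
    substeps = substeps or auto_substeps(dt)
    x0 = np.stack([traj.states[0] for traj in validation])
    rhs = model.rhs if not isinstance(model, ODESystem) else model.rhs
    preds = rk4_path(rhs, x0, times, substeps=substeps)
    obs = np.stack([traj.states for traj in validation])
    with np.errstate(over="ignore", invalid="ignore"):
        per_sample = np.sum((preds - obs) ** 2, axis=(1, 2))
    if not np.all(np.isfinite(per_sample)):
        return np.inf
    return float(np.sum(per_sample))


@dataclass(frozen=True)
class SelectionGrid:
    """Stage-2 hyperparameter grid: simulation steps, libraries, ridge alphas."""

    dt_values: tuple[float, ...]
    library_names: tuple[str, ...]
    alpha_values: tuple[float, ...]
    threshold: float
    max_iter: int = 20

    def __post_init__(self):
        if not (self.dt_values and self.library_names and self.alpha_values):
            raise ValidationError("selection grid lists must be non-empty")


@dataclass
class Candidate:
    """One scored candidate model from the stage-2 grid."""

    model: SymbolicModel
    dt: float | None
    library_name: str
    alpha: float
    k: int
    rss: float
    aicc: float
    success: bool
    topology_correct: bool | None = None
    extra: dict = field(default_factory=dict)


class RankedModelReport:
    """Candidates sorted ascending by AICc, with a tabular view."""

    def __init__(self, candidates: list[Candidate]):
        if not candidates:
            raise ValidationError("no candidates to rank")
        self.candidates = sorted(candidates, key=lambda c: (c.aicc, c.rss))

    @property
    def best(self) -> Candidate:
        return self.candidates[0]

    def table(self) -> pd.DataFrame:
        rows = []
        for rank, c in enumerate(self.candidates, start=1):
            rows.append(
                {
                    "rank": rank,
                    "dt": c.dt,
                    "library": c.library_name,
                    "alpha": c.alpha,
                    "k": c.k,
                    "rss": c.rss,
                    "aicc": c.aicc,
                    "success": c.success,
                    "topology_correct": c.topology_correct,
                    "equations": c.model.equations_text().replace("\n", " ; "),
                }
            )
        return pd.DataFrame(rows)

    def top(self, n: int = 10) -> list[Candidate]:
        return self.candidates[:n]


def rank_candidates(candidates: list[Candidate]) -> RankedModelReport:
    if all(not c.success for c in candidates):
        raise ValidationError("all candidate models failed")
    return RankedModelReport(candidates)


def select_models(
    fitted,
    dataset: TrajectoryDataset,
    grid: SelectionGrid,
    truth: ODESystem | None = None,
) -> RankedModelReport:
    """Run STLSQ for every grid cell and rank the candidates by AICc.

    ``fitted`` is a trained :class:`~hybridsindy.hybrid_model.HybridODERegressor`;
    regression inputs are its simulations over the training span at each
    candidate step size, and targets are NN evaluated on those states.
    When ``truth`` (with symbolic terms) is given, each candidate carries a
    topology-correctness flag.
    """
    n_val = len(dataset.validation)
    candidates: list[Candidate] = []
    for dt in grid.dt_values:
        regdata = simulate_regression_data(fitted, dataset, dt)
        states = regdata.states_stacked
        targets = regdata.targets_stacked
        for lib_name in grid.library_names:
            library = build_library(lib_name, dataset.d)
            theta = library.transform(states)
            for alpha in grid.alpha_values:
                coefs = stlsq(
                    theta, targets, alpha=alpha, threshold=grid.threshold,
                    max_iter=grid.max_iter, library=library,
                )
                model = SymbolicModel(
                    known=fitted.known_,
                    coefficients=coefs,
                    species_names=dataset.species_names
                    or [f"x{i + 1}" for i in range(dataset.d)],
                )
                rss = model_rss(model, dataset.validation)
                k = model.k
                score = _safe_aicc(rss, n_val, k)
                candidates.append(
                    Candidate(
                        model=model,
                        dt=dt,
                        library_name=lib_name,
                        alpha=alpha,
                        k=k,
                        rss=rss,
                        aicc=score,
                        success=np.isfinite(score),
                        topology_correct=(
                            topology_correct(model, truth) if truth is not None else None
                        ),
                    )
                )
    return rank_candidates(candidates)


def topology_correct(candidate: SymbolicModel, truth: ODESystem) -> bool:
    """True iff the candidate's nonzero term labels and signs per equation
    (known + learned combined) exactly match the ground truth's.

    Coefficient magnitudes are not compared; a term matches only if its
    sign matches.  The truth system must carry symbolic ``terms``.
    """
    if truth.terms is None:
        raise ValidationError("truth system carries no symbolic terms")
    if candidate.d != truth.d:
        raise ValidationError("dimension mismatch between candidate and truth")
    truth_signs = [
        {(label, 1 if c > 0 else -1) for label, c in eq} for eq in truth.terms
    ]
    return candidate.term_signs() == truth_signs
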