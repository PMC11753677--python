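"""Cell-state proportion trajectories and their model discovery.

The epithelial-mesenchymal transition (EMT) is summarized here as the
proportions of three cell states — epithelial (E), intermediate (I) and
mesenchymal (M) — across pseudotime bins.  Replicate trajectories are
sampled around per-bin median proportions from truncated Gaussians: each
draw is constrained to lie within one standard deviation of its base
distribution and within [0, 1], and the last state is closed to enforce the
exact sum-to-one constraint (the whole bin is redrawn if closure fails).

A synthetic profile generator emulates the canonical E -> I -> M shape
(E falls, I rises then falls, M rises toward 1) with logistic median
curves, providing a fully synthetic stand-in for pseudotime-binned
single-cell data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .hybrid_model import HybridODERegressor, KnownPart
from .model_selection import RankedModelReport, SelectionGrid, select_models
from .ode_models import Trajectory, ValidationError

__all__ = [
    "SamplingError",
    "ProportionProfile",
    "ProportionDataset",
    "sample_proportion_trajectory",
    "synthetic_emt_profile",
    "make_proportion_dataset",
    "EMT_SELECTION_GRID",
    "discover_emt_model",
]


class SamplingError(RuntimeError):
    """No valid closed draw found for a bin within the attempt cap."""


@dataclass
class ProportionProfile:
    """Per-bin median proportions and spreads of the cell states.

    ``medians`` rows must sum to one (within 1e-6); ``sds`` are elementwise
    non-negative.  ``times`` default to integer pseudotime bins 1..n_bins.
    """

    medians: np.ndarray  # (n_bins, n_states)
    sds: np.ndarray
    times: np.ndarray | None = None
    state_names: list[str] = field(default_factory=lambda: ["E", "I", "M"])

    def __post_init__(self):
        self.medians = np.asarray(self.medians, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if self.medians.shape != self.sds.shape:
            raise ValidationError("medians and sds must have the same shape")
        if np.any(self.medians < 0) or np.any(self.medians > 1):
            raise ValidationError("medians must lie in [0, 1]")
        if np.any(self.sds < 0):
            raise ValidationError("sds must be non-negative")
        if not np.allclose(self.medians.sum(axis=1), 1.0, atol=1e-6):
            raise ValidationError("median rows must sum to 1")
        if self.times is None:
            self.times = 1.0 + np.arange(self.medians.shape[0])
        else:
            self.times = np.asarray(self.times, dtype=float)
        if len(self.state_names) != self.medians.shape[1]:
            self.state_names = [f"x{i + 1}" for i in range(self.medians.shape[1])]

    @property
    def n_bins(self) -> int:
        return self.medians.shape[0]

    @property
    def n_states(self) -> int:
        return self.medians.shape[1]


def _draw_truncated(mu: float, sd: float, rng) -> float:
    """One draw from N(mu, sd) truncated to [mu - sd, mu + sd] & [0, 1]."""
    lo = max(0.0, mu - sd)
    hi = min(1.0, mu + sd)
    if sd == 0 or hi <= lo:
        return float(np.clip(mu, lo, hi))
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng))


def sample_proportion_trajectory(
    profile: ProportionProfile,
    seed: int | np.random.Generator,
    closure_state: int = -1,
    max_attempts: int = 1000,
) -> Trajectory:
    """Sample one replicate trajectory of cell-state proportions.

    For each bin, all states except ``closure_state`` are drawn from their
    truncated Gaussians; the closure state is set to one minus their sum.
    If the closed value falls outside [0, 1] the whole bin is redrawn, up to
    ``max_attempts`` times.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_states = profile.n_states
    closure = closure_state % n_states
    drawn_states = [k for k in range(n_states) if k != closure]
    out = np.empty((profile.n_bins, n_states))
    for j in range(profile.n_bins):
        for _ in range(max_attempts):
            for k in drawn_states:
                out[j, k] = _draw_truncated(profile.medians[j, k], profile.sds[j, k], rng)
            rem = 1.0 - out[j, drawn_states].sum()
            if 0.0 <= rem <= 1.0:
                out[j, closure] = rem
                break
        else:
            raise SamplingError(f"no valid closed draw for bin {j} in {max_attempts} attempts")
    return Trajectory(times=profile.times.copy(), states=out)


def synthetic_emt_profile(
    n_bins: int = 9,
    transition_times: tuple[float, float] = (3.0, 6.0),
    sharpness: tuple[float, float] = (1.5, 1.5),
    sd: float = 0.05,
    t_start: float = 1.0,
    dt: float = 1.0,
) -> ProportionProfile:
    """Logistic-shaped E -> I -> M median curves with rows summing to one.

    E decays logistically around the first transition time, M rises around
    the second, and I is the remainder; ``sharpness -> inf`` approaches a
    step-function profile.  The per-bin spread defaults to 0.05.
    """
    if n_bins < 3:
        raise ValidationError("need at least 3 pseudotime bins")
    t1, t2 = transition_times
    s1, s2 = sharpness
    if t2 <= t1:
        raise ValidationError("transition times must be increasing")
    t = t_start + dt * np.arange(n_bins)
    e = 1.0 / (1.0 + np.exp(s1 * (t - t1)))
    m = 1.0 / (1.0 + np.exp(-s2 * (t - t2)))
    i = 1.0 - e - m
    if np.any(i < -1e-9):
        raise ValidationError("transitions overlap: intermediate proportion negative")
    medians = np.stack([e, np.clip(i, 0.0, 1.0), m], axis=1)
    medians /= medians.sum(axis=1, keepdims=True)
    return ProportionProfile(medians=medians, sds=np.full_like(medians, sd), times=t)


@dataclass
class ProportionDataset:
    """Replicate proportion trajectories split for training/validation/testing.

    Duck-compatible with :class:`~hybridsindy.synthetic_data.TrajectoryDataset`
    for the training and selection machinery.
    """

    train: list[Trajectory]
    validation: list[Trajectory]
    test: list[Trajectory]
    profile: ProportionProfile
    seed: int
    species_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.species_names:
            self.species_names = list(self.profile.state_names)

    @property
    def d(self) -> int:
        return self.train[0].d

    @property
    def train_times(self) -> np.ndarray:
        return self.train[0].times

    @property
    def train_dt(self) -> float:
        t = self.train_times
        return float(t[1] - t[0])


def make_proportion_dataset(
    profile: ProportionProfile,
    n_train: int = 200,
    n_val: int = 50,
    n_test: int = 50,
    seed: int = 0,
    test_profile: ProportionProfile | None = None,
    closure_state: int = -1,
) -> ProportionDataset:
    """Sample train/validation/test replicates from (possibly two) profiles.

    ``test_profile`` allows test trajectories on a longer pseudotime span
    than the training bins.
    """
    test_profile = test_profile or profile
    children = np.random.SeedSequence(seed).spawn(n_train + n_val + n_test)
    rngs = [np.random.default_rng(s) for s in children]
    train = [
        sample_proportion_trajectory(profile, rngs[i], closure_state) for i in range(n_train)
    ]
    val = [
        sample_proportion_trajectory(profile, rngs[n_train + i], closure_state)
        for i in range(n_val)
    ]
    test = [
        sample_proportion_trajectory(test_profile, rngs[n_train + n_val + i], closure_state)
        for i in range(n_test)
    ]
    return ProportionDataset(
        train=train, validation=val, test=test, profile=profile, seed=seed
    )


#: Stage-2 grid for cell-state-proportion discovery: polynomial libraries and
#: polynomial/Hill mixtures, two interpolation steps, six ridge strengths.
EMT_SELECTION_GRID = SelectionGrid(
    dt_values=(0.5, 1.0),
    library_names=(
        "poly_max_2",
        "poly_1_2",
        "hill_2_poly_1",
        "hill_3_poly_1",
        "hill_2_poly_xy",
        "hill_3_poly_xy",
        "hill_2_poly_1_2",
        "hill_3_poly_1_2",
        "hill_max_3_poly_1",
    ),
    alpha_values=(0.05, 0.1, 0.5, 1.0, 5.0, 10.0),
    threshold=0.1,
)


def discover_emt_model(
    dataset: ProportionDataset,
    loss_rates: tuple[float, ...] = (1.0, 1.0, 1.0),
    selection_grid: SelectionGrid = EMT_SELECTION_GRID,
    hidden_layers: tuple[int, ...] = (8, 8),
    window: int = 5,
    batch_size: int = 5,
    lr: float = 0.01,
    epochs: int = 10,
    init_seed: int = 0,
) -> tuple[HybridODERegressor, RankedModelReport]:
    """Hybrid discovery on proportion data with known per-state loss terms.

    The known part is ``g_i(x) = -rate_i * x_i`` (unit loss rates by
    default); the network learns the transition dynamics, and stage-2
    selection searches the polynomial/Hill basis grid.
    """
    known = KnownPart.linear([-r for r in loss_rates], name="state_loss")
    model = HybridODERegressor(
        known=known,
        hidden_layers=hidden_layers,
        window=window,
        batch_size=batch_size,
        lr=lr,
        epochs=epochs,
        init_seed=init_seed,
    ).fit(dataset)
    report = select_models(model, dataset, selection_grid)
    return model, report
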