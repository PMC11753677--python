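"""Noisy observation datasets generated from ground-truth trajectories.

Two extrinsic (measurement) noise models are supported.  With noise level
``eps`` and true trajectory ``X``:

* additive — the observation of species ``k`` at time ``j`` is drawn from a
  Gaussian centred on the true value with standard deviation
  ``eps * mean_t(X[:, k])``: the noise magnitude is constant over time;
* multiplicative — the standard deviation is ``eps * |X[j, k]|``:
  proportional to the instantaneous true value.

The second argument of the Gaussian is interpreted as a standard deviation
(not a variance); see docs/methods.md.  Draws are independent across time
points, species and samples, and observations are not clipped, so states
may go slightly negative at high noise levels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ode_models import ODESystem, SimulationGrid, Trajectory, ValidationError, simulate

__all__ = [
    "NoiseSpec",
    "TrajectoryDataset",
    "apply_noise",
    "make_dataset",
    "save_dataset",
    "load_dataset",
    "save_trajectories",
    "load_trajectories",
]

_KINDS = ("additive", "multiplicative")


@dataclass(frozen=True)
class NoiseSpec:
    """Observation-noise model: kind in {additive, multiplicative}, level >= 0."""

    kind: str
    level: float

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValidationError(f"noise kind must be one of {_KINDS}, got {self.kind!r}")
        if not (np.isfinite(self.level) and self.level >= 0):
            raise ValidationError("noise level must be a finite non-negative real")


def apply_noise(
    truth: Trajectory,
    noise: NoiseSpec,
    rng_seed: int | np.random.Generator,
) -> Trajectory:
    """Return one noisy realization of ``truth`` under ``noise``.

    ``rng_seed`` may be an integer seed or a ``numpy.random.Generator``.
    A level of zero returns the truth exactly.
    """
    if noise.level == 0:
        return Trajectory(times=truth.times.copy(), states=truth.states.copy())
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    if noise.kind == "additive":
        scale = noise.level * truth.states.mean(axis=0)  # per-species, constant in time
        obs = truth.states + rng.standard_normal(truth.states.shape) * scale[None, :]
    else:
        scale = noise.level * np.abs(truth.states)
        obs = truth.states + rng.standard_normal(truth.states.shape) * scale
    return Trajectory(times=truth.times.copy(), states=obs)


@dataclass
class TrajectoryDataset:
    """Train/validation/test collections of noisy trajectories.

    Train and validation samples share the training time grid; test samples
    live on the (typically longer) test grid.  All samples in a dataset are
    independent noise realizations of a single shared ground-truth
    trajectory per grid.
    """

    train: list[Trajectory]
    validation: list[Trajectory]
    test: list[Trajectory]
    noise: NoiseSpec
    seed: int
    system_name: str = ""
    species_names: list[str] = field(default_factory=list)
    truth_train: Trajectory | None = None
    truth_test: Trajectory | None = None

    def __post_init__(self):
        for split in (self.train, self.validation, self.test):
            if not split:
                continue
            t0 = split[0].times
            for traj in split[1:]:
                if not np.allclose(traj.times, t0):
                    raise ValidationError("all trajectories in a split must share a time grid")

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


def make_dataset(
    system: ODESystem,
    x0,
    train_grid: SimulationGrid,
    test_grid: SimulationGrid,
    noise: NoiseSpec,
    n_train: int = 200,
    n_val: int = 50,
    n_test: int = 50,
    seed: int = 0,
    rtol: float = 1e-8,
    atol: float = 1e-8,
) -> TrajectoryDataset:
    """Simulate the ground truth once per grid and draw independent noisy samples.

    Deterministic given ``seed``: per-sample RNG substreams are spawned from
    one master ``SeedSequence``.
    """
    for count, label in ((n_train, "n_train"), (n_val, "n_val"), (n_test, "n_test")):
        if count < 1:
            raise ValidationError(f"{label} must be positive")
    truth_train = simulate(system, x0, train_grid, rtol=rtol, atol=atol)
    truth_test = simulate(system, x0, test_grid, rtol=rtol, atol=atol)

    children = np.random.SeedSequence(seed).spawn(n_train + n_val + n_test)
    rngs = [np.random.default_rng(s) for s in children]
    train = [apply_noise(truth_train, noise, rngs[i]) for i in range(n_train)]
    val = [apply_noise(truth_train, noise, rngs[n_train + i]) for i in range(n_val)]
    test = [apply_noise(truth_test, noise, rngs[n_train + n_val + i]) for i in range(n_test)]
    return TrajectoryDataset(
        train=train,
        validation=val,
        test=test,
        noise=noise,
        seed=seed,
        system_name=system.name,
        species_names=list(system.species_names),
        truth_train=truth_train,
        truth_test=truth_test,
    )


# ---------------------------------------------------------------------------
# delimited-text serialization: columns sample_id, t, <species...>


def save_trajectories(path, trajectories: list[Trajectory], species_names: list[str]) -> None:
    frames = []
    for i, traj in enumerate(trajectories):
        frame = pd.DataFrame(traj.states, columns=species_names)
        frame.insert(0, "t", traj.times)
        frame.insert(0, "sample_id", i)
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def load_trajectories(path) -> tuple[list[Trajectory], list[str]]:
    frame = pd.read_csv(path)
    species = [c for c in frame.columns if c not in ("sample_id", "t")]
    out = []
    for _, group in frame.groupby("sample_id", sort=True):
        out.append(Trajectory(times=group["t"].to_numpy(), states=group[species].to_numpy()))
    return out, species


def save_dataset(directory, dataset: TrajectoryDataset) -> None:
    """Write one CSV per split plus a JSON sidecar with noise spec and seed."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = dataset.species_names or [f"x{i + 1}" for i in range(dataset.d)]
    for split in ("train", "validation", "test"):
        save_trajectories(directory / f"{split}.csv", getattr(dataset, split), names)
    if dataset.truth_train is not None:
        save_trajectories(directory / "truth_train.csv", [dataset.truth_train], names)
    if dataset.truth_test is not None:
        save_trajectories(directory / "truth_test.csv", [dataset.truth_test], names)
    sidecar = {
        "system": dataset.system_name,
        "species": names,
        "noise": {"kind": dataset.noise.kind, "level": dataset.noise.level},
        "seed": dataset.seed,
        "counts": {
            "train": len(dataset.train),
            "validation": len(dataset.validation),
            "test": len(dataset.test),
        },
    }
    (directory / "dataset.json").write_text(json.dumps(sidecar, indent=2))


def load_dataset(directory) -> TrajectoryDataset:
    directory = Path(directory)
    meta = json.loads((directory / "dataset.json").read_text())
    splits = {}
    species = meta["species"]
    for split in ("train", "validation", "test"):
        splits[split], _ = load_trajectories(directory / f"{split}.csv")
    truths = {}
    for key in ("truth_train", "truth_test"):
        path = directory / f"{key}.csv"
        if path.exists():
            trajs, _ = load_trajectories(path)
            truths[key] = trajs[0]
    return TrajectoryDataset(
        train=splits["train"],
        validation=splits["validation"],
        test=splits["test"],
        noise=NoiseSpec(meta["noise"]["kind"], meta["noise"]["level"]),
        seed=meta["seed"],
        system_name=meta.get("system", ""),
        species_names=species,
        truth_train=truths.get("truth_train"),
        truth_test=truths.get("truth_test"),
    )
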