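"""Sliding-window segmentation and batching of training trajectories.

Each raw training sample is cut into overlapping windows of ``w``
consecutive grid points (step 1).  Windows from all samples are pooled,
globally shuffled, and chunked into batches; a trailing partial batch is
kept.  Reshuffling each epoch uses epoch-indexed seeds derived from the
base shuffle seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ode_models import Trajectory, ValidationError

__all__ = ["WindowSegment", "BatchSet", "sliding_windows", "pool_windows", "make_batches", "batch_arrays"]


@dataclass
class WindowSegment:
    """One window of ``w`` contiguous grid points from one sample."""

    sample_index: int
    start_index: int
    times: np.ndarray
    states: np.ndarray  # (w, d)

    @property
    def w(self) -> int:
        return self.states.shape[0]


@dataclass
class BatchSet:
    batches: list[list[WindowSegment]]
    batch_size: int
    shuffle_seed: int

    @property
    def n_windows(self) -> int:
        return sum(len(b) for b in self.batches)


def sliding_windows(traj: Trajectory, w: int, sample_index: int = 0) -> list[WindowSegment]:
    """All ``n_points - w + 1`` windows of size ``w`` with step 1."""
    if w < 2:
        raise ValidationError("window size must be >= 2")
    if w > traj.n_points:
        raise ValidationError(f"window size {w} exceeds trajectory length {traj.n_points}")
    return [
        WindowSegment(
            sample_index=sample_index,
            start_index=start,
            times=traj.times[start : start + w],
            states=traj.states[start : start + w],
        )
        for start in range(traj.n_points - w + 1)
    ]


def pool_windows(trajectories: list[Trajectory], w: int) -> list[WindowSegment]:
    """Windows of all samples pooled into one list (shuffled later as a whole)."""
    pooled: list[WindowSegment] = []
    for i, traj in enumerate(trajectories):
        pooled.extend(sliding_windows(traj, w, sample_index=i))
    return pooled


def make_batches(windows: list[WindowSegment], b: int, seed: int) -> BatchSet:
    """Globally shuffle the pooled windows, then chunk into groups of ``b``."""
    if not windows:
        raise ValidationError("cannot batch an empty window list")
    if b < 1:
        raise ValidationError("batch size must be >= 1")
    order = np.random.default_rng(seed).permutation(len(windows))
    shuffled = [windows[i] for i in order]
    batches = [shuffled[i : i + b] for i in range(0, len(shuffled), b)]
    return BatchSet(batches=batches, batch_size=b, shuffle_seed=seed)


def batch_arrays(batch: list[WindowSegment]) -> tuple[np.ndarray, np.ndarray, float]:
    """Stack a batch into arrays: initial states (B, d), observations (B, w, d), grid step."""
    obs = np.stack([seg.states for seg in batch])
    dt = float(batch[0].times[1] - batch[0].times[0])
    return obs[:, 0, :].copy(), obs, dt
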