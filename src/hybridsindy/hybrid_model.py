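"""Hybrid dynamical systems ``x' = g(x) + NN(x)`` and their training.

The known closed-form part ``g`` encodes partial prior knowledge (e.g.
growth/decay terms with known rates); the network learns the remaining
latent dynamics.  Training simulates each short window from its first
observed (noisy) state, measures the mean squared error against the
observed window, and backpropagates through the solver
(discretize-then-optimize with a fixed-step RK4 scheme, whose reverse pass
is derived by hand).  After every epoch the model is scored on validation
trajectories simulated over the full training span; the weights from the
best epoch are kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._integrate import rk4_path
from ._nn import MLP, Adam
from .ode_models import Trajectory, ValidationError
from .preprocessing import batch_arrays, make_batches, pool_windows, WindowSegment
from .synthetic_data import TrajectoryDataset

__all__ = [
    "KnownPart",
    "NetworkSpec",
    "TrainConfig",
    "TrainingFailure",
    "HybridODERegressor",
    "window_loss",
    "validation_loss",
    "train_hybrid",
    "grid_search_nn",
]


class TrainingFailure(RuntimeError):
    """Raised when no hyperparameter combination produced a finite fit."""


@dataclass
class KnownPart:
    """Known closed-form part ``g`` of a hybrid system.

    ``f`` evaluates g (vectorized over leading axes); ``vjp(x, v)`` returns
    the vector-Jacobian product ``J_g(x)^T v`` needed for backpropagation;
    ``terms`` lists the symbolic form per equation as (label, coefficient)
    pairs, used when assembling and rendering discovered models.
    """

    d: int
    f: Callable[[np.ndarray], np.ndarray]
    vjp: Callable[[np.ndarray, np.ndarray], np.ndarray]
    terms: list[list[tuple[str, float]]]
    name: str = ""

    @classmethod
    def zero(cls, d: int) -> "KnownPart":
        """No prior knowledge: g(x) = 0 (the pure-NN formulation)."""
        return cls(
            d=d,
            f=lambda x: np.zeros_like(np.asarray(x, dtype=float)),
            vjp=lambda x, v: np.zeros_like(np.asarray(v, dtype=float)),
            terms=[[] for _ in range(d)],
            name="zero",
        )

    @classmethod
    def linear(cls, coeffs: Sequence[float], name: str = "linear") -> "KnownPart":
        """Diagonal linear part g_i(x) = c_i * x_i.

        Covers the known parts used in practice: prey growth / predator
        death for Lotka-Volterra (c = (alpha, -delta)) and unit degradation
        for the repressilator and cell-state models (c = (-1, ..., -1)).
        """
        c = np.asarray(coeffs, dtype=float)
        if c.ndim != 1 or not np.all(np.isfinite(c)):
            raise ValidationError("coeffs must be a finite 1-D sequence")
        terms = [
            ([(f"x{i + 1}", float(c[i]))] if c[i] != 0 else []) for i in range(c.size)
        ]
        return cls(
            d=c.size,
            f=lambda x: np.asarray(x, dtype=float) * c,
            vjp=lambda x, v: np.asarray(v, dtype=float) * c,
            terms=terms,
            name=name,
        )


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture of the NN part: hidden widths, activation, init seed."""

    hidden_layers: tuple[int, ...] = (8,)
    activation: str = "tanh"
    init_seed: int = 0

    def build(self, d: int) -> MLP:
        if any(h < 1 for h in self.hidden_layers):
            raise ValidationError("hidden layer widths must be positive")
        return MLP([d, *self.hidden_layers, d], activation=self.activation, seed=self.init_seed)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings for hybrid training (Adam, fixed-step RK4)."""

    lr: float = 0.01
    epochs: int = 10
    substeps: int = 2
    shuffle_seed: int = 0
    reshuffle_each_epoch: bool = True
    skip_nonfinite_batches: bool = True

    def __post_init__(self):
        if self.lr <= 0:
            raise ValidationError("learning rate must be positive")
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")


# ---------------------------------------------------------------------------
# forward/backward simulation of windows


def _window_forward(fun, x0: np.ndarray, dt: float, n_intervals: int, substeps: int):
    """Simulate a batch of windows; returns predictions (B, w, d) and the
    tape of RK4 stage inputs needed for the reverse pass."""
    B, d = x0.shape
    h = dt / substeps
    preds = np.empty((B, n_intervals + 1, d))
    preds[:, 0] = x0
    tape = []
    x = x0
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        for j in range(n_intervals):
            for _ in range(substeps):
                k1 = fun(x)
                x2 = x + 0.5 * h * k1
                k2 = fun(x2)
                x3 = x + 0.5 * h * k2
                k3 = fun(x3)
                x4 = x + h * k3
                k4 = fun(x4)
                tape.append((x, x2, x3, x4))
                x = x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            preds[:, j + 1] = x
    return preds, tape


def _window_backward(vjp, grads_out: np.ndarray, tape, dt: float, n_intervals: int, substeps: int):
    """Reverse pass of :func:`_window_forward`.

    ``vjp(x, v)`` must return the VJP of the full right-hand side at ``x``
    and accumulate parameter gradients as a side effect.  ``grads_out`` is
    dL/d(preds).  Returns dL/d(x0).
    """
    h = dt / substeps
    a = grads_out[:, -1].copy()
    ti = len(tape) - 1
    for j in range(n_intervals - 1, -1, -1):
        for _ in range(substeps):
            x1, x2, x3, x4 = tape[ti]
            ti -= 1
            g4 = (h / 6.0) * a
            v4 = vjp(x4, g4)
            g3 = (h / 3.0) * a + h * v4
            v3 = vjp(x3, g3)
            g2 = (h / 3.0) * a + 0.5 * h * v3
            v2 = vjp(x2, g2)
            g1 = (h / 6.0) * a + 0.5 * h * v2
            v1 = vjp(x1, g1)
            a = a + v1 + v2 + v3 + v4
        a = a + grads_out[:, j]
    return a


def window_loss(known: KnownPart, net: MLP, segment: WindowSegment, substeps: int = 2) -> float:
    """MSE between the hybrid simulation of a window (from its first observed
    state) and the observed window, over all w points and d species."""
    x0, obs, dt = batch_arrays([segment])

    def fun(x):
        return known.f(x) + net.forward(x)

    preds, _ = _window_forward(fun, x0, dt, obs.shape[1] - 1, substeps)
    return float(np.mean((preds - obs) ** 2))


def validation_loss(
    rhs: Callable[[np.ndarray], np.ndarray],
    validation: list[Trajectory],
    substeps: int = 2,
) -> float:
    """Mean per-sample MSE of full-span simulations against validation data.

    Each sample is simulated from its own (noisy) first observation over the
    full training span and evaluated at the observed grid times.  A sample
    whose simulation diverges contributes +inf, penalizing unstable fits.
    """
    if not validation:
        raise ValidationError("validation set must be non-empty")
    times = validation[0].times
    x0 = np.stack([traj.states[0] for traj in validation])
    preds = rk4_path(rhs, x0, times, substeps=substeps)
    obs = np.stack([traj.states for traj in validation])
    with np.errstate(over="ignore", invalid="ignore"):
        per_sample = np.mean((preds - obs) ** 2, axis=(1, 2))
    per_sample = np.where(np.isfinite(per_sample), per_sample, np.inf)
    return float(np.mean(per_sample))


# ---------------------------------------------------------------------------
# estimator


class HybridODERegressor(BaseEstimator):
    """Trainable hybrid dynamical system ``x' = g(x) + NN(x)``.

    scikit-learn style estimator: hyperparameters in ``__init__``,
    :meth:`fit` consumes a :class:`~hybridsindy.synthetic_data.TrajectoryDataset`
    and sets trailing-underscore attributes.

    Parameters
    ----------
    known : KnownPart or None
        Closed-form part g; ``None`` means g = 0 (pure-NN formulation).
    hidden_layers, activation, init_seed
        Network architecture (see :class:`NetworkSpec`).
    window, batch_size
        Sliding-window length w and batch size b for preprocessing.
    lr, epochs
        Adam learning rate and number of passes over all batches.
    substeps
        Internal RK4 steps per data interval during training and validation.
    shuffle_seed, reshuffle_each_epoch
        Batch shuffling control; epoch-indexed seeds when reshuffling.

    Attributes
    ----------
    network_ : MLP
        Weights from the epoch with the lowest validation loss.
    known_ : KnownPart
    history_ : pandas.DataFrame
        Per-epoch mean training batch loss and validation loss.
    best_epoch_ : int
        1-based index of the retained epoch.
    validation_loss_ : float
    """

    def __init__(
        self,
        known: KnownPart | None = None,
        hidden_layers: tuple[int, ...] = (8,),
        activation: str = "tanh",
        init_seed: int = 0,
        window: int = 5,
        batch_size: int = 5,
        lr: float = 0.01,
        epochs: int = 10,
        substeps: int = 2,
        shuffle_seed: int = 0,
        reshuffle_each_epoch: bool = True,
    ):
        self.known = known
        self.hidden_layers = hidden_layers
        self.activation = activation
        self.init_seed = init_seed
        self.window = window
        self.batch_size = batch_size
        self.lr = lr
        self.epochs = epochs
        self.substeps = substeps
        self.shuffle_seed = shuffle_seed
        self.reshuffle_each_epoch = reshuffle_each_epoch

    # -- fitted-model evaluation ------------------------------------------

    def rhs(self, x: np.ndarray) -> np.ndarray:
        """Full fitted right-hand side f(x) = g(x) + NN(x)."""
        return self.known_.f(x) + self.network_.forward(x)

    def nn(self, x: np.ndarray) -> np.ndarray:
        """Fitted network part NN(x) alone."""
        return self.network_.forward(x)

    def simulate(self, x0, times, substeps: int | None = None) -> np.ndarray:
        """Integrate the fitted hybrid system from ``x0`` over ``times``."""
        return rk4_path(self.rhs, np.asarray(x0, dtype=float), np.asarray(times, dtype=float),
                        substeps=substeps or self.substeps)

    def predict(self, x0, times) -> np.ndarray:
        return self.simulate(x0, times)

    # -- training ----------------------------------------------------------

    def fit(self, dataset: TrajectoryDataset, y=None) -> "HybridODERegressor":
        if not dataset.train:
            raise ValidationError("dataset train split must be non-empty")
        d = dataset.d
        known = self.known if self.known is not None else KnownPart.zero(d)
        if known.d != d:
            raise ValidationError("known part dimension does not match data")
        spec = NetworkSpec(tuple(self.hidden_layers), self.activation, self.init_seed)
        net = spec.build(d)
        adam = Adam(net.weights, lr=self.lr)
        windows = pool_windows(dataset.train, self.window)
        w = self.window

        def fun(x):
            return known.f(x) + net.forward(x)

        # epoch 0: the untrained model (g plus a zero-initialized network) is a
        # legitimate candidate -- when g is already correct, training must not
        # be able to degrade the returned model
        best_loss = validation_loss(fun, dataset.validation, substeps=self.substeps)
        best_weights = net.copy_weights()
        best_epoch = 0
        history = [
            {
                "epoch": 0,
                "train_loss": np.nan,
                "validation_loss": best_loss,
                "batches_skipped": 0,
            }
        ]
        for epoch in range(1, self.epochs + 1):
            seed = self.shuffle_seed + (epoch - 1 if self.reshuffle_each_epoch else 0)
            batches = make_batches(windows, self.batch_size, seed=seed)
            losses = []
            skipped = 0
            for batch in batches.batches:
                x0, obs, dt = batch_arrays(batch)
                B = x0.shape[0]
                preds, tape = _window_forward(fun, x0, dt, w - 1, self.substeps)
                residual = preds - obs
                if not np.all(np.isfinite(residual)):
                    skipped += 1
                    continue
                losses.append(float(np.mean(residual**2)))
                grads_accum = net.zero_grads()

                def vjp(x, v):
                    out, cache = net.forward(x, need_cache=True)
                    dx, gs = net.backward(cache, v)
                    for acc, g in zip(grads_accum, gs):
                        acc += g
                    return dx + known.vjp(x, v)

                grads_out = 2.0 * residual / (B * w * d)
                _window_backward(vjp, grads_out, tape, dt, w - 1, self.substeps)
                if not all(np.all(np.isfinite(g)) for g in grads_accum):
                    skipped += 1
                    continue
                adam.step(net.weights, grads_accum)

            vloss = validation_loss(fun, dataset.validation, substeps=self.substeps)
            history.append(
                {
                    "epoch": epoch,
                    "train_loss": float(np.mean(losses)) if losses else np.nan,
                    "validation_loss": vloss,
                    "batches_skipped": skipped,
                }
            )
            if vloss < best_loss:
                best_loss = vloss
                best_weights = net.copy_weights()
                best_epoch = epoch

        net.set_weights(best_weights)
        self.network_ = net
        self.known_ = known
        self.history_ = pd.DataFrame(history)
        self.best_epoch_ = best_epoch
        self.validation_loss_ = float(best_loss)
        self.n_features_in_ = d
        return self


def train_hybrid(
    dataset: TrajectoryDataset,
    known: KnownPart | None,
    spec: NetworkSpec = NetworkSpec(),
    w: int = 5,
    b: int = 5,
    cfg: TrainConfig = TrainConfig(),
) -> HybridODERegressor:
    """Functional wrapper over :class:`HybridODERegressor`."""
    model = HybridODERegressor(
        known=known,
        hidden_layers=spec.hidden_layers,
        activation=spec.activation,
        init_seed=spec.init_seed,
        window=w,
        batch_size=b,
        lr=cfg.lr,
        epochs=cfg.epochs,
        substeps=cfg.substeps,
        shuffle_seed=cfg.shuffle_seed,
        reshuffle_each_epoch=cfg.reshuffle_each_epoch,
    )
    return model.fit(dataset)


def grid_search_nn(
    dataset: TrajectoryDataset,
    known: KnownPart | None,
    spec: NetworkSpec = NetworkSpec(),
    grid: dict | None = None,
    epochs: int = 10,
    substeps: int = 2,
    shuffle_seed: int = 0,
) -> tuple[HybridODERegressor, pd.DataFrame]:
    """Stage-1 model selection: train every (w, b, lr) combination and keep
    the fit with the lowest mean validation loss.

    Returns the best fitted estimator and a table of all combinations with
    their best-epoch validation losses.  Combinations whose training never
    produced a finite validation loss are recorded as failed, not raised.
    """
    grid = grid or {"w": [5, 10], "b": [5, 10, 20], "lr": [0.001, 0.01, 0.1]}
    rows = []
    best_model = None
    for w, b, lr in product(grid["w"], grid["b"], grid["lr"]):
        cfg = TrainConfig(lr=lr, epochs=epochs, substeps=substeps, shuffle_seed=shuffle_seed)
        try:
            model = train_hybrid(dataset, known, spec, w=w, b=b, cfg=cfg)
            vloss = model.validation_loss_
            status = "ok" if np.isfinite(vloss) else "diverged"
        except (ValidationError, FloatingPointError) as exc:  # pragma: no cover - defensive
            warnings.warn(f"training failed for (w={w}, b={b}, lr={lr}): {exc}")
            model, vloss, status = None, np.inf, "error"
        rows.append(
            {
                "w": w,
                "b": b,
                "lr": lr,
                "validation_loss": vloss,
                "best_epoch": getattr(model, "best_epoch_", -1),
                "status": status,
            }
        )
        if model is not None and (best_model is None or vloss < best_model.validation_loss_):
            if np.isfinite(vloss):
                best_model = model
    table = pd.DataFrame(rows)
    if best_model is None:
        raise TrainingFailure("all hyperparameter combinations failed to train")
    return best_model, table
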