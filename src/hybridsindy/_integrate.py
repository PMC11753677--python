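"""Fixed-step batched RK4 integration used for training and model scoring.

The classical fourth-order Runge-Kutta scheme with ``substeps`` internal
steps per output interval integrates a whole batch of initial conditions at
once (the right-hand side must be vectorized over leading axes).  Overflow
in diverging candidate models is deliberately tolerated: non-finite values
propagate and are detected by callers, which treat the affected sample as a
failed simulation.
"""

from __future__ import annotations

import numpy as np

__all__ = ["rk4_path", "auto_substeps"]


def auto_substeps(dt: float, target_h: float = 0.05) -> int:
    """Number of internal RK4 substeps so the internal step is <= target_h."""
    return max(1, int(np.ceil(dt / target_h - 1e-12)))


def rk4_path(fun, x0: np.ndarray, times: np.ndarray, substeps: int = 2) -> np.ndarray:
    """Integrate ``x' = fun(x)`` for a batch of initial conditions.

    Parameters
    ----------
    fun : callable
        Vectorized autonomous right-hand side mapping (..., d) -> (..., d).
    x0 : ndarray, shape (B, d) or (d,)
        Initial conditions at ``times[0]``.
    times : ndarray
        Uniformly spaced output times.
    substeps : int
        Internal steps per output interval.

    Returns
    -------
    ndarray, shape (B, len(times), d) (or (len(times), d) for 1-D input).
    """
    x0 = np.asarray(x0, dtype=float)
    single = x0.ndim == 1
    x = x0[None, :] if single else x0
    times = np.asarray(times, dtype=float)
    n_out = times.shape[0]
    out = np.empty((x.shape[0], n_out, x.shape[1]))
    out[:, 0] = x
    if n_out > 1:
        h = float(times[1] - times[0]) / substeps
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            for j in range(1, n_out):
                for _ in range(substeps):
                    k1 = fun(x)
                    k2 = fun(x + 0.5 * h * k1)
                    k3 = fun(x + 0.5 * h * k2)
                    k4 = fun(x + h * k3)
                    x = x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
                out[:, j] = x
    return out[0] if single else out
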