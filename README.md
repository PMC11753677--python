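# hybridsindy

Data-driven discovery of ordinary differential equation models from noisy,
short biological time series, for researchers who know *part* of their
system — say, the degradation rates — and want to learn the rest from
data.

Direct sparse regression (SINDy-style) needs accurate derivative
estimates, which noisy biological data rarely afford. `hybridsindy`
instead fits a **hybrid dynamical system**

    x' = f(x) = g(x) + NN(x)

where `g(x)` collects the known closed-form terms and a small neural
network `NN(x)` learns the latent dynamics by simulating short sliding
windows of the data and backpropagating through the ODE solver. The fitted
(denoised, interpolatable) model is then re-simulated and its network part
regressed onto a library of candidate terms Θ(x) — monomials and Hill
functions `1/(1+x^n)` — by Sequentially Thresholded Least Squares, giving
a sparse symbolic model `f(x) = g(x) + Θ(x)Ξ̂`. Model selection is
two-stage: validation loss picks the network hyperparameters `(w, b, lr)`,
and the corrected Akaike information criterion

    AICc = n ln(RSS/n) + 2k + 2(k+1)(k+2)/(n−k−2)

ranks the symbolic candidates over a grid of simulation steps, libraries,
and ridge strengths. Four baselines (finite-difference SINDy with and
without the known terms, weak-form SINDy, and a pure neural network) share
the same selection machinery for apples-to-apples comparison. Benchmark
generators (Lotka-Volterra, repressilator, cell-state proportion
trajectories with sum-to-one closure) produce the noisy multi-sample
datasets.

## Worked example

Discover the Lotka-Volterra interaction terms from 50 noisy trajectories
(0.1% additive noise) assuming the growth/death terms `1.3*x1` and
`-1.8*x2` are known:

```python
import numpy as np
from hybridsindy import (
    HybridODERegressor, KnownPart, NoiseSpec, SimulationGrid,
    get_preset, lotka_volterra, make_dataset, select_models,
)

system = lotka_volterra(alpha=1.3, beta=0.9, gamma=0.8, delta=1.8)
dataset = make_dataset(
    system, [0.4425, 4.6281],
    SimulationGrid(0, 4, 0.1), SimulationGrid(0, 20, 0.1),
    NoiseSpec("additive", 0.001), n_train=50, n_val=50, n_test=5, seed=100,
)
model = HybridODERegressor(
    known=KnownPart.linear([1.3, -1.8]),
    window=5, batch_size=5, lr=0.01, epochs=10, init_seed=0,
).fit(dataset)
report = select_models(model, dataset,
                       get_preset("lotka_volterra").selection_grid, truth=system)
best = report.best
print(f"AICc {best.aicc:.1f}  library {best.library_name}  "
      f"topology correct: {best.topology_correct}")
print(best.model.equations_text())
```

Output:

```
AICc 31.4  library poly_max_2  topology correct: True
x1' = 1.300*x1 - 0.862*x1*x2
x2' = -1.800*x2 + 0.765*x1*x2
```

The selected model has exactly the true predator-prey topology; the
learned interaction coefficients (−0.862, +0.765) sit within a few percent
of the true (−0.9, +0.8), with the known terms fixed. The same pipeline on
repressilator data recovers the three order-3 Hill repression terms with
coefficients near the true basal rate β = 10.

The same workflows are available from the shell:

```bash
hybridsindy discover --system lotka_volterra --noise-level 0.001 --seed 1
hybridsindy compare  --system lotka_volterra --noise-level 0.05 --methods base,weak
hybridsindy emt-demo --n-train 100
```

`compare` with all methods and full grids across the twelve noise settings
reproduces the full benchmark table; that is an hours-long opt-in run.

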