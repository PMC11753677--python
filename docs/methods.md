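# Methods

## The model-discovery problem

Given `n` noisy trajectories `X = {X^(1), ..., X^(n)}` of a `d`-species
dynamical system sampled on a uniform grid over `[0, T]`, we want the
symbolic ODE `x' = f(x)` that generated them. We assume partial prior
knowledge: some terms of `f` (typically growth or degradation terms with
known rates) are given in closed form as `g(x)`. The discovery proceeds in
two stages around the hybrid dynamical system

    x' = f(x) = g(x) + NN(x),

where `NN` is a small fully-connected network that absorbs the unknown
dynamics.

**Stage 1 (network fit).** Each training trajectory is cut into sliding
windows of `w` consecutive points (step 1); windows from all samples are
pooled, shuffled, and batched (`b` windows per batch, trailing partial
batch kept, re-shuffled each epoch with epoch-indexed seeds). For each
window the hybrid system is integrated from the window's first *observed*
(noisy) state, and the batch loss is the mean over windows of the MSE
between simulation and observation over all `w` points and `d` species.
Gradients with respect to the network weights flow through the solver:
we integrate with classical RK4 at a fixed internal step (`substeps`
subdivisions of the data interval, default 2) and differentiate the
discrete computation exactly (discretize-then-optimize), with the RK4
reverse pass derived by hand and the network's vector-Jacobian products
computed analytically. Weights are updated by Adam. After each of the 10
epochs the model is scored on validation data — each validation sample is
simulated from its own first observation over the full training span and
compared by MSE — and the weights of the best epoch are kept. A grid over
`(w, b, lr)` (defaults `{5,10} x {5,10,20} x {0.001,0.01,0.1}`) selects the
network with the lowest validation loss; combinations that diverge are
recorded as failed rather than raised.

**Stage 2 (sparse regression and selection).** The fitted hybrid system is
re-simulated over `[0, T]` at a step `dt` (possibly finer than the data)
from every training sample's first observation, giving states `X̂` and
pointwise targets `NN(X̂)`. For each candidate basis library Θ the sparse
coefficient matrix `Ξ` solving `NN(X̂) ≈ Θ(X̂) Ξ` is found by Sequentially
Thresholded Least Squares: ridge regression (strength `α`, applied to raw
unstandardized columns so thresholds live on natural coefficient scales)
alternated with hard thresholding at `λ`, until the active set is stable
(max 20 iterations; `α = λ = 0` reduces to ordinary least squares). The
full model `f(x) = g(x) + Θ(x) Ξ̂` is scored on the validation samples by
the corrected Akaike information criterion

    AICc = n ln(RSS/n) + 2k + 2(k+1)(k+2)/(n-k-2),

with `n` the number of validation samples, `RSS` the squared residuals of
per-sample simulations over the training span, and `k` the number of
*learned* nonzero coefficients — known terms are free because they are not
estimated. The grid over `(dt, library, α)` yields a ranked report; the
lowest-AICc candidate is the selected model. A candidate that diverges, or
has too many parameters for the validation budget (`n ≤ k + 2`), is ranked
last rather than aborting the grid. A model is called *topology-correct*
when its per-equation sets of nonzero term labels and signs (known +
learned combined) exactly match the ground truth's; coefficient accuracy
is reported separately.

## Benchmark systems and synthetic data

* **Lotka-Volterra** (`d = 2`): `x1' = αx1 − βx1x2`, `x2' = γx1x2 − δx2`
  with `(α, β, γ, δ) = (1.3, 0.9, 0.8, 1.8)`, `x0 = (0.4425, 4.6281)`;
  training span `[0, 4]`, test span `[0, 20]`, `Δt = 0.1`. The known part
  is the growth/death pair `(αx1, −δx2)`; the network learns the
  interactions. Stage-2 grid: `dt ∈ {0.05, 0.1}`, libraries `poly_max_2`
  and `poly_2_3`, `α ∈ {0.05, 0.1, 0.5, 1, 5, 10}`, `λ = 0.1`. Two
  alternative parameterizations are shipped as presets
  (`lotka_volterra_alt_x0`, `lotka_volterra_alt_params`) because published
  descriptions of the alternative study disagree; neither is used in the
  default checks.
* **Repressilator** (`d = 3`): `xi' = β/(1 + x_{i−1}^n) − γ xi` cyclically,
  with `β = 10`, `n = 3`, `γ = 1`, half-max constant fixed at `k = 1`
  (not configurable), `x0 = (1, 1, 1.2)`; spans `[0, 10]` / `[0, 30]`,
  `Δt = 0.2`. Known part: unit degradation `−xi`. Stage-2 grid:
  `dt ∈ {0.1, 0.2}`, libraries `hill_1`, `hill_2`, `hill_3`, `hill_max_3`,
  same `α` values, `λ = 1.0`. An asymmetric variant (`β = (7, 6, 8)`,
  `n = 2`) is included as a preset.

Ground truths are integrated with adaptive LSODA at `rtol = atol = 1e-8`,
so integration error is far below observation noise even at the 0.1%
level. Observation noise at level `ε` is Gaussian and independent across
time points, species, and samples: *additive* noise has standard deviation
`ε · mean_t(X_true[:, k])` (constant over time for each species);
*multiplicative* noise has standard deviation `ε · |X_true[j, k]|`. The
second Gaussian argument is read as a standard deviation, not a variance
(the alternative reading is possible but inconsistent with ±3 s.d. ribbon
widths scaling visibly with ε); observations are not clipped, so states
can go slightly negative at high ε. Every dataset shares a single
ground-truth trajectory per grid — samples differ only in their noise
realization — and all randomness flows from one master seed through
spawned per-sample substreams.

What the generator does *not* emulate: intrinsic (demographic)
stochasticity, time-correlated or asymmetric noise, irregular sampling,
and missing data. Passing tests therefore demonstrate robustness to
independent Gaussian measurement noise only.

## Baselines

All baselines consume the same datasets and emit the same ranked-report
schema, sharing the stage-2 scoring verbatim.

* **Base SINDy** — derivatives per training sample by second-order central
  finite differences (one-sided second-order stencils at the endpoints),
  rows stacked, STLSQ, AICc ranking. No `dt` hyperparameter: finite
  differences cannot interpolate.
* **Base-known** — identical, with `g(X)` subtracted from the derivative
  estimates; the reported model is `g` plus the learned terms. With
  `g = 0` it is bitwise identical to base SINDy.
* **Weak-form SINDy** — the regression is integrated against polynomial
  bump test functions `φ(t) = ((t − a)(b − t))^p` (default `p = 3`,
  normalized to unit maximum) on `K = 100` random subwindows per sample
  (minimum length a quarter of the trajectory); by parts,
  `−∫ φ' x dt = ∫ φ Θ(x) dt · Ξ`, with trapezoidal quadrature on the data
  grid. The weak-form hyperparameters are package defaults (configurable);
  weak-form results are assessed qualitatively (correct/incorrect per
  noise regime), not numerically.
* **Pure NN** — the hybrid pipeline with `g = 0`, by construction.

## Cell-state proportion data

The epithelial-mesenchymal transition module works on proportions of three
cell states (E, I, M) over integer pseudotime bins. Replicates are drawn
per bin from Gaussians truncated to `[μ − σ, μ + σ] ∩ [0, 1]`; the last
state (configurable) is closed to `1 − Σ(others)`, and the whole bin is
redrawn (cap 1000) if closure leaves `[0, 1]`. A synthetic profile
generator produces the canonical shape — E falling, I transient, M rising
toward 1 — from two logistic transitions (defaults: 9 bins, transitions at
pseudotime 3 and 6, sharpness 1.5, σ = 0.05). Discovery uses the hybrid
pipeline with known unit loss terms `−xi` and a basis grid of polynomial
and Hill/polynomial mixtures (`poly_max_2`, `poly_1_2`,
`hill_{2,3}_poly_1`, `hill_{2,3}_poly_xy`, `hill_{2,3}_poly_1_2`,
`hill_max_3_poly_1`), `dt ∈ {0.5, 1}`, `λ = 0.1`.

A caveat specific to compositional data: on the simplex `x1 + x2 + x3 = 1`
the constant function is a linear combination of the linear terms, so
coefficient representations are not unique — a cancellation such as a
learned `+x3` against a known `−x3` loss may be distributed across several
equivalent terms. The tests therefore check the *function* the selected
model computes (no net M loss at the M-dominant state, stable
extrapolation, correct transition directions), not a particular
coefficient representation.

## Numerical choices

* **Training integrator.** Fixed-step RK4 with `substeps = 2` per data
  interval during training and validation; regression data and candidate
  scoring use enough substeps that the internal step is ≤ 0.05. Exact
  discrete gradients make short-window training cheap and reproducible;
  data generation still uses adaptive LSODA. An unstable candidate model
  overflows to non-finite values, which is detected and treated as a
  failed simulation (infinite RSS).
* **Network.** One hidden layer of 8 tanh units for two-species problems,
  two hidden layers of 8 for three-species problems. The activation is
  tanh (smooth and bounded-derivative, so the network integrates well;
  softplus available). Hidden weights use fan-in-scaled uniform
  initialization; the output layer starts at zero so the hybrid model
  begins exactly at its known part — with a correct `g` and no noise the
  initial validation loss is already at floor.
* **Batches.** Non-finite window simulations or gradients skip the batch
  (counted in the training history) rather than aborting; a learning rate
  of 0.1 routinely diverges and is simply recorded as a failed grid cell.
* **Determinism.** Identical seeds (dataset, init, shuffle) give
  bit-identical fits on the same platform; every stochastic entry point
  takes an explicit seed.
* **Degenerate inputs.** Zero noise returns the truth exactly; a
  degenerate time grid yields a single-row trajectory; an empty STLSQ
  active set yields an all-zero column with a warning (the model may still
  be valid through `g`).

## Problem sizes used in the checked examples

The shipped tests and the acceptance script run the pipeline at reduced
scale, chosen once: Lotka-Volterra end-to-end uses 50 training / 50
validation samples with the single configuration `(w=5, b=5, lr=0.01)`
over three seeds; the repressilator uses 100 training / 50 validation
samples with `(w=5, b=10, lr=0.01)`; both at 0.1% additive noise with
their full published stage-2 grids. The full 12-dataset × 5-method
benchmark is available through the `compare` command as a long-running
opt-in.

## Known limitations

* At 10–20% noise the selected model often carries extra terms (as in the
  original study); correct models may appear lower in the ranking.
* The weak-form test-function family is a reasonable default, not a tuned
  reimplementation of any specific weak-SINDy variant.
* Hill bases assume unit half-max constants; rational-function discovery
  and stochastic dynamics are out of scope.
* Coefficient identifiability on compositional (sum-to-one) data is
  limited by simplex collinearity, as discussed above.
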