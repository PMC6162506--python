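# Methods

`swarmgate` automates flow-cytometry gating: given labeled event tables
(rows = cells, columns = scatter/fluorescence channels), it trains a
soft-margin support vector machine, tunes the two hyperparameters that
dominate its accuracy — the penalty factor `c` and the kernel parameter
`g` — with a particle-swarm optimizer extended by an adaptive mutation
step, and evaluates held-out correctness. This note records the models,
the defaults and their rationale, the numerical choices, and what the
synthetic data generator does and does not emulate.

## Soft-margin SVM

The binary classifier solves the standard dual problem

```
max_a  Σ a_i − ½ Σ_ij a_i a_j y_i y_j k(x_i, x_j)
s.t.   0 ≤ a_i ≤ c,   Σ a_i y_i = 0
```

with labels `y ∈ {−1, +1}`. Four kernel families are provided, in the
single-parameter convention a tuner needs:

| family     | k(x, y)                  | parameters read          |
|------------|--------------------------|--------------------------|
| linear     | `x·y`                    | —                        |
| polynomial | `(g·x·y + coef0)^d`      | `g`, `d` (default 3), `coef0` (default 0) |
| rbf        | `exp(−g·‖x−y‖²)`         | `g` (= 1/(2σ²))          |
| sigmoid    | `tanh(β·x·y + θ)`        | `β` (default 1), `θ` (default 0) |

The textbook Gaussian form is recovered at `g = 1/(2σ²)` and the plain
polynomial `(x·y)^d` at `g = 1, coef0 = 0`. Each family reads only its
own parameters.

**Solver.** A working-set method (compiled with numba): each step picks
the maximal KKT violator as the first index and the partner of maximal
second-order objective decrease as the second, then updates both dual
variables in closed form. Stopping: KKT gap ≤ 1e-3, measured relative to
the multiplier magnitude — identical to the usual absolute 1e-3 on
normalized problems, but well-defined when a tuner probes extreme
`(c, g)` where decision values reach 1e6. Two safety valves exist for
such pathological candidates: a machine-precision stagnation check, and
an iteration budget `min(10·n², 300·n + 30000)`; exhausting the budget
returns the current feasible iterate with a logged warning (the
candidate then scores poorly in cross-validation and is discarded),
rather than stalling or aborting a tuning run. Dual variables above
`1e-8·c` count as support vectors; the bias is the mean of
`y_i − f(x_i)` over free support vectors, or the midpoint of the KKT
feasibility interval when none are free. The dual of the sigmoid kernel
is non-concave (tanh Gram matrices are indefinite), so there the solver
returns a KKT-stationary point rather than a certified global optimum —
the standard behaviour of working-set SVM solvers.

**Multiclass.** One-vs-one: `K(K−1)/2` pairwise models, majority vote,
ties broken toward the lowest class index. The reported support-vector
count (`nSVtotal`) is the number of *distinct* training events appearing
in any pairwise model.

**Scaling.** Channels are min-max scaled to [0, 1] using parameters
fitted on the training table only; raw cytometry intensities span
10⁰–10⁴ and make kernel evaluations ill-conditioned. Scaling is on by
default and can be disabled (`--no-scale`).

## PSO with adaptive mutation

Particles minimize a fitness over a box with the classic update

```
v_i ← w·v_i + c1·rand()·(pbest_i − x_i) + c2·rand()·(gbest − x_i)
x_i ← x_i + v_i
```

with a fresh uniform draw per particle, per dimension, per term.
Defaults: `w = 0.8` fixed, `c1 = c2 = 2`, swarm 30, 100 iterations,
velocity clamp `vmax = 0.2·(hi − lo)` per dimension, positions clamped
to the box with the velocity zeroed in clamped dimensions. Each
iteration evaluates every particle once after its move; mutated
particles (below) are evaluated once more at their re-initialized
position, so the bests always reflect every sampled point.

**Adaptive mutation.** After each iteration, every particle except the
current global-best holder is, with probability `p_m = 0.1`,
re-initialized uniformly inside the box `gbest ± R`, clipped to the
bounds, where the per-dimension radius `R = mean_i |pbest_i − gbest|` is
the swarm's personal-best dispersion; the velocity is redrawn within
`±min(R, vmax)`. Early in a run the personal bests span the whole box,
so mutation re-seeds particles globally and can pull a prematurely
converged swarm out of a local optimum; as the personal bests agree the
region contracts, and mutation becomes a local resampling operator that
sharpens the optimum. This is the sense in which the mutation
continuously reduces the population's search space. Personal and global
bests are never reset, so the global-best trace is non-increasing by
construction. `p_m = 0` recovers plain PSO exactly.

A design note: re-initializing mutated particles over the *full* box
every iteration (the most literal reading of "the particle is
reinitialized") empirically destroys refinement — with the fixed-inertia
dynamics above, a particle needs tens of iterations of undisturbed
oscillation decay to localize an optimum to 1e-2, while constant
full-range mutation re-randomizes it every ~1/p_m iterations; the
global-best trace then stalls and the mutation variant converges *more
slowly* than plain PSO, inverting the intended comparison. The shrinking
region construction is the variant under which mutation both escapes
local optima and accelerates convergence.

**Benchmark.** On the 2-D Ackley function (standard constants a=20,
b=0.2, 2π; global minimum 0 at the origin), with the defaults above and
convergence declared when the global-best fitness first reaches 1e-2:
plain PSO's median convergence iteration over 20 seeds is ~62, the
adaptive-mutation variant's is ~22–25 (stable across seed sets), and the
final position lands within 0.05 of the origin per coordinate in 20/20
runs. `examples/ackley_benchmark.py` and `scripts/acceptance.py`
recompute these numbers.

## Hyperparameter tuning

The tuning objective is stratified k-fold cross-validated correctness
(percent) of the one-vs-one SVM at a candidate `(c, g)`. Defaults:
k = 5 folds; search box `c ∈ [0.01, 100]`, `g ∈ [0.01, 10]` with
log-uniform particle initialization so the small-`g` corner is
reachable. Fold assignment canonicalizes each class's events by
lexicographic feature order before the seeded shuffle, making the
objective invariant to the row order of the input table. `(c, g)` pairs
quantized to 1e-6 are memoized within a run — the swarm revisits
near-identical points; caching changes no result, only time.

Three tuners share this objective: exhaustive grid search (ties broken
toward smaller `c`, then smaller `g`), plain PSO, and AM-PSO.
`tuner_comparison` runs all three plus the untuned baseline
(`c = 1, g = 0.7` — the conventional default pairing) on identical
splits and folds, refits each winner on the full training table,
evaluates on the held-out test table, and reports the percentage-point
difference between the AM-PSO row and the baseline row.

For tuning, the swarm defaults are deliberately smaller than the
benchmark defaults: swarm 6, 10 iterations (and a 4×4 log-spaced default
grid). The CV objective costs ~30 SVM fits per point, the `(c, g)`
landscape is two-dimensional and smooth, and this effort level already
saturates it; the full four-tuner comparison on a 2,600-event table runs
in a couple of minutes on one core. Wall-clock times are reported for
orientation but never asserted.

## Synthetic flow-cytometry data

Real pulse signals have Gaussian-like intensity traces, and a stained
population forms a roughly Gaussian cluster in channel space, so each
population is a multivariate normal over six channels (FSC, SSC, FITC,
PE, APC, PerCP; arbitrary units on a 0–1000 scale), plus an additive
white-noise floor (s.d. 2% of the largest population mean, a detector
noise proxy) and truncation of negative intensities at zero.

Two stock mixtures mirror the compositions used throughout the
experiments: peripheral blood (lymphocyte/neutrophil/monocyte/debris at
proportions 0.275/0.43/0.075/0.22, the 110:172:30:88 ratio) and a
lymphocyte sub-mixture (T/B/NK at 306:232:62). Per-population counts use
largest-remainder apportionment with a floor of one event per
population, so class counts are exact and deterministic — `n = 400`
yields exactly 110/172/30/88.

Cluster locations are fixture constants chosen so the populations
separate principally in the (FITC, SSC) plane, with one deliberate
difficulty: the debris/impurity population is broad (its FITC spread of
±190 reaches the lymphocyte cluster at 580±100), reflecting the
heterogeneous autofluorescence of real debris. Consequently the untuned
default `(c=1, g=0.7)` visibly underfits (typically 1–2.5 percentage
points below a tuned model) while tuned models stay above 95% — the
regime in which hyperparameter tuning is worth demonstrating.

What the generator does **not** emulate: pulse-shape (height/width/area)
structure, spectral spillover and compensation, doublets, log-scale ADC
quantization, or non-Gaussian population shapes. Passing tests therefore
demonstrate the correctness of the algorithms and the pipeline, not
instrument-grade performance on real cytometry files; correctness values
on real data depend on panel design and gating quality and cannot be
inferred from the synthetic regime.

## Numerical and design choices

- **Degenerate inputs.** Constant channels min-max scale to 0; rows with
  non-finite values are dropped at load with a logged count (exported
  tables commonly carry saturated rows); a class smaller than the fold
  count or with fewer than 2 events is rejected with a clear error.
- **Determinism.** Every stochastic component (splits, folds, swarms,
  mutation, generator) flows from explicit integer seeds through
  `numpy.random.Generator`; identical configurations give bitwise
  identical outputs. Timing fields are excluded from any comparison.
- **Convergence iteration.** Operationalized as the first 1-based
  iteration at which the non-increasing global-best trace reaches the
  tolerance (1e-2 for Ackley); `None` if never reached.
- **Model serialization.** Versioned JSON carrying the kernel spec,
  per-pair support vectors, dual weights, biases and scaling parameters,
  so training and prediction can run as separate CLI invocations.
- **FCS input.** A minimal FCS 3.0/3.1 list-mode reader (float/double/
  integer data, little/big endian, names from $PnS/$PnN) covers exported
  event matrices; compensation keywords, analysis segments and FCS
  writing are out of scope. CSV is the primary interchange format.

## Known limitations

- The SMO-style solver targets dense problems up to a few thousand
  events per class pair; no shrinking heuristics or sparse inputs.
- No probability calibration, ν-SVM, regression variants, per-class
  penalty weighting, or Bayesian/nested tuning.
- The sigmoid kernel's indefiniteness means tuned results with it are
  stationary-point quality only; the polynomial and rbf families are the
  recommended (and default) choices.
- PSO uses a fixed inertia weight and global topology by design;
  constriction factors, neighborhood topologies and inertia schedules
  are deliberately not implemented.
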