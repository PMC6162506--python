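"""SVM hyperparameter selection: CV objective and the three tuners.

The tuning objective is stratified k-fold cross-validated correctness
(CVAcc, on the 0-100 scale) of the one-vs-one SVM at a candidate
``(c, g)``.  Three tuners maximize it over a 2-D box:

- exhaustive grid search,
- plain PSO (mutation probability 0),
- adaptive-mutation PSO.

``tuner_comparison`` runs all three plus the untuned default baseline
(c = 1, g = 0.7) on identical splits and folds, reporting CVAcc,
held-out correctness, total support vectors and wall-clock time per
tuner, along with the percentage-point improvement of the
adaptive-mutation tuner over the baseline.

Fold assignment is canonicalized: within each class, events are ordered
lexicographically by feature values, permuted by the seeded generator,
and dealt round-robin into folds — so the objective does not depend on
the row order of the input table.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .events import EventTable, apply_minmax, fit_minmax, stratified_split
from .kernels import KernelSpec
from .pso import PsoConfig, optimize
from .svm import EvaluationReport, SvmModel, evaluate, predict, train_multiclass

__all__ = [
    "TuneResult",
    "KernelComparisonRow",
    "cv_fitness",
    "tune_grid_cv",
    "tune_pso",
    "tune_ampso",
    "kernel_selection_experiment",
    "tuner_comparison",
    "DEFAULT_BOUNDS",
    "DEFAULT_BASELINE",
]

# search box for (c, g); log-uniform particle initialization makes the
# small-g corner reachable
DEFAULT_BOUNDS = ((0.01, 100.0), (0.01, 10.0))
DEFAULT_BASELINE = (1.0, 0.7)  # untuned (c, g)


@dataclass
class TuneResult:
    """Best hyperparameters found by one tuner and its search trajectory."""

    tuner_name: str
    best_c: float
    best_g: float
    cv_accuracy: float  # CVAcc, percent
    trace: list[float]  # running-best CVAcc per step/iteration
    convergence_iteration: Optional[int]
    elapsed_seconds: float = 0.0
    n_evaluations: int = 0


@dataclass
class KernelComparisonRow:
    """One kernel-family result at a given training size (defaults c, g)."""

    kernel: str
    n: int
    correctness: float
    n_correct: int
    n_total: int
    n_support_vectors: int


def _fold_assignment(table: EventTable, k: int, seed: int) -> np.ndarray:
    """Stratified fold labels, invariant to the row order of the table."""
    labels = table.require_labels()
    folds = np.empty(table.n_events, dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < k:
            raise ValueError(f"class {cls} has {idx.size} events; need >= k={k}")
        # canonical order: lexicographic by feature values (row-order invariant)
        canon = idx[np.lexsort(table.values[idx].T)]
        rng = np.random.default_rng([seed, int(cls)])
        shuffled = canon[rng.permutation(idx.size)]
        folds[shuffled] = np.arange(idx.size) % k
    return folds


def cv_fitness(
    table: EventTable,
    c: float,
    g: float,
    spec_template: KernelSpec,
    k: int = 5,
    seed: int = 0,
) -> float:
    """Stratified k-fold cross-validated correctness (percent) at ``(c, g)``."""
    if k < 2:
        raise ValueError("k must be >= 2")
    spec = spec_template.with_g(g)
    folds = _fold_assignment(table, k, seed)
    n_correct = 0
    for f in range(k):
        train = table.subset(folds != f)
        held = table.subset(folds == f)
        model = train_multiclass(train, c, spec)
        n_correct += int((predict(model, held) == held.labels).sum())
    return 100.0 * n_correct / table.n_events


class _CachedObjective:
    """Memoizes cv_fitness on (c, g) quantized to 1e-6.

    PSO revisits near-identical points; caching changes no result, only
    time.  Counts distinct evaluations.
    """

    def __init__(self, table, spec, k, seed):
        self.args = (table, spec, k, seed)
        self.cache: dict[tuple[float, float], float] = {}
        self.n_evaluations = 0

    def __call__(self, c: float, g: float) -> float:
        key = (round(float(c), 6), round(float(g), 6))
        if key not in self.cache:
            table, spec, k, seed = self.args
            self.cache[key] = cv_fitness(table, key[0], key[1], spec, k, seed)
            self.n_evaluations += 1
        return self.cache[key]


def _trace_convergence(trace: Sequence[float]) -> Optional[int]:
    """First 1-based step at which the running best reaches its final value."""
    if not len(trace):
        return None
    final = trace[-1]
    return int(np.flatnonzero(np.asarray(trace) >= final - 1e-12)[0]) + 1


def tune_grid_cv(
    table: EventTable,
    grid: tuple[Sequence[float], Sequence[float]],
    spec_template: KernelSpec,
    k: int = 5,
    seed: int = 0,
) -> TuneResult:
    """Exhaustive CV over a (c, g) grid.

    Ties are broken toward smaller c, then smaller g (simpler models);
    the trace is the running best in grid order.
    """
    c_values, g_values = (sorted(set(map(float, grid[0]))), sorted(set(map(float, grid[1]))))
    if not c_values or not g_values:
        raise ValueError("grid must be nonempty")
    obj = _CachedObjective(table, spec_template, k, seed)
    t0 = time.perf_counter()
    best = (-np.inf, None, None)
    trace: list[float] = []
    for c in c_values:
        for g in g_values:
            acc = obj(c, g)
            if acc > best[0]:  # strict: first (smallest c, g) maximizer kept
                best = (acc, c, g)
            trace.append(best[0])
    return TuneResult(
        tuner_name="grid_cv",
        best_c=best[1],
        best_g=best[2],
        cv_accuracy=best[0],
        trace=trace,
        convergence_iteration=_trace_convergence(trace),
        elapsed_seconds=time.perf_counter() - t0,
        n_evaluations=obj.n_evaluations,
    )


def _tune_swarm(
    name: str,
    table: EventTable,
    bounds,
    spec_template: KernelSpec,
    k: int,
    cfg: PsoConfig,
    seed: int,
) -> TuneResult:
    obj = _CachedObjective(table, spec_template, k, seed)
    t0 = time.perf_counter()
    (best_c, best_g), neg_best, neg_trace = optimize(
        cfg, lambda x: -obj(x[0], x[1])
    )
    trace = [-v for v in neg_trace]  # accuracy scale, non-decreasing
    return TuneResult(
        tuner_name=name,
        best_c=float(best_c),
        best_g=float(best_g),
        cv_accuracy=-neg_best,
        trace=trace,
        convergence_iteration=_trace_convergence(trace),
        elapsed_seconds=time.perf_counter() - t0,
        n_evaluations=obj.n_evaluations,
    )


def _swarm_config(bounds, cfg: Optional[PsoConfig], p_m: float, seed: int) -> PsoConfig:
    if cfg is None:
        # default search effort for hyperparameter tuning (the CV objective
        # is expensive; the (c, g) landscape is low-dimensional and smooth)
        cfg = PsoConfig(
            bounds=bounds, swarm_size=6, max_iters=10, mutation_prob=p_m,
            log_init=True, seed=seed,
        )
    else:
        cfg = PsoConfig(
            bounds=bounds, swarm_size=cfg.swarm_size, max_iters=cfg.max_iters,
            w=cfg.w, c1=cfg.c1, c2=cfg.c2, vmax=cfg.vmax, mutation_prob=p_m,
            elitist_mutation=cfg.elitist_mutation, log_init=cfg.log_init, seed=seed,
        )
    return cfg


def tune_pso(
    table: EventTable,
    bounds=DEFAULT_BOUNDS,
    spec_template: KernelSpec = KernelSpec("polynomial"),
    k: int = 5,
    cfg: Optional[PsoConfig] = None,
    seed: int = 0,
) -> TuneResult:
    """Plain PSO (no mutation) over the (c, g) box, maximizing CVAcc."""
    return _tune_swarm(
        "pso", table, bounds, spec_template, k, _swarm_config(bounds, cfg, 0.0, seed), seed
    )


def tune_ampso(
    table: EventTable,
    bounds=DEFAULT_BOUNDS,
    spec_template: KernelSpec = KernelSpec("polynomial"),
    k: int = 5,
    cfg: Optional[PsoConfig] = None,
    p_m: float = 0.1,
    seed: int = 0,
) -> TuneResult:
    """Adaptive-mutation PSO over the (c, g) box, maximizing CVAcc."""
    return _tune_swarm(
        "ampso", table, bounds, spec_template, k, _swarm_config(bounds, cfg, p_m, seed), seed
    )


def kernel_selection_experiment(
    table: EventTable,
    sizes: Sequence[int],
    defaults: tuple[float, float] = DEFAULT_BASELINE,
    seed: int = 0,
    train_fraction: float = 0.75,
    scale: bool = True,
) -> list[KernelComparisonRow]:
    """Train all four kernel families at default (c, g) on nested subsets.

    For each size, a seeded random subset is drawn, split into train and
    test, and each kernel family is trained at the default ``(c, g)``;
    the row records held-out correctness and the support-vector count.
    """
    c, g = defaults
    labels = table.require_labels()
    rows: list[KernelComparisonRow] = []
    rng = np.random.default_rng(seed)
    for n in sizes:
        if n > table.n_events:
            raise ValueError(f"size {n} exceeds table of {table.n_events} events")
        subset = table.subset(np.sort(rng.choice(table.n_events, size=n, replace=False)))
        train, test = stratified_split(subset, train_fraction, seed)
        if scale:
            params = fit_minmax(train)
            train, test = apply_minmax(train, params), apply_minmax(test, params)
        for family in ("linear", "polynomial", "rbf", "sigmoid"):
            spec = KernelSpec(family=family, g=g)
            model = train_multiclass(train, c, spec)
            report = evaluate(model, test)
            rows.append(
                KernelComparisonRow(
                    kernel=family,
                    n=n,
                    correctness=report.correctness,
                    n_correct=report.n_correct,
                    n_total=report.n_total,
                    n_support_vectors=report.n_support_vectors,
                )
            )
    return rows


@dataclass
class ComparisonReport:
    """Four-row tuner comparison on identical splits and folds."""

    tuners: list[TuneResult]
    evaluations: list[EvaluationReport]
    models: list[SvmModel] = field(repr=False, default_factory=list)
    improvement_pp: float = 0.0  # AM-PSO correctness minus baseline, percentage points

    def rows(self) -> list[dict]:
        out = []
        for t, e in zip(self.tuners, self.evaluations):
            out.append(
                {
                    "tuner": t.tuner_name,
                    "c": t.best_c,
                    "g": t.best_g,
                    "cv_accuracy": t.cv_accuracy,
                    "correctness": e.correctness,
                    "n_support_vectors": e.n_support_vectors,
                    "elapsed_seconds": t.elapsed_seconds + e.elapsed_seconds,
                }
            )
        return out


def tuner_comparison(
    table: EventTable,
    spec_template: KernelSpec = KernelSpec("polynomial"),
    bounds=DEFAULT_BOUNDS,
    grid: Optional[tuple[Sequence[float], Sequence[float]]] = None,
    k: int = 5,
    cfg: Optional[PsoConfig] = None,
    train_fraction: float = 10.0 / 13.0,
    seed: int = 0,
    scale: bool = True,
) -> ComparisonReport:
    """Baseline vs grid CV vs plain PSO vs adaptive-mutation PSO.

    All four use the identical train/test split and CV folds; each tuned
    ``(c, g)`` is refit on the full training table and evaluated on the
    held-out test table.  The report's ``improvement_pp`` is the
    adaptive-mutation row's correctness minus the baseline row's, in
    percentage points.
    """
    train, test = stratified_split(table, train_fraction, seed)
    if scale:
        params = fit_minmax(train)
        train, test = apply_minmax(train, params), apply_minmax(test, params)
    if grid is None:
        grid = (
            np.geomspace(bounds[0][0], bounds[0][1], 4).tolist(),
            np.geomspace(bounds[1][0], bounds[1][1], 4).tolist(),
        )

    c0, g0 = DEFAULT_BASELINE
    t0 = time.perf_counter()
    baseline = TuneResult(
        tuner_name="baseline",
        best_c=c0,
        best_g=g0,
        cv_accuracy=cv_fitness(train, c0, g0, spec_template, k, seed),
        trace=[],
        convergence_iteration=None,
        elapsed_seconds=time.perf_counter() - t0,
    )
    tuners = [
        baseline,
        tune_grid_cv(train, grid, spec_template, k, seed),
        tune_pso(train, bounds, spec_template, k, cfg, seed),
        tune_ampso(train, bounds, spec_template, k, cfg, seed=seed),
    ]
    models, reports = [], []
    for t in tuners:
        model = train_multiclass(train, t.best_c, spec_template.with_g(t.best_g))
        models.append(model)
        reports.append(evaluate(model, test))
    return ComparisonReport(
        tuners=tuners,
        evaluations=reports,
        models=models,
        improvement_pp=reports[3].correctness - reports[0].correctness,
    )
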