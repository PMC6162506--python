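"""Particle swarm optimization with optional adaptive mutation.

The swarm minimizes a real objective over a box.  Velocities follow the
classic update

    v_i <- w*v_i + c1*rand()*(pbest_i - x_i) + c2*rand()*(gbest - x_i)
    x_i <- x_i + v_i

with a fresh uniform draw per particle, per dimension, per term.
Adaptive mutation re-initializes each particle's position and velocity
with probability ``p_m`` after every iteration, drawing them inside the
box spanned by the swarm's personal-best dispersion around the global
best.  Personal and global bests are never reset, so the swarm keeps its
memory, and the re-initialization region contracts as the swarm agrees —
wide early (escaping local optima), narrow late (accelerating
refinement).  With ``p_m = 0`` the algorithm is plain PSO.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .errors import FitnessError

__all__ = [
    "PsoConfig",
    "SwarmState",
    "ackley",
    "init_swarm",
    "pso_step",
    "mutate",
    "optimize",
    "convergence_iteration",
]


@dataclass
class PsoConfig:
    """Swarm constants, search box and mutation setting.

    Defaults are the classic choices: fixed inertia ``w = 0.8``, cognitive
    and social factors ``c1 = c2 = 2``, velocity clamp 20% of each
    dimension's range, 30 particles, 100 iterations, mutation probability
    0.1 with the current global-best particle exempt.
    """

    bounds: Sequence[tuple[float, float]] = ((-5.0, 5.0), (-5.0, 5.0))
    swarm_size: int = 30
    max_iters: int = 100
    w: float = 0.8
    c1: float = 2.0
    c2: float = 2.0
    vmax: Optional[Sequence[float]] = None  # default: 0.2 * (hi - lo) per dim
    mutation_prob: float = 0.1
    elitist_mutation: bool = True
    log_init: bool = False  # draw initial positions log-uniformly (positive bounds)
    seed: int = 0

    def __post_init__(self) -> None:
        self.bounds = [(float(lo), float(hi)) for lo, hi in self.bounds]
        if any(not np.isfinite([lo, hi]).all() or lo >= hi for lo, hi in self.bounds):
            raise ValueError("bounds must be finite with lo < hi")
        if self.swarm_size < 2:
            raise ValueError("swarm_size must be >= 2")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if not 0.0 <= self.mutation_prob <= 1.0:
            raise ValueError("mutation_prob must lie in [0, 1]")
        if self.vmax is None:
            self.vmax = [0.2 * (hi - lo) for lo, hi in self.bounds]
        else:
            self.vmax = [float(v) for v in self.vmax]
            if any(v <= 0 for v in self.vmax):
                raise ValueError("vmax must be positive")
        if self.log_init and any(lo <= 0 for lo, _ in self.bounds):
            raise ValueError("log_init requires strictly positive bounds")

    @property
    def n_dims(self) -> int:
        return len(self.bounds)

    @property
    def lo(self) -> np.ndarray:
        return np.array([b[0] for b in self.bounds])

    @property
    def hi(self) -> np.ndarray:
        return np.array([b[1] for b in self.bounds])

    @property
    def vmax_arr(self) -> np.ndarray:
        return np.array(self.vmax)


@dataclass
class SwarmState:
    """Positions, velocities, personal bests and the global best."""

    positions: np.ndarray  # (swarm, dims)
    velocities: np.ndarray
    pbest_positions: np.ndarray
    pbest_fitness: np.ndarray
    gbest_position: np.ndarray
    gbest_fitness: float
    iteration: int = 0
    n_evaluations: int = 0
    trace: list[float] = field(default_factory=list)


def ackley(x: Sequence[float]) -> float:
    """Ackley test function: multimodal, global minimum 0 at the origin.

    ``f(x) = -20 exp(-0.2 sqrt(mean(x^2))) - exp(mean(cos(2 pi x))) + 20 + e``
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("ackley needs at least one coordinate")
    return float(
        -20.0 * np.exp(-0.2 * np.sqrt(np.mean(x**2)))
        - np.exp(np.mean(np.cos(2.0 * np.pi * x)))
        + 20.0
        + np.e
    )


def _evaluate(fitness: Callable, X: np.ndarray) -> np.ndarray:
    vals = np.array([fitness(x) for x in X], dtype=float)
    if not np.all(np.isfinite(vals)):
        bad = X[int(np.flatnonzero(~np.isfinite(vals))[0])]
        raise FitnessError(f"non-finite fitness at position {bad.tolist()}")
    return vals


def init_swarm(cfg: PsoConfig, fitness: Callable, rng: np.random.Generator) -> SwarmState:
    """Draw initial positions/velocities and evaluate once."""
    lo, hi, vmax = cfg.lo, cfg.hi, cfg.vmax_arr
    shape = (cfg.swarm_size, cfg.n_dims)
    if cfg.log_init:
        positions = np.exp(rng.uniform(np.log(lo), np.log(hi), size=shape))
    else:
        positions = rng.uniform(lo, hi, size=shape)
    velocities = rng.uniform(-vmax, vmax, size=shape)
    fits = _evaluate(fitness, positions)
    best = int(np.argmin(fits))
    return SwarmState(
        positions=positions,
        velocities=velocities,
        pbest_positions=positions.copy(),
        pbest_fitness=fits,
        gbest_position=positions[best].copy(),
        gbest_fitness=float(fits[best]),
        n_evaluations=cfg.swarm_size,
    )


def pso_step(
    state: SwarmState, cfg: PsoConfig, fitness: Callable, rng: np.random.Generator
) -> SwarmState:
    """One velocity/position update with clamping, then best bookkeeping.

    Positions are clamped to the box with the velocity zeroed in clamped
    dimensions; velocities are clamped componentwise to ``±vmax``.
    """
    shape = state.positions.shape
    r1 = rng.random(shape)
    r2 = rng.random(shape)
    v = (
        cfg.w * state.velocities
        + cfg.c1 * r1 * (state.pbest_positions - state.positions)
        + cfg.c2 * r2 * (state.gbest_position[None, :] - state.positions)
    )
    np.clip(v, -cfg.vmax_arr, cfg.vmax_arr, out=v)
    x = state.positions + v
    lo, hi = cfg.lo, cfg.hi
    clamped = (x < lo) | (x > hi)
    np.clip(x, lo, hi, out=x)
    v[clamped] = 0.0

    fits = _evaluate(fitness, x)
    improved = fits < state.pbest_fitness
    state.positions = x
    state.velocities = v
    state.pbest_positions[improved] = x[improved]
    state.pbest_fitness[improved] = fits[improved]
    best = int(np.argmin(state.pbest_fitness))
    if state.pbest_fitness[best] < state.gbest_fitness:
        state.gbest_fitness = float(state.pbest_fitness[best])
        state.gbest_position = state.pbest_positions[best].copy()
    state.n_evaluations += shape[0]
    state.iteration += 1
    return state


def mutate(
    state: SwarmState,
    cfg: PsoConfig,
    rng: np.random.Generator,
    fitness: Callable | None = None,
) -> SwarmState:
    """Re-initialize each particle with probability ``p_m`` inside the
    swarm's current search region.

    The region is the box ``gbest ± R`` (clipped to the bounds) with
    per-dimension radius ``R = mean_i |pbest_i - gbest|`` — the swarm's
    personal-best dispersion.  Early in a run the personal bests span the
    whole box, so mutation re-seeds particles globally and can pull the
    swarm out of a local optimum; as the personal bests close in on the
    global best the region contracts, so mutation turns into a local
    resampling step and the population's search space shrinks with every
    iteration.  Velocities are redrawn uniformly within ``±min(R, vmax)``.

    Positions and velocities are redrawn; personal and global bests are
    never reset, so the global-best trace cannot increase.  With
    ``elitist_mutation`` the particle currently holding the global best
    is exempt.  When ``fitness`` is given the re-initialized positions
    are evaluated immediately and the bests updated on improvement — the
    loop order of the algorithm, where every position (mutated or moved)
    is evaluated once per iteration before the next velocity update.
    """
    if cfg.mutation_prob == 0.0:
        return state
    mask = rng.random(cfg.swarm_size) < cfg.mutation_prob
    if cfg.elitist_mutation:
        mask[int(np.argmin(state.pbest_fitness))] = False
    n = int(mask.sum())
    if n:
        lo, hi, vmax = cfg.lo, cfg.hi, cfg.vmax_arr
        radius = np.abs(state.pbest_positions - state.gbest_position[None, :]).mean(axis=0)
        box_lo = np.maximum(state.gbest_position - radius, lo)
        box_hi = np.minimum(state.gbest_position + radius, hi)
        vr = np.minimum(radius, vmax)
        state.positions[mask] = rng.uniform(box_lo, box_hi, size=(n, cfg.n_dims))
        state.velocities[mask] = rng.uniform(-vr, vr, size=(n, cfg.n_dims))
        if fitness is not None:
            fits = _evaluate(fitness, state.positions[mask])
            state.n_evaluations += n
            improved = fits < state.pbest_fitness[mask]
            idx = np.flatnonzero(mask)[improved]
            state.pbest_positions[idx] = state.positions[idx]
            state.pbest_fitness[idx] = fits[improved]
            best = int(np.argmin(state.pbest_fitness))
            if state.pbest_fitness[best] < state.gbest_fitness:
                state.gbest_fitness = float(state.pbest_fitness[best])
                state.gbest_position = state.pbest_positions[best].copy()
    return state


def optimize(
    cfg: PsoConfig, fitness: Callable, callback: Callable | None = None
) -> tuple[np.ndarray, float, list[float]]:
    """Run ``max_iters`` iterations of step + mutation from ``cfg.seed``.

    Returns ``(gbest_position, gbest_fitness, trace)`` where ``trace[k]``
    is the global-best fitness after iteration ``k+1``.  Fully
    reproducible from the seed.
    """
    rng = np.random.default_rng(cfg.seed)
    state = init_swarm(cfg, fitness, rng)
    for _ in range(cfg.max_iters):
        pso_step(state, cfg, fitness, rng)
        mutate(state, cfg, rng, fitness)
        state.trace.append(state.gbest_fitness)
        if callback is not None:
            callback(state)
    return state.gbest_position.copy(), state.gbest_fitness, list(state.trace)


def convergence_iteration(trace: Sequence[float], tol: float) -> Optional[int]:
    """First 1-based iteration at which the best-fitness trace reaches ``tol``.

    The trace must be non-increasing (global-best semantics); returns
    ``None`` when the tolerance is never reached.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    trace = np.asarray(trace, dtype=float)
    if np.any(np.diff(trace) > 1e-12):
        raise ValueError("trace must be non-increasing (global-best fitness)")
    hits = np.flatnonzero(trace <= tol)
    return int(hits[0]) + 1 if hits.size else None
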