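"""Hybrid social ski-driver / spider-monkey (SSS) metaheuristic.

A population of agents minimises a black-box objective inside a box.  The
update blends two ingredients: the ski-driver velocity, which steers an
agent toward its personal best and toward the mean of the current three
best positions (with a sine/cosine stochastic gate and an annealed
exploration factor ``l``), and the spider-monkey social term, which pulls
toward the global leader and a randomly chosen partner agent.  The two are
algebraically combined into a single closed-form candidate position:

    N' = [ (o01*Gl + o11*Sm_t)
           - (l*sin(o1)*(G - N) + sin(o1)*(g - N)) * (1 - o01 - o11) ]
         / (o01 + o11)

with o01 ~ U[0,1], o11 ~ U[-1,1] (redrawn while |o01 + o11| < 1e-6),
o1 ~ U[0,1], G the personal best, g the mean of the top three, Gl the
global leader and Sm_t a random partner.  The social coefficients act
dimension by dimension (each coordinate mixes the leader and the partner
with its own draws — a crossover-like move that scales to the
several-hundred-dimensional weight vectors of the network).  A candidate replaces the agent
only if it improves the fitness (greedy acceptance), so the best-fitness
trace is monotone non-increasing.

Pure ski-driver (SSD) and spider-monkey-position (SMO) updates are also
provided as reference baselines for head-to-head comparisons in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional

import numpy as np

from .network import NetworkSpec, ParamVector, forward

DENOM_GUARD = 1e-6


@dataclass
class SSSConfig:
    y: int = 30  # population size (needs >= 4: three best + one)
    K: int = 100  # iteration budget
    lb: float = -1.0
    ub: float = 1.0
    l_start: float = 2.0  # exploration -> exploitation annealing
    l_end: float = 0.0
    tol: float = 0.0  # early stop when improvement < tol for `patience` iters
    patience: int = 25
    seed: int = 0

    def validate(self) -> None:
        if self.y < 4:
            raise ValueError(f"population size must be >= 4, got {self.y}")
        if self.K < 1:
            raise ValueError(f"iteration budget must be >= 1, got {self.K}")
        if not self.lb < self.ub:
            raise ValueError(f"bounds must satisfy lb < ub, got [{self.lb}, {self.ub}]")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class Population:
    positions: np.ndarray  # (y, d)
    velocities: np.ndarray
    fitness: np.ndarray
    pbest: np.ndarray
    pbest_fitness: np.ndarray
    gl: np.ndarray  # global leader (best-ever position)
    gl_fitness: float
    lb: float
    ub: float
    rng: np.random.Generator
    k: int = 0

    @property
    def y(self) -> int:
        return self.positions.shape[0]

    @property
    def dims(self) -> int:
        return self.positions.shape[1]


def fitness_mse(expected: np.ndarray, generated: np.ndarray) -> float:
    """Mean squared error over samples and output components."""
    a = np.asarray(expected, dtype=float)
    b = np.asarray(generated, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: expected {a.shape}, generated {b.shape}")
    return float(np.mean((a - b) ** 2))


def init_population(y: int, dims: int, lb: float, ub: float,
                    seed_or_rng=0, objective: Optional[Callable] = None) -> Population:
    """Uniformly seeded population with zero velocities.

    When ``objective`` is given the initial fitness, personal bests and the
    global leader are evaluated immediately.
    """
    if y < 4:
        raise ValueError(f"population size must be >= 4 (three best + one), got {y}")
    if not lb < ub:
        raise ValueError(f"bounds must satisfy lb < ub, got [{lb}, {ub}]")
    rng = seed_or_rng if isinstance(seed_or_rng, np.random.Generator) else np.random.default_rng(seed_or_rng)
    pos = rng.uniform(lb, ub, size=(y, dims))
    fit = np.full(y, np.inf)
    if objective is not None:
        fit = np.array([float(objective(p)) for p in pos])
    best = int(np.argmin(fit))
    return Population(
        positions=pos, velocities=np.zeros((y, dims)), fitness=fit,
        pbest=pos.copy(), pbest_fitness=fit.copy(),
        gl=pos[best].copy(), gl_fitness=float(fit[best]),
        lb=lb, ub=ub, rng=rng,
    )


def mean_global(population: Population) -> np.ndarray:
    """Componentwise mean of the three lowest-fitness positions (stable
    tie-break by agent index)."""
    if population.y < 3:
        raise ValueError("mean_global needs at least 3 agents")
    order = np.argsort(population.fitness, kind="stable")[:3]
    return population.positions[order].mean(axis=0)


def ssd_velocity(position: np.ndarray, pbest: np.ndarray, g: np.ndarray,
                 l: float, o1: float, o2: float) -> np.ndarray:
    """Ski-driver velocity: sine branch for o2 <= 0.5, cosine otherwise."""
    trig = np.sin if o2 <= 0.5 else np.cos
    return l * trig(o1) * (pbest - position) + trig(o1) * (g - position)


def sss_update(position: np.ndarray, pbest: np.ndarray, g: np.ndarray,
               gl: np.ndarray, partner: np.ndarray, l: float,
               o1, o01, o11) -> np.ndarray:
    """Closed-form hybrid candidate position (unclipped).

    ``o1``, ``o01`` and ``o11`` may be scalars or per-dimension arrays
    (they broadcast).  Caller guarantees |o01 + o11| >= the denominator
    guard.
    """
    ssd_term = l * np.sin(o1) * (pbest - position) + np.sin(o1) * (g - position)
    numerator = (o01 * gl + o11 * partner) - ssd_term * (1.0 - o01 - o11)
    return numerator / (o01 + o11)


def _draw_social(rng: np.random.Generator, dims: int, max_redraws: int = 100):
    """Per-dimension social coefficients with the denominator guard.

    The social pull operates dimension by dimension, so o(0,1) and
    o(-1,1) are drawn independently per coordinate; coordinates whose sum
    falls inside the guard band are redrawn.
    """
    o01 = rng.uniform(0, 1, dims)
    o11 = rng.uniform(-1, 1, dims)
    for _ in range(max_redraws):
        bad = np.abs(o01 + o11) < DENOM_GUARD
        if not bad.any():
            return o01, o11
        o01[bad] = rng.uniform(0, 1, bad.sum())
        o11[bad] = rng.uniform(-1, 1, bad.sum())
    return None


def step(population: Population, objective: Callable, l: float) -> Population:
    """One SSS iteration with greedy acceptance (in place; returned for
    chaining)."""
    pop = population
    g = mean_global(pop)
    for x in range(pop.y):
        draws = _draw_social(pop.rng, pop.dims)
        o1 = pop.rng.uniform(0, 1, pop.dims)
        t = int(pop.rng.integers(0, pop.y - 1))
        if t >= x:
            t += 1
        if draws is None:
            continue  # pathological draw streak: skip this agent this step
        o01, o11 = draws
        cand = sss_update(pop.positions[x], pop.pbest[x], g, pop.gl,
                          pop.positions[t], l, o1, o01, o11)
        cand = np.clip(cand, pop.lb, pop.ub)
        f = float(objective(cand))
        if not np.isfinite(f):
            continue  # infeasible candidate rejected
        if f < pop.fitness[x]:
            pop.positions[x] = cand
            pop.fitness[x] = f
            if f < pop.pbest_fitness[x]:
                pop.pbest[x] = cand.copy()
                pop.pbest_fitness[x] = f
            if f < pop.gl_fitness:
                pop.gl = cand.copy()
                pop.gl_fitness = f
    pop.k += 1
    return pop


@dataclass
class OptimizeResult:
    position: np.ndarray
    fitness: float
    trace: List[float]
    n_iterations: int


def optimize(objective: Callable, dims: int, config: SSSConfig | None = None) -> OptimizeResult:
    """Run the SSS loop: K iterations or early stop on stalled improvement."""
    config = config or SSSConfig()
    config.validate()
    pop = init_population(config.y, dims, config.lb, config.ub,
                          np.random.default_rng(config.seed), objective)
    trace: List[float] = []
    stalled = 0
    for k in range(config.K):
        l = config.l_start + (config.l_end - config.l_start) * k / max(config.K - 1, 1)
        prev = pop.gl_fitness
        step(pop, objective, l)
        trace.append(pop.gl_fitness)
        if prev - pop.gl_fitness < config.tol:
            stalled += 1
            if config.tol > 0 and stalled >= config.patience:
                break
        else:
            stalled = 0
    return OptimizeResult(position=pop.gl.copy(), fitness=pop.gl_fitness,
                          trace=trace, n_iterations=pop.k)


# ---------------------------------------------------------------------------
# reference baselines (test comparators only)

def optimize_ssd(objective: Callable, dims: int, config: SSSConfig | None = None) -> OptimizeResult:
    """Pure ski-driver: velocity update + greedy acceptance."""
    config = config or SSSConfig()
    config.validate()
    pop = init_population(config.y, dims, config.lb, config.ub,
                          np.random.default_rng(config.seed), objective)
    trace: List[float] = []
    for k in range(config.K):
        l = config.l_start + (config.l_end - config.l_start) * k / max(config.K - 1, 1)
        g = mean_global(pop)
        for x in range(pop.y):
            o1 = float(pop.rng.uniform(0, 1))
            o2 = float(pop.rng.uniform(0, 1))
            vel = ssd_velocity(pop.positions[x], pop.pbest[x], g, l, o1, o2)
            cand = np.clip(pop.positions[x] + vel, pop.lb, pop.ub)
            f = float(objective(cand))
            if np.isfinite(f) and f < pop.fitness[x]:
                pop.positions[x] = cand
                pop.velocities[x] = vel
                pop.fitness[x] = f
                if f < pop.pbest_fitness[x]:
                    pop.pbest[x], pop.pbest_fitness[x] = cand.copy(), f
                if f < pop.gl_fitness:
                    pop.gl, pop.gl_fitness = cand.copy(), f
        pop.k += 1
        trace.append(pop.gl_fitness)
    return OptimizeResult(pop.gl.copy(), pop.gl_fitness, trace, pop.k)


def optimize_smo(objective: Callable, dims: int, config: SSSConfig | None = None) -> OptimizeResult:
    """Spider-monkey position term only, with greedy acceptance."""
    config = config or SSSConfig()
    config.validate()
    pop = init_population(config.y, dims, config.lb, config.ub,
                          np.random.default_rng(config.seed), objective)
    trace: List[float] = []
    for _ in range(config.K):
        for x in range(pop.y):
            o01 = float(pop.rng.uniform(0, 1))
            o11 = float(pop.rng.uniform(-1, 1))
            t = int(pop.rng.integers(0, pop.y - 1))
            if t >= x:
                t += 1
            cand = (pop.positions[x]
                    + o01 * (pop.gl - pop.positions[x])
                    + o11 * (pop.positions[t] - pop.positions[x]))
            cand = np.clip(cand, pop.lb, pop.ub)
            f = float(objective(cand))
            if np.isfinite(f) and f < pop.fitness[x]:
                pop.positions[x], pop.fitness[x] = cand, f
                if f < pop.pbest_fitness[x]:
                    pop.pbest[x], pop.pbest_fitness[x] = cand.copy(), f
                if f < pop.gl_fitness:
                    pop.gl, pop.gl_fitness = cand.copy(), f
        pop.k += 1
        trace.append(pop.gl_fitness)
    return OptimizeResult(pop.gl.copy(), pop.gl_fitness, trace, pop.k)


# ---------------------------------------------------------------------------
# network training

def one_hot(labels: np.ndarray, classes) -> np.ndarray:
    classes = list(classes)
    out = np.zeros((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        out[i, classes.index(lab)] = 1.0
    return out


def train_drn(X: np.ndarray, y_labels: np.ndarray, spec: NetworkSpec,
              config: SSSConfig | None = None, classes=None):
    """Optimise the network's flat weight vector by SSS with MSE fitness.

    The objective is the mean squared error between one-hot labels and the
    softmax output on the training matrix.  Returns
    ``(ParamVector, best_fitness, trace, classes)``.
    """
    config = config or SSSConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y_labels = np.asarray(y_labels)
    if classes is None:
        classes = sorted(np.unique(y_labels).tolist())
    if len(classes) < 2:
        raise ValueError("training needs at least two classes")
    target = one_hot(y_labels, classes)
    dims = ParamVector.zeros(spec).flat.size

    def objective(flat: np.ndarray) -> float:
        probs = forward(spec, flat, X)
        return fitness_mse(target, probs)

    result = optimize(objective, dims, config)
    params = ParamVector.from_flat(spec, result.position)
    return params, result.fitness, result.trace, classes
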