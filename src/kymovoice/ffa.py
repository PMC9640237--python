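"""Farmland fertility algorithm (FFA), a population metaheuristic.

The population of N candidate solutions is split by index into k equal
"soil regions".  Each iteration, for a minimization problem:

1. the worst region (largest mean fitness) is identified;
2. every individual of the worst region is refertilized toward a random
   member of the *global memory* (the best round(t*N) individuals):
   ``x' = x + h1 (x - x_mem)`` with ``h1 = alpha * U(-1, 1)``;
3. individuals of the other regions move relative to a random peer drawn
   from the whole population: ``x' = x + h2 (x - x_u)`` with
   ``h2 = beta * U(0, 1)``;
4. memories are refreshed (*local memory* per region holds its best
   round(t*n) individuals);
5. every individual is fused with the best solutions: with probability Q it
   moves by ``omega1 * (x - best_global)``, otherwise each coordinate moves
   toward or away from the region's local best by a random fraction,
   ``x_j + U(-1, 1) * (x_j - best_local_j)``;
6. the step factor decays, ``omega1 <- omega1 * U(0, 1)``.

Moves are clipped to the box bounds, and every proposal is accepted only if
it improves fitness (greedy replacement), which makes the best-so-far trace
monotone non-increasing.

Random draw order (one seeded generator): initialization draws the N-by-D
uniform matrix row-major; the worst-region phase draws the memory indices as
one batch then the h1 factors as one batch; the other-region phase draws
peer indices then the h2 factors; the fusion phase draws the branch
variables for all N individuals, then the local-branch scale factors for
all N as an N-by-D matrix (consumed only where the local branch is taken);
finally one uniform draw decays omega1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "FFAConfig",
    "Bounds",
    "FFAState",
    "FFAResult",
    "initialize",
    "partition_regions",
    "worst_region",
    "update_memories",
    "refertilize_worst",
    "refertilize_others",
    "fuse_with_best",
    "decay_omega",
    "optimize",
    "sphere",
    "rosenbrock",
    "rastrigin",
    "BENCHMARKS",
]

Objective = Callable[[np.ndarray], float]


@dataclass(frozen=True)
class FFAConfig:
    """Algorithm constants.

    ``N`` individuals in ``k`` regions (N divisible by k, k >= 2);
    ``t`` in [0.1, 1] sets the memory sizes round(t*n) and round(t*N);
    ``alpha`` scales the worst-region move, ``beta`` the other-region move;
    ``Q`` is the probability of fusing with the global rather than local
    best (0.7 by convention); ``omega1_init`` the initial decay factor
    (1 by convention).
    """

    N: int = 40
    k: int = 4
    t: float = 0.5
    alpha: float = 0.5
    beta: float = 0.5
    Q: float = 0.7
    omega1_init: float = 1.0
    max_iters: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.N < self.k or self.N % self.k != 0:
            raise ValueError("N must be a positive multiple of k")
        if not 0.1 <= self.t <= 1.0:
            raise ValueError("t must be in [0.1, 1]")
        for name in ("alpha", "beta", "Q"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.omega1_init <= 0:
            raise ValueError("omega1_init must be positive")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")

    @property
    def n_per_region(self) -> int:
        return self.N // self.k

    @property
    def m_local(self) -> int:
        return int(np.round(self.t * self.n_per_region))

    @property
    def m_global(self) -> int:
        return int(np.round(self.t * self.N))


@dataclass(frozen=True)
class Bounds:
    """Per-dimension box bounds L < U."""

    L: np.ndarray
    U: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "L", np.atleast_1d(np.asarray(self.L, dtype=np.float64)))
        object.__setattr__(self, "U", np.atleast_1d(np.asarray(self.U, dtype=np.float64)))
        if self.L.shape != self.U.shape:
            raise ValueError("L and U must have the same shape")
        if not (self.L < self.U).all():
            raise ValueError("need L < U elementwise")

    @property
    def dim(self) -> int:
        return len(self.L)

    def clip(self, X: np.ndarray) -> np.ndarray:
        return np.clip(X, self.L, self.U)


@dataclass
class FFAState:
    """Population, fitness, memories, and decay state of the optimizer."""

    X: np.ndarray
    fitness: np.ndarray
    local_memory: list[np.ndarray]
    local_memory_fitness: list[np.ndarray]
    global_memory: np.ndarray
    global_memory_fitness: np.ndarray
    omega1: float
    iteration: int
    best_x: np.ndarray
    best_fitness: float
    rng: np.random.Generator


def _evaluate(objective: Objective, X: np.ndarray) -> np.ndarray:
    fits = np.array([float(objective(x)) for x in X], dtype=np.float64)
    if not np.isfinite(fits).all():
        bad = int(np.flatnonzero(~np.isfinite(fits))[0])
        raise ValueError(
            f"objective returned a non-finite value for individual {bad}: {X[bad]}"
        )
    return fits


def initialize(objective: Objective, bounds: Bounds, cfg: FFAConfig) -> FFAState:
    """Uniform-in-box initialization with fitness evaluation and memory fill."""
    if cfg.m_local == 0 or cfg.m_global == 0:
        raise ValueError("memory size rounds to 0; increase t")
    rng = np.random.default_rng(cfg.seed)
    X = bounds.L + rng.random((cfg.N, bounds.dim)) * (bounds.U - bounds.L)
    fitness = _evaluate(objective, X)
    best = int(np.argmin(fitness))
    state = FFAState(
        X=X, fitness=fitness,
        local_memory=[], local_memory_fitness=[],
        global_memory=np.empty((0, bounds.dim)), global_memory_fitness=np.empty(0),
        omega1=cfg.omega1_init, iteration=0,
        best_x=X[best].copy(), best_fitness=float(fitness[best]),
        rng=rng,
    )
    update_memories(state, cfg)
    return state


def partition_regions(cfg: FFAConfig) -> list[np.ndarray]:
    """Index sets of the k regions: region a holds individuals a*n .. a*n+n-1."""
    n = cfg.n_per_region
    return [np.arange(a * n, (a + 1) * n) for a in range(cfg.k)]


def worst_region(state: FFAState, cfg: FFAConfig) -> int:
    """Region with the largest mean fitness (worst soil); ties -> lowest index."""
    means = state.fitness.reshape(cfg.k, cfg.n_per_region).mean(axis=1)
    return int(np.argmax(means))


def update_memories(state: FFAState, cfg: FFAConfig) -> FFAState:
    """Refresh local/global memories with the current best individuals."""
    ml, mg = cfg.m_local, cfg.m_global
    if ml == 0 or mg == 0:
        raise ValueError("memory size rounds to 0; increase t")
    order = np.argsort(state.fitness, kind="stable")
    state.global_memory = state.X[order[:mg]].copy()
    state.global_memory_fitness = state.fitness[order[:mg]].copy()
    state.local_memory = []
    state.local_memory_fitness = []
    for idx in partition_regions(cfg):
        local_order = idx[np.argsort(state.fitness[idx], kind="stable")]
        state.local_memory.append(state.X[local_order[:ml]].copy())
        state.local_memory_fitness.append(state.fitness[local_order[:ml]].copy())
    return state


def _greedy_accept(
    state: FFAState,
    idx: np.ndarray,
    proposals: np.ndarray,
    objective: Objective,
) -> None:
    """Evaluate proposals and keep each only where fitness strictly improves."""
    new_fit = _evaluate(objective, proposals)
    better = new_fit < state.fitness[idx]
    sel = idx[better]
    state.X[sel] = proposals[better]
    state.fitness[sel] = new_fit[better]
    if better.any():
        local_best = int(np.argmin(new_fit[better]))
        if new_fit[better][local_best] < state.best_fitness:
            state.best_fitness = float(new_fit[better][local_best])
            state.best_x = proposals[better][local_best].copy()


def refertilize_worst(
    state: FFAState, cfg: FFAConfig, objective: Objective, bounds: Bounds
) -> FFAState:
    """Move every individual of the worst region toward/away from a random
    global-memory member: x' = x + h1 (x - x_mem), h1 = alpha * U(-1, 1)."""
    if len(state.global_memory) == 0:
        raise ValueError("global memory is empty; call update_memories first")
    a = worst_region(state, cfg)
    idx = partition_regions(cfg)[a]
    mem_idx = state.rng.integers(0, len(state.global_memory), size=len(idx))
    h1 = cfg.alpha * state.rng.uniform(-1.0, 1.0, size=len(idx))
    Xi = state.X[idx]
    proposals = bounds.clip(Xi + h1[:, None] * (Xi - state.global_memory[mem_idx]))
    _greedy_accept(state, idx, proposals, objective)
    return state


def refertilize_others(
    state: FFAState, cfg: FFAConfig, objective: Objective, bounds: Bounds
) -> FFAState:
    """Move every individual outside the worst region relative to a random
    peer from the whole population: x' = x + h2 (x - x_u), h2 = beta * U(0, 1)."""
    a = worst_region(state, cfg)
    idx = np.concatenate([r for b, r in enumerate(partition_regions(cfg)) if b != a])
    snapshot = state.X.copy()  # peers drawn from the pre-phase population
    peer = state.rng.integers(0, cfg.N, size=len(idx))
    h2 = cfg.beta * state.rng.uniform(0.0, 1.0, size=len(idx))
    Xi = state.X[idx]
    proposals = bounds.clip(Xi + h2[:, None] * (Xi - snapshot[peer]))
    _greedy_accept(state, idx, proposals, objective)
    return state


def fuse_with_best(
    state: FFAState, cfg: FFAConfig, objective: Objective, bounds: Bounds
) -> FFAState:
    """Fuse each individual with the global or its region's local best.

    With probability Q the move is ``omega1 * (x - best_global)``; otherwise
    each coordinate moves by a fresh ``U(-1, 1)`` fraction of its offset
    from the region's local best, covering both the toward- and away-
    senses of the fusion (the two directional readings either stall or
    collapse the population; the symmetric per-coordinate form subsumes
    both).  Proposals are clipped to bounds and accepted greedily.
    """
    dim = state.X.shape[1]
    branch = state.rng.uniform(0.0, 1.0, size=cfg.N)
    local_scale = state.rng.uniform(-1.0, 1.0, size=(cfg.N, dim))
    gb = state.global_memory[0]
    lb = np.vstack([
        state.local_memory[a][0]
        for a in range(cfg.k)
        for _ in range(cfg.n_per_region)
    ])
    take_global = cfg.Q > branch
    scale = np.where(take_global[:, None], state.omega1, local_scale)
    target = np.where(take_global[:, None], gb[None, :], lb)
    proposals = bounds.clip(state.X + scale * (state.X - target))
    _greedy_accept(state, np.arange(cfg.N), proposals, objective)
    return state


def decay_omega(state: FFAState) -> FFAState:
    """omega1 <- omega1 * U(0, 1): strictly non-increasing over iterations."""
    state.omega1 *= float(state.rng.uniform(0.0, 1.0))
    return state


@dataclass
class FFAResult:
    best_x: np.ndarray
    best_fitness: float
    trace: np.ndarray  # best-so-far fitness per iteration
    state: FFAState = field(repr=False)


def optimize(
    objective: Objective,
    bounds: Bounds,
    cfg: FFAConfig,
    initial_guess: np.ndarray | Sequence[float] | None = None,
) -> FFAResult:
    """Run the full optimizer loop for ``cfg.max_iters`` iterations.

    Each iteration: worst-region refertilization -> other-region
    refertilization -> memory update -> fusion with best -> omega decay.
    ``initial_guess``, when given, replaces the first individual of the
    initial population (a warm start used e.g. to seed a known default
    configuration).  Returns the best solution ever evaluated and the
    monotone best-so-far trace.
    """
    state = initialize(objective, bounds, cfg)
    if initial_guess is not None:
        guess = bounds.clip(np.asarray(initial_guess, dtype=np.float64))
        state.X[0] = guess
        state.fitness[0] = _evaluate(objective, guess[None, :])[0]
        if state.fitness[0] < state.best_fitness:
            state.best_fitness = float(state.fitness[0])
            state.best_x = guess.copy()
        update_memories(state, cfg)
    trace = np.empty(cfg.max_iters)
    for d in range(cfg.max_iters):
        refertilize_worst(state, cfg, objective, bounds)
        refertilize_others(state, cfg, objective, bounds)
        update_memories(state, cfg)
        fuse_with_best(state, cfg, objective, bounds)
        decay_omega(state)
        state.iteration = d + 1
        trace[d] = state.best_fitness
    update_memories(state, cfg)
    return FFAResult(
        best_x=state.best_x.copy(), best_fitness=state.best_fitness,
        trace=trace, state=state,
    )


# ---------------------------------------------------------------------------
# Benchmark objectives


def sphere(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=np.float64)
    return float(np.dot(x, x))


def rosenbrock(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=np.float64)
    return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1.0 - x[:-1]) ** 2))


def rastrigin(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=np.float64)
    return float(10.0 * len(x) + np.sum(x**2 - 10.0 * np.cos(2.0 * np.pi * x)))


BENCHMARKS = {"sphere": sphere, "rosenbrock": rosenbrock, "rastrigin": rastrigin}
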