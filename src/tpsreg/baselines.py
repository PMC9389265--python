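"""Comparison optimizers sharing the TPSysIR objective/bounds contracts.

Three classic derivative-free maximizers over the same 4-D transform box:
a flat global-best PSO, a real-coded GA, and a PSO whose best point is
polished by Powell-style coordinate-direction line searches. All return
the same :class:`~tpsreg.tps_core.RegistrationResult` shape with a
non-decreasing best-score trace and are pure functions of
(objective, bounds, config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .imaging import Image2D, TransformParams, similarity
from .tps_core import DEFAULT_BOUNDS, RegistrationResult

__all__ = [
    "PSOConfig",
    "GAConfig",
    "PowellConfig",
    "optimize_pso",
    "optimize_ga",
    "optimize_pso_powell",
    "run_pso",
    "run_ga",
    "run_pso_powell",
]


def _check_bounds(bounds) -> tuple[np.ndarray, np.ndarray]:
    bounds = tuple(bounds)
    if not bounds:
        raise ValueError("bounds must be nonempty")
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    if np.any(hi < lo):
        raise ValueError("each bound must satisfy lo <= hi")
    return lo, hi


@dataclass(frozen=True)
class PSOConfig:
    swarm: int = 30
    iters: int = 60
    omega_start: float = 0.9
    omega_end: float = 0.4
    c1: float = 2.0  # cognitive
    c2: float = 2.0  # social
    bins: int = 64

    def __post_init__(self) -> None:
        if self.swarm < 1 or self.iters < 1:
            raise ValueError("swarm and iters must be >= 1")


@dataclass(frozen=True)
class GAConfig:
    population: int = 40
    generations: int = 80
    crossover_rate: float = 0.9
    mutation_rate: float = 0.1
    tournament_k: int = 3
    blend_alpha: float = 0.5
    sigma_frac: float = 0.1  # mutation sd as a fraction of the bound width
    bins: int = 64

    def __post_init__(self) -> None:
        if self.population < 2 or self.generations < 1:
            raise ValueError("population must be >= 2 and generations >= 1")


@dataclass(frozen=True)
class PowellConfig:
    pso: PSOConfig = PSOConfig()
    tol: float = 1e-4
    max_sweeps: int = 20
    bins: int = 64


def optimize_pso(objective, bounds, config: PSOConfig, seed: int) -> RegistrationResult:
    """Flat global-best PSO maximizing ``objective`` inside ``bounds``.

    Inertia decays linearly; velocities are clamped to half the bound
    width per dimension and positions clipped into bounds, matching the
    tissue-P-system contracts.
    """
    lo, hi = _check_bounds(bounds)
    dim = lo.size
    rng = np.random.default_rng(seed)
    clamp = 0.5 * (hi - lo)

    pos = lo + (hi - lo) * rng.random((config.swarm, dim))
    vel = np.zeros((config.swarm, dim))
    pbest = pos.copy()
    pbest_score = np.array([objective(p) for p in pos])
    g = int(np.argmax(pbest_score))
    gbest, gbest_score = pbest[g].copy(), float(pbest_score[g])

    trace = []
    for t in range(config.iters):
        if config.iters == 1:
            omega = config.omega_start
        else:
            omega = config.omega_start + (
                config.omega_end - config.omega_start
            ) * t / (config.iters - 1)
        r1 = rng.random((config.swarm, dim))
        r2 = rng.random((config.swarm, dim))
        vel = (
            omega * vel
            + config.c1 * r1 * (pbest - pos)
            + config.c2 * r2 * (gbest - pos)
        )
        vel = np.clip(vel, -clamp, clamp)
        pos = np.clip(pos + vel, lo, hi)
        scores = np.array([objective(p) for p in pos])
        improved = scores > pbest_score
        pbest[improved] = pos[improved]
        pbest_score[improved] = scores[improved]
        g = int(np.argmax(pbest_score))
        if pbest_score[g] > gbest_score:
            gbest, gbest_score = pbest[g].copy(), float(pbest_score[g])
        trace.append((t, gbest_score))

    return RegistrationResult(
        best_params=_to_params(gbest),
        best_score=gbest_score,
        trace=tuple(trace),
        steps_run=config.iters,
        seed=seed,
    )


def optimize_ga(objective, bounds, config: GAConfig, seed: int) -> RegistrationResult:
    """Real-coded GA: tournament selection, blend crossover, Gaussian
    mutation clipped to bounds, elitism of one."""
    lo, hi = _check_bounds(bounds)
    dim = lo.size
    rng = np.random.default_rng(seed)
    width = hi - lo

    pop = lo + width * rng.random((config.population, dim))
    fitness = np.array([objective(p) for p in pop])
    e = int(np.argmax(fitness))
    best, best_score = pop[e].copy(), float(fitness[e])

    trace = []
    for gen in range(config.generations):
        def tournament() -> np.ndarray:
            idx = rng.integers(config.population, size=config.tournament_k)
            return pop[idx[np.argmax(fitness[idx])]]

        children = [best.copy()]  # elitism of 1
        while len(children) < config.population:
            p1, p2 = tournament(), tournament()
            if rng.random() < config.crossover_rate:
                # BLX-alpha blend crossover
                span = np.abs(p1 - p2)
                lo_c = np.minimum(p1, p2) - config.blend_alpha * span
                hi_c = np.maximum(p1, p2) + config.blend_alpha * span
                child = lo_c + (hi_c - lo_c) * rng.random(dim)
            else:
                child = p1.copy()
            mutate = rng.random(dim) < config.mutation_rate
            child = child + mutate * rng.normal(0.0, 1.0, dim) * (
                config.sigma_frac * width
            )
            children.append(np.clip(child, lo, hi))
        pop = np.array(children)
        fitness = np.array([objective(p) for p in pop])
        e = int(np.argmax(fitness))
        if fitness[e] > best_score:
            best, best_score = pop[e].copy(), float(fitness[e])
        trace.append((gen, best_score))

    return RegistrationResult(
        best_params=_to_params(best),
        best_score=best_score,
        trace=tuple(trace),
        steps_run=config.generations,
        seed=seed,
    )


def optimize_pso_powell(
    objective, bounds, config: PowellConfig, seed: int
) -> RegistrationResult:
    """PSO followed by Powell-style coordinate-direction refinement.

    The swarm's best point is polished by successive bounded scalar line
    maximizations along each parameter axis until a full sweep improves
    the score by less than ``tol`` or ``max_sweeps`` is reached. Only
    improvements are accepted, so the final score never drops below the
    swarm's.
    """
    lo, hi = _check_bounds(bounds)
    pso_res = optimize_pso(objective, bounds, config.pso, seed)
    if not np.isfinite(config.tol):
        return pso_res  # refinement disabled limit
    best = _from_params(pso_res.best_params, lo.size)
    best_score = pso_res.best_score
    trace = list(pso_res.trace)

    sweep = 0
    while sweep < config.max_sweeps:
        improved = 0.0
        for d in range(lo.size):
            if hi[d] - lo[d] <= 0:
                continue

            def neg_along(v: float, d: int = d) -> float:
                trial = best.copy()
                trial[d] = v
                return -objective(trial)

            res = minimize_scalar(
                neg_along, bounds=(lo[d], hi[d]), method="bounded",
                options={"xatol": 1e-6},
            )
            if -res.fun > best_score:
                improved += -res.fun - best_score
                best_score = float(-res.fun)
                best[d] = float(res.x)
        sweep += 1
        trace.append((pso_res.steps_run + sweep - 1, best_score))
        if improved < config.tol:
            break

    return RegistrationResult(
        best_params=_to_params(best),
        best_score=best_score,
        trace=tuple(trace),
        steps_run=pso_res.steps_run + sweep,
        seed=seed,
    )


def _to_params(vec: np.ndarray) -> TransformParams:
    """Pack an optimizer vector into TransformParams.

    Surrogate objectives may use fewer or more than 4 dimensions; missing
    trailing components default to the identity transform values.
    """
    v = list(np.asarray(vec, dtype=float))
    defaults = [0.0, 0.0, 0.0, 1.0]
    v = (v + defaults[len(v):])[:4]
    return TransformParams(x=v[0], y=v[1], theta=v[2], z=v[3])


def _from_params(params: TransformParams, dim: int) -> np.ndarray:
    return params.to_array()[:dim].copy()


def _mi_objective(ref: Image2D, flt: Image2D, bins: int):
    def objective(p: np.ndarray) -> float:
        return similarity(ref, flt, TransformParams.from_array(p), bins=bins)

    return objective


def run_pso(
    ref: Image2D,
    flt: Image2D,
    bounds=DEFAULT_BOUNDS,
    config: PSOConfig = PSOConfig(),
    seed: int = 0,
) -> RegistrationResult:
    """Register with plain PSO on the MI objective."""
    return optimize_pso(_mi_objective(ref, flt, config.bins), bounds, config, seed)


def run_ga(
    ref: Image2D,
    flt: Image2D,
    bounds=DEFAULT_BOUNDS,
    config: GAConfig = GAConfig(),
    seed: int = 0,
) -> RegistrationResult:
    """Register with the real-coded GA on the MI objective."""
    return optimize_ga(_mi_objective(ref, flt, config.bins), bounds, config, seed)


def run_pso_powell(
    ref: Image2D,
    flt: Image2D,
    bounds=DEFAULT_BOUNDS,
    config: PowellConfig = PowellConfig(),
    seed: int = 0,
) -> RegistrationResult:
    """Register with PSO followed by Powell coordinate refinement."""
    return optimize_pso_powell(
        _mi_objective(ref, flt, config.bins), bounds, config, seed
    )
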