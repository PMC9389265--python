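"""The tissue-P-system optimizer core.

A tissue P system here is a fixed three-level membrane tree connected by
bidirectional channels. The nine leaf (level-3) membranes each hold a small
particle swarm whose objects — transform-parameter tuples — evolve under a
PSO-style velocity/position rule with three attractors: the membrane's own
local best, a best randomly chosen among sibling membranes, and the best
handed down by the parent. Communication rules copy (never move) local
bests between siblings, up to the three level-2 membranes and finally to
the single level-1 output membrane, whose object at halting is the answer.

All selection rules are max-substitutions with incumbent-keeping ties, so
every membrane's best score — and the global best — is non-decreasing over
steps. The whole run is a pure function of (objective, config, seed).

The objective is an opaque callable mapping a 4-vector ``(x, y, theta, z)``
to a real score to be maximized; this module never touches pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .imaging import Image2D, TransformParams, similarity

__all__ = [
    "TissueTopology",
    "MembraneState",
    "EvolutionConfig",
    "RegistrationResult",
    "build_topology",
    "inertia_weight",
    "select_neighbor_best",
    "evolve_membrane",
    "intra_communicate",
    "inter_communicate",
    "select_substitute",
    "promote_global",
    "tps_step",
    "optimize_tps",
    "run_tps",
]

Objective = Callable[[np.ndarray], float]

#: default search box: +-15 px translation, +-15 deg rotation, scale 2/3..1.5
DEFAULT_BOUNDS: tuple[tuple[float, float], ...] = (
    (-15.0, 15.0),
    (-15.0, 15.0),
    (-15.0, 15.0),
    (2.0 / 3.0, 1.5),
)


@dataclass(frozen=True)
class TissueTopology:
    """The fixed 13-membrane, 3-level tree with its channel graph."""

    membrane_ids: tuple[str, ...]
    level: dict
    children: dict
    channels: frozenset  # of ordered (a, b) pairs; symmetric

    def parent_of(self, mid: str) -> str | None:
        for parent, kids in self.children.items():
            if mid in kids:
                return parent
        return None


def build_topology() -> TissueTopology:
    """Build the 1 + 3 + 9 membrane tree.

    The level-1 output membrane has three level-2 children; each of those
    has three level-3 children. Channels connect every parent-child pair
    and every sibling pair sharing a parent, bidirectionally.
    """
    out = "m0"
    level = {out: 1}
    children: dict[str, list[str]] = {out: []}
    channels: set[tuple[str, str]] = set()

    def connect(a: str, b: str) -> None:
        channels.add((a, b))
        channels.add((b, a))

    for i in range(1, 4):
        mid = f"m0{i}"
        level[mid] = 2
        children[out].append(mid)
        children[mid] = []
        connect(out, mid)
        for j in range(1, 4):
            leaf = f"m0{i}{j}"
            level[leaf] = 3
            children[mid].append(leaf)
            children[leaf] = []
            connect(mid, leaf)
    for sibs in list(children.values()):
        for a in sibs:
            for b in sibs:
                if a != b:
                    connect(a, b)
    ids = tuple(sorted(level, key=lambda m: (level[m], m)))
    return TissueTopology(
        membrane_ids=ids,
        level=dict(level),
        children={k: tuple(v) for k, v in children.items()},
        channels=frozenset(channels),
    )


@dataclass
class MembraneState:
    """Mutable per-membrane state.

    Level-3 membranes hold particles; level-2 and the output membrane only
    aggregate. ``neighbor_bests`` and ``pool`` hold value-copies of
    (params 4-vector, score) pairs received over channels; the score rides
    along so selection rules need not re-evaluate the objective.
    """

    id: str
    positions: np.ndarray | None = None  # (m, 4) leaf membranes only
    velocities: np.ndarray | None = None  # (m, 4)
    local_best: np.ndarray | None = None
    local_best_score: float = -np.inf
    neighbor_bests: list = field(default_factory=list)
    parent_best: tuple | None = None  # (params, score)
    pool: list = field(default_factory=list)

    @property
    def n_particles(self) -> int:
        return 0 if self.positions is None else self.positions.shape[0]


@dataclass(frozen=True)
class EvolutionConfig:
    """Tunable knobs of the tissue-P-system run.

    ``omega_start``/``omega_end`` are the endpoints of the linearly
    decaying inertia weight; ``l0``, ``l1``, ``l2`` weight the local,
    neighbor and parent attractors; ``velocity_clamp`` defaults to half
    the bound width per dimension.
    """

    bounds: tuple[tuple[float, float], ...] = DEFAULT_BOUNDS
    omega_start: float = 0.9
    omega_end: float = 0.4
    l0: float = 1.4
    l1: float = 1.4
    l2: float = 1.4
    particles_per_membrane: int = 10
    steps: int = 40
    bins: int = 64
    seed: int = 0
    velocity_clamp: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.bounds) != 4:
            raise ValueError("bounds must cover (x, y, theta, z)")
        for lo, hi in self.bounds:
            if hi < lo:
                raise ValueError("each bound must satisfy lo <= hi")
        if self.bounds[3][0] <= 0:
            raise ValueError("scale lower bound must be positive")
        if not (self.omega_start >= self.omega_end >= 0):
            raise ValueError("need omega_start >= omega_end >= 0")
        if min(self.l0, self.l1, self.l2) < 0:
            raise ValueError("learning factors must be non-negative")
        if self.particles_per_membrane < 1 or self.steps < 1:
            raise ValueError("particles_per_membrane and steps must be >= 1")
        if self.bins < 2:
            raise ValueError("bins must be >= 2")

    def lower(self) -> np.ndarray:
        return np.array([b[0] for b in self.bounds])

    def upper(self) -> np.ndarray:
        return np.array([b[1] for b in self.bounds])

    def clamp(self) -> np.ndarray:
        if self.velocity_clamp is not None:
            return np.asarray(self.velocity_clamp, dtype=float)
        return 0.5 * (self.upper() - self.lower())


@dataclass(frozen=True)
class RegistrationResult:
    """Outcome of one optimizer run."""

    best_params: TransformParams
    best_score: float
    trace: tuple  # of (step index, global best score)
    steps_run: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "best_params": {
                "x": self.best_params.x,
                "y": self.best_params.y,
                "theta": self.best_params.theta,
                "z": self.best_params.z,
            },
            "best_score": self.best_score,
            "trace": [[int(t), float(s)] for t, s in self.trace],
            "steps_run": self.steps_run,
            "seed": self.seed,
        }


def inertia_weight(t: int, config: EvolutionConfig) -> float:
    """Linearly decaying inertia weight at step ``t`` (0-based)."""
    T = config.steps
    if T == 1:
        return config.omega_start
    frac = t / (T - 1)
    return config.omega_start + (config.omega_end - config.omega_start) * frac


def select_neighbor_best(mem: MembraneState, rng: np.random.Generator) -> np.ndarray:
    """Uniformly pick one of the bests received from sibling membranes.

    Before any communication has happened the neighbor list is empty and
    the membrane's own local best is returned, making step 1 well-defined.
    """
    if not mem.neighbor_bests:
        return np.array(mem.local_best, copy=True)
    idx = int(rng.integers(len(mem.neighbor_bests)))
    return np.array(mem.neighbor_bests[idx][0], copy=True)


def evolve_membrane(
    mem: MembraneState,
    objective: Objective,
    t: int,
    config: EvolutionConfig,
    rng: np.random.Generator,
) -> MembraneState:
    """One velocity/position update plus local-best selection in one leaf.

    Per particle and per dimension, three independent Uniform(0,1) draws
    weight the pulls toward the local, neighbor and parent attractors; the
    velocity is inertia-damped, clamped, and integrated; positions are
    clipped into bounds. The local best then becomes the argmax of the
    objective over all new positions and the incumbent, ties keeping the
    incumbent, so the local best score never decreases.
    """
    if mem.positions is None or mem.n_particles == 0:
        raise ValueError("evolve_membrane requires a leaf membrane with particles")
    m = mem.n_particles
    omega = inertia_weight(t, config)
    local = mem.local_best
    neighbor = select_neighbor_best(mem, rng)
    parent = (
        np.array(mem.parent_best[0], copy=True)
        if mem.parent_best is not None
        else np.array(local, copy=True)
    )

    z0 = rng.random((m, 4))
    z1 = rng.random((m, 4))
    z2 = rng.random((m, 4))
    vel = (
        omega * mem.velocities
        + config.l0 * z0 * (local - mem.positions)
        + config.l1 * z1 * (neighbor - mem.positions)
        + config.l2 * z2 * (parent - mem.positions)
    )
    clamp = config.clamp()
    vel = np.clip(vel, -clamp, clamp)
    pos = np.clip(mem.positions + vel, config.lower(), config.upper())
    if not (np.all(np.isfinite(vel)) and np.all(np.isfinite(pos))):
        raise ArithmeticError("non-finite particle update; check bounds/clamp")

    scores = np.array([objective(p) for p in pos])
    k = int(np.argmax(scores))
    best, best_score = mem.local_best, mem.local_best_score
    if scores[k] > best_score:  # strict: ties keep the incumbent
        best, best_score = np.array(pos[k], copy=True), float(scores[k])
    return replace(
        mem,
        positions=pos,
        velocities=vel,
        local_best=best,
        local_best_score=best_score,
    )


def intra_communicate(siblings: Sequence[MembraneState]) -> list[MembraneState]:
    """Exchange value-copies of local bests among sibling membranes.

    Each membrane's neighbor list is overwritten with copies of every other
    sibling's current local best; sources are never mutated.
    """
    bests = [
        (np.array(s.local_best, copy=True), float(s.local_best_score))
        for s in siblings
    ]
    out = []
    for i, s in enumerate(siblings):
        nb = [
            (np.array(p, copy=True), sc)
            for j, (p, sc) in enumerate(bests)
            if j != i
        ]
        out.append(replace(s, neighbor_bests=nb))
    return out


def inter_communicate(
    parent: MembraneState, children: Sequence[MembraneState]
) -> tuple[MembraneState, list[MembraneState]]:
    """Copy child bests up into the parent's pool and the parent's best down.

    Replicative in both directions: children keep their own bests, and each
    child's ``parent_best`` becomes a value-copy of the parent's current
    local best (None stays None until the parent first holds one).
    """
    pool = list(parent.pool) + [
        (np.array(c.local_best, copy=True), float(c.local_best_score))
        for c in children
    ]
    down = (
        (np.array(parent.local_best, copy=True), float(parent.local_best_score))
        if parent.local_best is not None
        else None
    )
    new_children = [replace(c, parent_best=down) for c in children]
    return replace(parent, pool=pool), new_children


def select_substitute(parent: MembraneState, objective: Objective) -> MembraneState:
    """Max-substitution at a level-2 membrane over its received pool.

    The best-scoring pooled candidate replaces the local best only when
    strictly better; ties keep the incumbent. The pool is cleared.
    """
    best, best_score = parent.local_best, parent.local_best_score
    for params, score in parent.pool:
        if score > best_score:
            best, best_score = np.array(params, copy=True), float(score)
    return replace(
        parent, local_best=best, local_best_score=best_score, pool=[]
    )


def promote_global(
    output_mem: MembraneState, level2: Sequence[MembraneState]
) -> MembraneState:
    """Promote the best level-2 object to the level-1 output membrane."""
    best, best_score = output_mem.local_best, output_mem.local_best_score
    for mem in level2:
        if mem.local_best is not None and mem.local_best_score > best_score:
            best = np.array(mem.local_best, copy=True)
            best_score = float(mem.local_best_score)
    return replace(output_mem, local_best=best, local_best_score=best_score)


def tps_step(
    state: dict,
    topology: TissueTopology,
    objective: Objective,
    t: int,
    config: EvolutionConfig,
    rng: np.random.Generator,
) -> dict:
    """One full system step, in rule order.

    Evolve all nine leaves; exchange bests within each sibling triple;
    exchange up/down with each level-2 parent; max-substitute at level 2;
    promote the global best to the output membrane.
    """
    state = dict(state)
    out_id = next(m for m in topology.membrane_ids if topology.level[m] == 1)
    level2_ids = topology.children[out_id]

    for mid in level2_ids:
        for leaf in topology.children[mid]:
            state[leaf] = evolve_membrane(state[leaf], objective, t, config, rng)
    for mid in level2_ids:
        leaves = topology.children[mid]
        for leaf, new in zip(leaves, intra_communicate([state[m] for m in leaves])):
            state[leaf] = new
    for mid in level2_ids:
        leaves = topology.children[mid]
        parent, kids = inter_communicate(state[mid], [state[m] for m in leaves])
        state[mid] = parent
        for leaf, new in zip(leaves, kids):
            state[leaf] = new
    for mid in level2_ids:
        state[mid] = select_substitute(state[mid], objective)
    state[out_id] = promote_global(state[out_id], [state[m] for m in level2_ids])
    return state


def _init_state(
    topology: TissueTopology,
    objective: Objective,
    config: EvolutionConfig,
    rng: np.random.Generator,
) -> dict:
    """Seeded initialization: uniform positions in bounds, zero velocities.

    Each leaf's local best starts as its best-scoring initial particle;
    aggregating membranes start empty.
    """
    lo, hi = config.lower(), config.upper()
    m = config.particles_per_membrane
    state: dict[str, MembraneState] = {}
    for mid in topology.membrane_ids:
        if topology.level[mid] == 3:
            pos = lo + (hi - lo) * rng.random((m, 4))
            vel = np.zeros((m, 4))
            scores = np.array([objective(p) for p in pos])
            k = int(np.argmax(scores))
            state[mid] = MembraneState(
                id=mid,
                positions=pos,
                velocities=vel,
                local_best=np.array(pos[k], copy=True),
                local_best_score=float(scores[k]),
            )
        else:
            state[mid] = MembraneState(id=mid)
    return state


def optimize_tps(objective: Objective, config: EvolutionConfig) -> RegistrationResult:
    """Run the tissue-P-system optimizer on an arbitrary objective.

    Halts after exactly ``config.steps`` full system steps and returns the
    output membrane's object with the per-step global-best trace.
    """
    topology = build_topology()
    rng = np.random.default_rng(config.seed)
    state = _init_state(topology, objective, config, rng)
    out_id = next(m for m in topology.membrane_ids if topology.level[m] == 1)
    trace = []
    for t in range(config.steps):
        state = tps_step(state, topology, objective, t, config, rng)
        trace.append((t, float(state[out_id].local_best_score)))
    out = state[out_id]
    return RegistrationResult(
        best_params=TransformParams.from_array(out.local_best),
        best_score=float(out.local_best_score),
        trace=tuple(trace),
        steps_run=config.steps,
        seed=config.seed,
    )


def run_tps(ref: Image2D, flt: Image2D, config: EvolutionConfig) -> RegistrationResult:
    """Register ``flt`` onto ``ref`` by maximizing mutual information."""

    def objective(p: np.ndarray) -> float:
        return similarity(ref, flt, TransformParams.from_array(p), bins=config.bins)

    return optimize_tps(objective, config)
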