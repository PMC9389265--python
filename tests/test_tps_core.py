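"""Tissue-P-system rule semantics, topology, and run-level contracts."""

import numpy as np
import pytest

from tpsreg.imaging import Image2D, TransformParams
from tpsreg.tps_core import (
    EvolutionConfig,
    MembraneState,
    build_topology,
    evolve_membrane,
    inertia_weight,
    inter_communicate,
    intra_communicate,
    optimize_tps,
    promote_global,
    run_tps,
    select_neighbor_best,
    select_substitute,
    tps_step,
)

BOUNDS = ((-10.0, 10.0), (-10.0, 10.0), (-10.0, 10.0), (0.5, 2.0))


def quadratic(center):
    c = np.asarray(center, dtype=float)

    def f(p):
        return -float(np.sum((np.asarray(p) - c) ** 2))

    return f


def leaf(pos, vel=None, best=None, best_score=None, objective=None):
    pos = np.atleast_2d(np.asarray(pos, dtype=float))
    vel = np.zeros_like(pos) if vel is None else np.atleast_2d(np.asarray(vel, float))
    if best is None:
        best = pos[0].copy()
    if best_score is None:
        best_score = objective(best) if objective else 0.0
    return MembraneState(
        id="m011",
        positions=pos,
        velocities=vel,
        local_best=np.asarray(best, float),
        local_best_score=float(best_score),
    )


class TestTopology:
    def test_thirteen_membranes_three_levels(self):
        topo = build_topology()
        assert len(topo.membrane_ids) == 13
        counts = {lvl: 0 for lvl in (1, 2, 3)}
        for m in topo.membrane_ids:
            counts[topo.level[m]] += 1
        assert counts == {1: 1, 2: 3, 3: 9}

    def test_each_level2_membrane_has_three_children(self):
        topo = build_topology()
        out = [m for m in topo.membrane_ids if topo.level[m] == 1][0]
        assert len(topo.children[out]) == 3
        for mid in topo.children[out]:
            assert len(topo.children[mid]) == 3

    def test_channels_symmetric_and_cover_tree_and_siblings(self):
        topo = build_topology()
        for a, b in topo.channels:
            assert (b, a) in topo.channels
        out = [m for m in topo.membrane_ids if topo.level[m] == 1][0]
        for parent, kids in topo.children.items():
            for kid in kids:
                assert (parent, kid) in topo.channels
            for a in kids:
                for b in kids:
                    if a != b:
                        assert (a, b) in topo.channels
        assert topo.parent_of(out) is None


class TestInertiaWeight:
    def test_endpoints(self):
        cfg = EvolutionConfig(bounds=BOUNDS, steps=11)
        assert inertia_weight(0, cfg) == cfg.omega_start
        assert inertia_weight(10, cfg) == cfg.omega_end

    def test_midpoint_is_linear_average(self):
        cfg = EvolutionConfig(bounds=BOUNDS, steps=11)
        assert inertia_weight(5, cfg) == pytest.approx(
            (cfg.omega_start + cfg.omega_end) / 2
        )

    def test_single_step_constant(self):
        cfg = EvolutionConfig(bounds=BOUNDS, steps=1)
        assert inertia_weight(0, cfg) == cfg.omega_start

    def test_nonincreasing(self):
        cfg = EvolutionConfig(bounds=BOUNDS, steps=7)
        ws = [inertia_weight(t, cfg) for t in range(7)]
        assert all(a >= b for a, b in zip(ws, ws[1:]))


class TestSelectNeighborBest:
    def test_singleton_always_chosen(self):
        mem = leaf([[0.0] * 4], best=[1, 1, 1, 1])
        mem.neighbor_bests = [(np.array([2.0, 2, 2, 2]), 0.5)]
        rng = np.random.default_rng(0)
        for _ in range(10):
            assert np.array_equal(
                select_neighbor_best(mem, rng), [2.0, 2, 2, 2]
            )

    def test_empty_falls_back_to_local_best(self):
        mem = leaf([[0.0] * 4], best=[3, 1, 4, 1])
        out = select_neighbor_best(mem, np.random.default_rng(0))
        assert np.array_equal(out, [3, 1, 4, 1])

    def test_three_neighbors_uniform_frequency(self):
        mem = leaf([[0.0] * 4])
        mem.neighbor_bests = [
            (np.array([float(i), 0, 0, 1]), 0.0) for i in range(3)
        ]
        rng = np.random.default_rng(42)
        draws = [select_neighbor_best(mem, rng)[0] for _ in range(3000)]
        freqs = np.bincount(np.array(draws, dtype=int), minlength=3) / 3000
        assert np.all(np.abs(freqs - 1 / 3) <= 0.03)


class TestEvolveMembrane:
    def test_pure_inertia_advances_by_velocity(self):
        cfg = EvolutionConfig(
            bounds=BOUNDS, l0=0, l1=0, l2=0, omega_start=1.0, omega_end=1.0,
            velocity_clamp=(1e9,) * 4, steps=5,
        )
        obj = quadratic([0, 0, 0, 1])
        pos = np.array([[1.0, 2.0, -3.0, 1.0], [0.0, 0.0, 0.0, 1.0]])
        vel = np.array([[0.5, -0.5, 1.0, 0.0], [1.0, 1.0, 1.0, 0.0]])
        mem = leaf(pos, vel=vel, objective=obj)
        out = evolve_membrane(mem, obj, 0, cfg, np.random.default_rng(0))
        assert np.allclose(out.positions, pos + vel)
        assert np.allclose(out.velocities, vel)

    def test_fixed_point_when_all_attractors_coincide(self):
        cfg = EvolutionConfig(bounds=BOUNDS, steps=5)
        obj = quadratic([0, 0, 0, 1])
        p = np.array([[2.0, 2.0, 2.0, 1.0]])
        mem = leaf(p, best=p[0], objective=obj)
        mem.parent_best = (p[0].copy(), obj(p[0]))
        out = evolve_membrane(mem, obj, 0, cfg, np.random.default_rng(0))
        assert np.array_equal(out.positions, p)
        assert np.array_equal(out.velocities, np.zeros((1, 4)))
        assert out.local_best_score == mem.local_best_score

    def test_matches_scalar_oracle_dimension_by_dimension(self):
        """Independent scalar reimplementation of the velocity/position rule."""
        cfg = EvolutionConfig(
            bounds=BOUNDS, steps=10, omega_start=0.9, omega_end=0.4,
            l0=1.4, l1=1.4, l2=1.4,
        )
        obj = quadratic([1, -2, 3, 1])
        pos = np.array([[1.0, -1.0, 2.0, 1.0]])
        vel = np.array([[0.3, -0.2, 0.1, 0.05]])
        local = np.array([0.5, 0.5, 0.5, 1.0])
        nbr = np.array([2.0, -2.0, 2.0, 0.8])
        par = np.array([-1.0, 1.0, -1.0, 1.2])
        mem = leaf(pos, vel=vel, best=local, best_score=obj(local))
        mem.neighbor_bests = [(nbr, obj(nbr))]
        mem.parent_best = (par, obj(par))
        t = 3
        seed = 99

        out = evolve_membrane(mem, obj, t, cfg, np.random.default_rng(seed))

        # oracle: replay the identical draw sequence, then scalar arithmetic
        rng = np.random.default_rng(seed)
        rng.integers(1)  # the singleton neighbor selection draw
        z0 = rng.random((1, 4))
        z1 = rng.random((1, 4))
        z2 = rng.random((1, 4))
        omega = 0.9 + (0.4 - 0.9) * t / (cfg.steps - 1)
        clamp = [0.5 * (hi - lo) for lo, hi in BOUNDS]
        for d in range(4):
            v = (
                omega * vel[0, d]
                + 1.4 * z0[0, d] * (local[d] - pos[0, d])
                + 1.4 * z1[0, d] * (nbr[d] - pos[0, d])
                + 1.4 * z2[0, d] * (par[d] - pos[0, d])
            )
            v = min(max(v, -clamp[d]), clamp[d])
            x = min(max(pos[0, d] + v, BOUNDS[d][0]), BOUNDS[d][1])
            assert out.velocities[0, d] == pytest.approx(v, abs=1e-12)
            assert out.positions[0, d] == pytest.approx(x, abs=1e-12)

    def test_local_best_never_decreases_and_ties_keep_incumbent(self):
        cfg = EvolutionConfig(bounds=BOUNDS, steps=5)
        # objective constant: every candidate ties the incumbent
        obj = lambda p: 1.0  # noqa: E731
        pos = np.array([[1.0, 1.0, 1.0, 1.0]])
        incumbent = np.array([9.0, 9.0, 9.0, 1.0])
        mem = leaf(pos, best=incumbent, best_score=1.0)
        out = evolve_membrane(mem, obj, 0, cfg, np.random.default_rng(1))
        assert np.array_equal(out.local_best, incumbent)
        assert out.local_best_score == 1.0

    def test_positions_respect_bounds(self):
        cfg = EvolutionConfig(bounds=BOUNDS, steps=3)
        obj = quadratic([0, 0, 0, 1])
        pos = np.array([[9.9, -9.9, 9.9, 1.9]])
        mem = leaf(pos, vel=np.full((1, 4), 50.0), objective=obj)
        out = evolve_membrane(mem, obj, 0, cfg, np.random.default_rng(0))
        lo, hi = cfg.lower(), cfg.upper()
        assert np.all(out.positions >= lo) and np.all(out.positions <= hi)


class TestCommunication:
    def make_triple(self):
        sibs = []
        for i in range(3):
            s = leaf([[float(i)] * 4], best=[float(i)] * 4, best_score=float(i))
            s.id = f"m01{i + 1}"
            sibs.append(s)
        return sibs

    def test_intra_each_receives_other_two(self):
        sibs = intra_communicate(self.make_triple())
        got = sorted(p[0][0] for p in sibs[0].neighbor_bests)
        assert got == [1.0, 2.0]
        for i, s in enumerate(sibs):
            assert len(s.neighbor_bests) == 2
            assert s.local_best[0] == float(i)  # own best untouched

    def test_intra_copies_are_value_equal_but_independent(self):
        orig = self.make_triple()
        sibs = intra_communicate(orig)
        received = sibs[0].neighbor_bests[0][0]
        assert np.array_equal(received, orig[1].local_best)
        received[0] = 123.0
        assert orig[1].local_best[0] == 1.0  # mutation does not reach source

    def test_intra_idempotent_without_evolution(self):
        once = intra_communicate(self.make_triple())
        twice = intra_communicate(once)
        for a, b in zip(once, twice):
            assert np.array_equal(
                np.array([p for p, _ in a.neighbor_bests]),
                np.array([p for p, _ in b.neighbor_bests]),
            )

    def test_inter_pool_and_parent_best_direction(self):
        kids = self.make_triple()
        parent = MembraneState(
            id="m01",
            local_best=np.array([7.0] * 4),
            local_best_score=7.0,
        )
        new_parent, new_kids = inter_communicate(parent, kids)
        assert len(new_parent.pool) == 3
        for kid, orig in zip(new_kids, kids):
            assert np.array_equal(kid.parent_best[0], [7.0] * 4)
            assert np.array_equal(kid.local_best, orig.local_best)

    def test_select_substitute_max_and_tie_semantics(self):
        obj = lambda p: 0.0  # noqa: E731
        parent = MembraneState(
            id="m01", local_best=np.array([0.0] * 4), local_best_score=1.0
        )
        parent.pool = [(np.array([5.0] * 4), 2.0)]
        out = select_substitute(parent, obj)
        assert out.local_best_score == 2.0 and out.local_best[0] == 5.0
        assert out.pool == []

        parent = MembraneState(
            id="m01", local_best=np.array([0.0] * 4), local_best_score=1.0
        )
        parent.pool = [(np.array([5.0] * 4), 1.0), (np.array([6.0] * 4), 0.5)]
        out = select_substitute(parent, obj)
        assert out.local_best[0] == 0.0  # exact tie keeps the incumbent

    def test_promote_global_monotone(self):
        out_mem = MembraneState(
            id="m0", local_best=np.array([1.0] * 4), local_best_score=3.0
        )
        worse = [
            MembraneState(id=f"m0{i}", local_best=np.array([9.0] * 4),
                          local_best_score=1.0)
            for i in range(1, 4)
        ]
        promoted = promote_global(out_mem, worse)
        assert promoted.local_best_score == 3.0
        assert promoted.local_best[0] == 1.0


class TestRun:
    def test_trace_monotone_and_conservation_over_steps(self):
        cfg = EvolutionConfig(
            bounds=BOUNDS, particles_per_membrane=4, steps=20, seed=5
        )
        res = optimize_tps(quadratic([2, -3, 5, 1.2]), cfg)
        scores = [s for _, s in res.trace]
        assert len(scores) == 20
        assert all(a <= b for a, b in zip(scores, scores[1:]))
        assert res.best_score == scores[-1]

    def test_global_best_is_max_over_all_membranes_each_step(self):
        from tpsreg.tps_core import _init_state

        cfg = EvolutionConfig(
            bounds=BOUNDS, particles_per_membrane=3, steps=6, seed=2
        )
        obj = quadratic([1, 1, 1, 1])
        topo = build_topology()
        rng = np.random.default_rng(cfg.seed)
        state = _init_state(topo, obj, cfg, rng)
        for t in range(cfg.steps):
            state = tps_step(state, topo, obj, t, cfg, rng)
            best_everywhere = max(
                state[m].local_best_score
                for m in topo.membrane_ids
                if state[m].local_best is not None
            )
            assert state["m0"].local_best_score == best_everywhere
            for m in topo.membrane_ids:
                if topo.level[m] == 3:
                    assert state[m].n_particles == 3

    def test_quadratic_optimum_found(self):
        cfg = EvolutionConfig(
            bounds=BOUNDS, particles_per_membrane=10, steps=80, seed=0
        )
        center = np.array([2.0, -3.0, 5.0, 1.2])
        res = optimize_tps(quadratic(center), cfg)
        assert np.all(np.abs(res.best_params.to_array() - center) < 1e-2)

    def test_seeded_determinism(self, small_phantom):
        img, _, _ = small_phantom
        from tpsreg.phantoms import make_float

        flt = make_float(img, TransformParams(x=3, y=2, theta=4))
        cfg = EvolutionConfig(
            bounds=((-8, 8), (-8, 8), (-8, 8), (1, 1)),
            particles_per_membrane=3, steps=4, bins=32, seed=11,
        )
        r1 = run_tps(img, flt, cfg)
        r2 = run_tps(img, flt, cfg)
        assert r1 == r2

    def test_constant_reference_returns_zero_without_error(self):
        const = Image2D.from_array(np.full((32, 32), 0.4), normalize=False)
        cfg = EvolutionConfig(
            bounds=((-5, 5), (-5, 5), (-5, 5), (1, 1)),
            particles_per_membrane=2, steps=3, bins=16, seed=0,
        )
        res = run_tps(const, const, cfg)
        assert res.best_score == 0.0

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            EvolutionConfig(bounds=BOUNDS, steps=0)
        with pytest.raises(ValueError):
            EvolutionConfig(bounds=((0, 1),))
        with pytest.raises(ValueError):
            EvolutionConfig(
                bounds=((-1, 1), (-1, 1), (-1, 1), (-0.5, 1.0))
            )
        with pytest.raises(ValueError):
            EvolutionConfig(bounds=BOUNDS, omega_start=0.3, omega_end=0.9)
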