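import numpy as np
import pytest

from vesihybrid.ssa import Species, TetSsa
from vesihybrid.vesicles import VesicleState, VesicleType
from vesihybrid.kinetics import (VesicleSurfaceReaction,
                                 SurfaceReactionChannel, BindingRule,
                                 BindingChannel, UnbindingRule,
                                 UnbindingChannel, ExocytosisRule,
                                 ExocytosisChannel, EndocytosisRule,
                                 EndocytosisChannel, RaftType, RaftState,
                                 RaftDissolution, RaftDissolutionChannel,
                                 RaftGeneration, RaftGenerationChannel,
                                 raft_step, ConfigError)


@pytest.fixture()
def world(coarse_sphere):
    state = VesicleState(coarse_sphere)
    ssa = TetSsa(coarse_sphere, [Species("A"), Species("X"),
                                 Species("glu")])
    vt = VesicleType("sv", 40e-9, D=0.0)
    return state, ssa, vt


class TestSurfaceReactionChannel:
    def test_max_distance_gates_propensity(self, world, rng):
        state, ssa, vt = world
        ves = state.add_vesicle(vt, [0, 0, 0])   # center: ~230 nm from wall
        ves.add_surface_point("S", [0, 0, 1])
        ssa2 = TetSsa(state.mesh, [Species("A")])
        rule = VesicleSurfaceReaction(
            "dock", rate=5.0, surface_reactants={"S": 1},
            membrane_products={"Sd": 1}, patch="surf", max_distance=25e-9)
        ch = SurfaceReactionChannel(rule, state)
        ch.sync(ssa2)
        assert ch.propensity(ssa2) == 0.0
        rule2 = VesicleSurfaceReaction(
            "decay", rate=5.0, surface_reactants={"S": 1},
            lumen_products={"Si": 1})
        ch2 = SurfaceReactionChannel(rule2, state)
        ch2.sync(ssa2)
        assert ch2.propensity(ssa2) == pytest.approx(5.0)

    def test_membrane_terms_require_patch(self):
        with pytest.raises(ConfigError):
            VesicleSurfaceReaction("bad", rate=1.0,
                                   surface_reactants={"S": 1},
                                   membrane_reactants={"M": 1})

    def test_lumen_products_and_dock_delta(self, world, rng):
        state, ssa, vt = world
        ves = state.add_vesicle(vt, [0, 0, 0])
        ves.add_surface_point("S", [1, 0, 0])
        rule = VesicleSurfaceReaction(
            "pump", rate=100.0, surface_reactants={"S": 1},
            surface_products={"S2": 1}, lumen_products={"glu": 3},
            dock_delta=1)
        ch = SurfaceReactionChannel(rule, state)
        ssa.extra_channels.append(ch)
        ch.sync(ssa)
        ssa.advance(0.5, rng)
        assert ves.surface_count("S") == 0
        assert ves.surface_count("S2") == 1
        assert ves.lumen["glu"] == 3
        assert ves.dock_count == 1


class TestBindingUnbinding:
    def _state(self, coarse_sphere):
        state = VesicleState(coarse_sphere)
        vt = VesicleType("sv", 40e-9, D=0.0)
        a = state.add_vesicle(vt, [-25e-9, 0, 0])
        b = state.add_vesicle(vt, [25e-9, 0, 0])
        a.add_surface_point("syA", [1, 0, 0])    # facing points, 10 nm gap
        b.add_surface_point("syB", [-1, 0, 0])
        return state, a, b

    def test_out_of_bounds_pairs_have_zero_propensity(self, coarse_sphere):
        state, a, b = self._state(coarse_sphere)
        rule = BindingRule("bind", "syA", "syB", "L", rate=10.0,
                          l_min=1e-9, l_max=5e-9)     # gap is 10 nm
        ssa = TetSsa(state.mesh, [])
        ch = BindingChannel(rule, state)
        ch.sync(ssa)
        assert ch.propensity(ssa) == 0.0

    def test_bind_then_unbind_restores_counts(self, coarse_sphere, rng):
        state, a, b = self._state(coarse_sphere)
        rule = BindingRule("bind", "syA", "syB", "L", rate=1000.0,
                          l_min=1e-9, l_max=20e-9)
        ssa = TetSsa(state.mesh, [])
        ch = BindingChannel(rule, state)
        ssa.extra_channels.append(ch)
        ch.sync(ssa)
        ssa.advance(0.05, rng)
        assert a.surface_count("syA") == 0 and b.surface_count("syB") == 0
        assert len(a.links) == 1 and a.links[0] is b.links[0]
        un = UnbindingRule("unbind", "L", "syA", "syB", rate=1000.0)
        ssa.extra_channels.append(UnbindingChannel(un, state, [ch]))
        ssa.extra_channels.remove(ch)
        ssa.advance(0.1, rng)
        assert not a.links and not b.links
        assert a.surface_count("syA") == 1 and b.surface_count("syB") == 1


class TestExocytosis:
    def test_full_collapse_conserves_species(self, world, rng):
        state, ssa, vt = world
        ves = state.add_vesicle(vt, [0.2e-6, 0, 0])
        for _ in range(4):
            ves.add_surface_point("X", rng.standard_normal(3))
        ves.lumen["glu"] = 100
        rule = ExocytosisRule("exo", rate=1000.0, patch="surf")
        ch = ExocytosisChannel(rule, state)
        ssa.extra_channels.append(ch)
        ch.sync(ssa)
        ssa.advance(0.05, rng)
        assert not state.vesicles                       # vesicle removed
        xi = ssa.s_index["X"]
        assert ssa.tri_counts[:, xi].sum() == 4         # surface -> membrane
        assert ch.released.get("glu") == 100            # lumen -> ledger

    def test_dependency_gates_rate(self, world, rng):
        state, ssa, vt = world
        ves = state.add_vesicle(vt, [0, 0, 0])
        rule = ExocytosisRule("exo", rate=5.0, patch="surf",
                              dependencies={"snare": 2})
        ch = ExocytosisChannel(rule, state)
        ch.sync(ssa)
        assert ch.propensity(ssa) == 0.0
        ves.add_surface_point("snare", [1, 0, 0])
        ves.add_surface_point("snare", [0, 1, 0])
        ch.sync(ssa)
        assert ch.propensity(ssa) == pytest.approx(5.0)

    def test_anti_dependency_blocks(self, world):
        state, ssa, vt = world
        ves = state.add_vesicle(vt, [0, 0, 0])
        ves.add_surface_point("inhib", [1, 0, 0])
        rule = ExocytosisRule("exo", rate=5.0, patch="surf",
                              anti_dependencies={"inhib": 1})
        ch = ExocytosisChannel(rule, state)
        ch.sync(ssa)
        assert ch.propensity(ssa) == 0.0

    def test_preserve_mode_binomial_release(self, world):
        state, ssa, vt = world
        n0, frac, reps = 1000, 0.64, 200
        released = []
        rule = ExocytosisRule("kr", rate=5.0, patch="surf",
                              mode="preserve", release_fraction=frac)
        rng = np.random.default_rng(11)
        ves = state.add_vesicle(vt, [0, 0, 0])
        ch = ExocytosisChannel(rule, state)
        ch.sync(ssa)
        for _ in range(reps):
            ves.lumen["glu"] = n0
            ch.released.clear()
            ch._eligible = [ves.id]
            ch.execute(ssa, rng)
            released.append(ch.released["glu"])
            assert ves.id in state.vesicles             # vesicle preserved
        mean = np.mean(released)
        se = np.sqrt(n0 * frac * (1 - frac) / reps)
        assert abs(mean - n0 * frac) <= 3 * se
        assert np.std(released, ddof=1) == pytest.approx(
            np.sqrt(n0 * frac * (1 - frac)), rel=0.25)

    def test_full_collapse_empty_lumen(self, world, rng):
        state, ssa, vt = world
        state.add_vesicle(vt, [0.2e-6, 0, 0])
        rule = ExocytosisRule("exo", rate=1000.0, patch="surf")
        ch = ExocytosisChannel(rule, state)
        ssa.extra_channels.append(ch)
        ch.sync(ssa)
        ssa.advance(0.05, rng)
        assert not state.vesicles and not ch.released


class TestEndocytosis:
    def _zone(self, mesh, n_tris=6):
        tris = np.asarray(mesh.patches["surf"].tris)
        z = mesh.tri_barycenter[tris, 2]
        zone = tris[np.argsort(z)[-n_tris:]]
        if "zone" not in mesh.zones:
            mesh.add_zone("zone", "surf", zone)
        return zone

    def test_zone_species_move_to_vesicle_surface(self, world, rng):
        state, ssa, vt = world
        zone = self._zone(state.mesh)
        ssa.tri_counts[zone, ssa.s_index["X"]] = 1
        rule = EndocytosisRule("endo", zone="zone", rate=1e4,
                               vesicle_type="sv", dependencies={"X": 1})
        ch = EndocytosisChannel(rule, state, {"sv": vt})
        ssa.extra_channels.append(ch)
        ssa.advance(0.01, rng)
        assert len(state.vesicles) >= 1
        ves = next(iter(state.vesicles.values()))
        total_on_surface = sum(v.surface_count("X")
                               for v in state.vesicles.values())
        remaining = ssa.tri_counts[zone, ssa.s_index["X"]].sum()
        assert total_on_surface + remaining == len(zone)  # conservation
        for pts in ves.surface.values():
            for p in pts:
                assert np.linalg.norm(p) == pytest.approx(vt.radius,
                                                          rel=1e-6)

    def test_blocked_space_rejects_event(self, world, rng):
        state, ssa, vt = world
        zone = self._zone(state.mesh)
        # occupy the space just inside the zone with an existing vesicle
        mesh = state.mesh
        w = mesh.tri_area[zone]
        centroid = (mesh.tri_barycenter[zone] * w[:, None]).sum(0) / w.sum()
        normal = mesh.tri_normal[zone].mean(axis=0)
        normal /= np.linalg.norm(normal)
        blocker = state.add_vesicle(vt, centroid - normal * vt.radius * 1.02)
        assert blocker is not None
        rule = EndocytosisRule("endo", zone="zone", rate=1e4,
                               vesicle_type="sv")
        ch = EndocytosisChannel(rule, state, {"sv": vt})
        before = ssa.tri_counts.copy()
        ch.execute(ssa, rng)
        assert len(state.vesicles) == 1                 # only the blocker
        np.testing.assert_array_equal(ssa.tri_counts, before)


class TestRafts:
    def test_exclusivity_on_add_and_move(self, coarse_sphere, rng):
        rafts = RaftState(coarse_sphere)
        rt = RaftType("r", radius=30e-9, D=1e-14)
        tris = np.asarray(coarse_sphere.patches["surf"].tris)
        r1 = rafts.add_raft(rt, int(tris[0]))
        assert r1 is not None
        assert rafts.add_raft(rt, r1.anchor_tri) is None
        # immobile raft never moves
        rt0 = RaftType("r0", radius=30e-9, D=0.0)
        far = tris[len(tris) // 2]
        r2 = rafts.add_raft(rt0, int(far))
        anchor = r2.anchor_tri
        raft_step(rafts, 1e-2, rng)
        assert r2.anchor_tri == anchor

    def test_dissolution_disperses_counts(self, coarse_sphere, rng):
        rafts = RaftState(coarse_sphere)
        rt = RaftType("r", radius=30e-9, D=0.0)
        tris = np.asarray(coarse_sphere.patches["surf"].tris)
        raft = rafts.add_raft(rt, int(tris[0]))
        raft.counts["G"] = 7
        ssa = TetSsa(coarse_sphere, [Species("G")])
        rule = RaftDissolution("dis", rate=100.0, below={"G": 100})
        ch = RaftDissolutionChannel(rule, rafts)
        overlap = list(raft.overlap_tris)
        ch.execute(ssa, rng)
        assert not rafts.rafts
        assert ssa.tri_counts[overlap, 0].sum() == 7

    def test_generation_consumes_signature(self, coarse_sphere, rng):
        rafts = RaftState(coarse_sphere)
        rt = RaftType("r", radius=10e-9, D=0.0)
        ssa = TetSsa(coarse_sphere, [Species("G")])
        tris = np.asarray(coarse_sphere.patches["surf"].tris)
        ssa.tri_counts[tris[5], 0] = 2
        rule = RaftGeneration("gen", rate=10.0, raft_type="r",
                              signature={"G": 2})
        ch = RaftGenerationChannel(rule, rafts, {"r": rt}, patch="surf")
        assert ch.propensity(ssa) == pytest.approx(10.0)
        ch.execute(ssa, rng)
        assert len(rafts.rafts) == 1
        raft = next(iter(rafts.rafts.values()))
        assert raft.counts["G"] == 2
        assert ssa.tri_counts[tris[5], 0] == 0
        assert ch.propensity(ssa) == 0.0
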