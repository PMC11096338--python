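import math

import numpy as np
import pytest
from scipy import stats

from vesihybrid.vesicles import (VesicleState, VesicleType, VesiclePath,
                                 SphericalPropagator, brownian_step,
                                 diffuse_all_vesicles, surface_diffuse,
                                 apply_link_constraints, place_vesicles,
                                 path_capture_and_advance, Link)


class TestBrownianStep:
    @pytest.mark.parametrize("D,dt,rms", [
        (0.06e-12, 1e-3, 18.97e-9),      # sqrt(6 D dt)
        (0.06e-12, 1e-4, 6.0e-9),
    ])
    def test_rms_displacement(self, coarse_sphere, D, dt, rms):
        st = VesicleState(coarse_sphere)
        ves = st.add_vesicle(VesicleType("v", 40e-9, D=D), [0, 0, 0])
        rng = np.random.default_rng(0)
        sq = [np.sum((brownian_step(ves, dt, rng) - ves.center) ** 2)
              for _ in range(4000)]
        assert math.sqrt(np.mean(sq)) == pytest.approx(rms, rel=0.05)

    def test_zero_diffusion_stays(self, coarse_sphere):
        st = VesicleState(coarse_sphere)
        ves = st.add_vesicle(VesicleType("v", 40e-9, D=0.0), [0, 0, 0])
        rng = np.random.default_rng(0)
        np.testing.assert_array_equal(brownian_step(ves, 1e-3, rng),
                                      ves.center)


class TestDiffuseAll:
    def test_hard_core_and_coverage_invariants(self, coarse_sphere, rng):
        st = VesicleState(coarse_sphere)
        vt = VesicleType("v", 40e-9, D=0.06e-12)
        place_vesicles(st, vt, 15, rng)
        for _ in range(25):
            st.time += 1e-3
            diffuse_all_vesicles(st, 1e-3, rng)
            centers = np.array([v.center for v in st.vesicles.values()])
            d = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
            np.fill_diagonal(d, 1.0)
            assert d.min() >= 40e-9 * (1 - 1e-9)
            for v in st.vesicles.values():
                assert v.overlap.complete

    def test_immobile_vesicles_do_not_move(self, coarse_sphere, rng):
        st = VesicleState(coarse_sphere)
        vt = VesicleType("v", 40e-9, D=0.06e-12)
        ves = st.add_vesicle(vt, [0, 0, 0], dock=1)
        p0 = ves.center.copy()
        for _ in range(10):
            diffuse_all_vesicles(st, 1e-3, rng)
        np.testing.assert_array_equal(ves.center, p0)


class TestSphericalPropagator:
    def test_small_tau_matches_rayleigh(self):
        # planar limit: theta ~ Rayleigh(sqrt(2 tau))
        for tau in (1e-3, 1e-4):
            mean, std = SphericalPropagator(tau).moments()
            assert mean == pytest.approx(
                math.sqrt(2 * tau) * math.sqrt(math.pi / 2), rel=0.01)

    def test_large_tau_is_uniform_sphere(self):
        mean, std = SphericalPropagator(5.0).moments()
        assert mean == pytest.approx(math.pi / 2, rel=1e-3)
        # uniform on sphere: var(theta) = pi^2/4 - 2
        assert std == pytest.approx(math.sqrt(math.pi ** 2 / 4 - 2),
                                    rel=1e-2)

    def test_sampler_matches_cdf_moments(self):
        prop = SphericalPropagator(0.05)
        mean, std = prop.moments()
        s = prop.sample(np.random.default_rng(0), 100_000)
        assert s.mean() == pytest.approx(mean, abs=4 * std / 316)

    def test_surface_diffuse_keeps_radius_and_zero_d(self, coarse_sphere):
        st = VesicleState(coarse_sphere)
        ves = st.add_vesicle(VesicleType("v", 40e-9), [0, 0, 0])
        for _ in range(5):
            ves.add_surface_point("S", np.random.default_rng(1).normal(size=3))
        before = [p.copy() for p in ves.surface["S"]]
        rng = np.random.default_rng(2)
        surface_diffuse(st, 1e-3, rng, {"S": 0.0})
        for a, b in zip(before, ves.surface["S"]):
            np.testing.assert_array_equal(a, b)      # D = 0: unchanged
        surface_diffuse(st, 1e-3, rng, {"S": 1e-12})
        for p in ves.surface["S"]:
            assert np.linalg.norm(p) == pytest.approx(20e-9, rel=1e-9)


class TestPaths:
    def test_dwelltimes_single_exponential(self):
        path = VesiclePath("p", [[0, 0, 0], [1e-6, 0, 0]],
                           speed=0.5e-6, stepsize=10e-9)
        rng = np.random.default_rng(5)
        draws = np.array([path.sample_dwell(rng) for _ in range(10_000)])
        mean = 10e-9 / 0.5e-6
        ks = stats.kstest(draws, "expon", args=(0, mean))
        assert ks.pvalue > 0.01
        assert draws.mean() == pytest.approx(mean, rel=0.05)

    def test_double_exp_stages_mean_and_shape(self):
        path = VesiclePath("p", [[0, 0, 0], [1e-6, 0, 0]],
                           speed=0.5e-6, stepsize=10e-9,
                           dwell_law=("double_exp", 1.0, 1.0))
        rng = np.random.default_rng(6)
        draws = np.array([path.sample_dwell(rng) for _ in range(20_000)])
        mean = 10e-9 / 0.5e-6
        assert draws.mean() == pytest.approx(mean, rel=0.03)
        # two equal stages: CV = 1/sqrt(2), clearly below exponential
        assert draws.std() / draws.mean() == pytest.approx(
            1 / math.sqrt(2), rel=0.05)

    def test_mixture_with_equal_taus_is_single_exp(self):
        path = VesiclePath("p", [[0, 0, 0], [1e-6, 0, 0]],
                           speed=0.5e-6, stepsize=10e-9,
                           dwell_law=("double_exp_mixture", 0.3, 2.0, 2.0))
        rng = np.random.default_rng(7)
        draws = np.array([path.sample_dwell(rng) for _ in range(10_000)])
        mean = 10e-9 / 0.5e-6
        ks = stats.kstest(draws, "expon", args=(0, mean))
        assert ks.pvalue > 0.01

    def test_stepsize_longer_than_path_rejected(self):
        with pytest.raises(ValueError):
            VesiclePath("p", [[0, 0, 0], [1e-8, 0, 0]],
                        speed=1e-6, stepsize=1e-7)

    def test_capture_advance_release(self, rng):
        from vesihybrid.mesh import make_box_mesh
        mesh = make_box_mesh([0.8e-6, 0.3e-6, 0.3e-6], 120e-9, seed=4)
        st = VesicleState(mesh)
        path = VesiclePath("p", [[0.1e-6, 0.15e-6, 0.15e-6],
                                 [0.6e-6, 0.15e-6, 0.15e-6]],
                           speed=2e-6, stepsize=20e-9)
        st.paths = [path]
        ves = st.add_vesicle(VesicleType("v", 40e-9, D=0.0),
                             [0.1e-6, 0.15e-6, 0.15e-6])
        st.time = 0.0
        captured = released = False
        for _ in range(2000):
            st.time += 1e-3
            path_capture_and_advance(st, 1e-3, rng)
            if ves.path_state is not None:
                captured = True
            elif captured:
                released = True
                break
        assert captured and released
        # vesicle traveled to near the path end
        assert ves.center[0] > 0.5e-6


class TestLinks:
    def _pair(self, coarse_sphere):
        st = VesicleState(coarse_sphere)
        vt = VesicleType("v", 40e-9, D=0.06e-12)
        a = st.add_vesicle(vt, [-30e-9, 0, 0])
        b = st.add_vesicle(vt, [30e-9, 0, 0])
        ra = a.add_surface_point("L", [1, 0, 0])
        rb = b.add_surface_point("L", [-1, 0, 0])
        ln = Link("L", a.id, b.id, ra, rb, l_min=5e-9, l_max=30e-9)
        a.links.append(ln)
        b.links.append(ln)
        a.surface["L"].remove(ra)
        b.surface["L"].remove(rb)
        return st, a, b, ln

    def test_move_within_bounds_accepted(self, coarse_sphere):
        st, a, b, ln = self._pair(coarse_sphere)
        assert apply_link_constraints(st, a.id, a.center + [0, 5e-9, 0])

    def test_stretch_beyond_lmax_rejected(self, coarse_sphere):
        st, a, b, ln = self._pair(coarse_sphere)
        # current link length 20 nm; moving 15 nm away exceeds 30 nm
        assert not apply_link_constraints(st, a.id,
                                          a.center - [15e-9, 0, 0])

    def test_linked_cluster_stays_linked_but_mobile(self, coarse_sphere,
                                                    rng):
        st, a, b, ln = self._pair(coarse_sphere)
        start = a.center.copy()
        moved = 0
        for _ in range(50):
            st.time += 1e-3
            moved += diffuse_all_vesicles(st, 1e-3, rng)
            assert ln.l_min <= ln.length(st) <= ln.l_max
        assert moved > 0
        assert np.linalg.norm(a.center - start) > 0


class TestLinkedCluster:
    def test_cluster_stays_linked_yet_fluid(self, rng):
        """A cluster of mutually linked vesicles plus inert bystanders:
        no link ever leaves its bounds, yet cluster members keep moving
        (liquid-like partial mobility) and inert vesicles stay mobile."""
        from vesihybrid.mesh import make_box_mesh
        mesh = make_box_mesh([0.6e-6] * 3, 110e-9, seed=8)
        st = VesicleState(mesh)
        vt = VesicleType("sv", 40e-9, D=0.06e-12)
        # place a loose grid of cluster members and chain-link neighbors
        members = []
        for i in range(4):
            for j in range(4):
                v = st.add_vesicle(vt, [0.18e-6 + i * 55e-9,
                                        0.18e-6 + j * 55e-9, 0.3e-6])
                assert v is not None
                members.append(v)
        links = []
        for a, b in zip(members[:-1], members[1:]):
            gap = b.center - a.center
            d = np.linalg.norm(gap)
            ra = a.add_surface_point("L", gap)
            rb = b.add_surface_point("L", -gap)
            a.surface["L"].remove(ra)
            b.surface["L"].remove(rb)
            ln = Link("L", a.id, b.id, ra, rb,
                      l_min=1e-9, l_max=(d - 40e-9) * 2.5)
            a.links.append(ln)
            b.links.append(ln)
            links.append(ln)
        inert = [st.add_vesicle(vt, [0.45e-6, 0.15e-6 + k * 60e-9, 0.3e-6])
                 for k in range(5)]
        assert all(v is not None for v in inert)
        start = {v.id: v.center.copy() for v in members + inert}
        for _ in range(40):
            st.time += 1e-3
            diffuse_all_vesicles(st, 1e-3, rng)
            for ln in links:
                assert ln.l_min <= ln.length(st) <= ln.l_max
        member_msd = np.mean([np.sum((st.vesicles[v.id].center
                                      - start[v.id]) ** 2) for v in members])
        inert_msd = np.mean([np.sum((st.vesicles[v.id].center
                                     - start[v.id]) ** 2) for v in inert])
        assert member_msd > 0                       # cluster is not frozen
        assert inert_msd > member_msd               # bystanders move freely


class TestPlacement:
    def test_rsa_reaches_target_occupancy(self, coarse_sphere, rng):
        st = VesicleState(coarse_sphere)
        vt = VesicleType("v", 40e-9)
        n = int(0.10 * coarse_sphere.total_volume / vt.volume)
        place_vesicles(st, vt, n, rng, dock=1)
        occ = st.occupancy_by_tet().sum() / coarse_sphere.total_volume
        assert occ == pytest.approx(0.10, rel=0.05)

    def test_lattice_reaches_dense_occupancy(self, rng):
        from vesihybrid.mesh import make_box_mesh
        mesh = make_box_mesh([0.5e-6] * 3, 100e-9, seed=9)
        st = VesicleState(mesh)
        vt = VesicleType("v", 40e-9)
        n = int(0.4 * mesh.total_volume / vt.volume)
        place_vesicles(st, vt, n, rng, method="lattice", dock=1)
        assert len(st.vesicles) == n
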