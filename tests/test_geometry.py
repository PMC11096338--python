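import math

import numpy as np
import pytest

from vesihybrid import sphere_tet_overlap, walk_to, compute_overlap
from vesihybrid.geometry import (disk_polygon_area, point_in_tet,
                                 sphere_tet_overlap_quadrature,
                                 position_valid, GeometryError)
from vesihybrid.mesh import build_mesh
from vesihybrid.vesicles import VesicleState, VesicleType

BALL = 4.0 / 3.0 * math.pi


def _mc_overlap(rng, center, r, verts, n=40_000):
    """Monte-Carlo oracle: fraction of ball-uniform points inside tet."""
    pts = rng.normal(size=(n, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    pts *= r * rng.uniform(size=(n, 1)) ** (1 / 3)
    pts += center
    a, b, c, d = verts
    T = np.linalg.inv(np.column_stack([b - a, c - a, d - a]))
    lam = (pts - a) @ T.T
    inside = (lam >= 0).all(axis=1) & (lam.sum(axis=1) <= 1)
    vs = BALL * r ** 3
    frac = inside.mean()
    return frac * vs, vs * math.sqrt(max(frac * (1 - frac), 1e-12) / n)


class TestOverlapKernel:
    def test_full_containment_both_ways(self):
        big = np.array([[-10, -10, -10], [10, -10, -10],
                        [0, 10, -10], [0, 0, 10]], float)
        assert sphere_tet_overlap([0, 0, 0], 1.0, big) == \
            pytest.approx(BALL, rel=1e-12)
        small = np.array([[0, 0, 0], [.1, 0, 0], [0, .1, 0], [0, 0, .1]])
        v_tet = abs(np.linalg.det(small[1:] - small[0])) / 6
        assert sphere_tet_overlap([0, 0, 0], 1.0, small) == \
            pytest.approx(v_tet, rel=1e-12)

    def test_half_ball_on_face_plane(self):
        half = np.array([[-100, -100, 0], [100, -100, 0],
                         [0, 100, 0], [0, 0, 100]], float)
        assert sphere_tet_overlap([0, 0, 0], 1.0, half) == \
            pytest.approx(2.0 / 3.0 * math.pi, rel=1e-9)

    def test_disjoint_is_zero(self):
        tet = np.array([[5, 5, 5], [6, 5, 5], [5, 6, 5], [5, 5, 6]], float)
        assert sphere_tet_overlap([0, 0, 0], 1.0, tet) == 0.0

    def test_degenerate_tet_raises(self):
        flat = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float)
        with pytest.raises(GeometryError):
            sphere_tet_overlap([0, 0, 0.1], 1.0, flat)

    def test_monte_carlo_oracle_random_configs(self):
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(200):
            verts = rng.normal(size=(4, 3))
            if abs(np.linalg.det(verts[1:] - verts[0])) < 0.05:
                continue
            center = rng.normal(scale=0.8, size=3)
            r = rng.uniform(0.3, 1.5)
            v = sphere_tet_overlap(center, r, verts)
            mc, se = _mc_overlap(rng, center, r, verts)
            assert abs(v - mc) <= max(3 * se, 1e-3 * BALL * r ** 3)
            checked += 1
            if checked >= 100:
                break
        assert checked >= 100

    def test_quadrature_agrees_with_exact(self):
        rng = np.random.default_rng(7)
        vs = 0
        for _ in range(60):
            verts = rng.normal(size=(4, 3))
            if abs(np.linalg.det(verts[1:] - verts[0])) < 0.05:
                continue
            center = rng.normal(scale=0.8, size=3)
            r = rng.uniform(0.3, 1.5)
            v = sphere_tet_overlap(center, r, verts)
            q = sphere_tet_overlap_quadrature(center, r, verts)
            assert abs(v - q) <= 1e-4 * BALL * r ** 3

    def test_additivity_full_coverage(self, coarse_sphere, fine_sphere):
        """Sphere fully inside the mesh: per-tet overlaps sum to its
        volume at every resolution."""
        for mesh in (coarse_sphere, fine_sphere):
            k = mesh.containing_tet([0, 0, 0])
            omap = compute_overlap(mesh, [0, 0, 0], 20e-9, [k])
            assert omap.coverage_fraction == pytest.approx(1.0, abs=1e-6)

    def test_overlap_entry_bounds(self, fine_sphere):
        k = fine_sphere.containing_tet([0, 0, 0])
        omap = compute_overlap(fine_sphere, [0, 0, 0], 20e-9, [k])
        v_sphere = BALL * (20e-9) ** 3
        for t, v in omap.entries.items():
            assert 0 < v <= min(fine_sphere.tet_volume[t], v_sphere) * (1 + 1e-9)


class TestDiskPolygonArea:
    def test_polygon_inside_disk(self):
        square = [(-.1, -.1), (.1, -.1), (.1, .1), (-.1, .1)]
        assert disk_polygon_area(square, 1.0) == pytest.approx(0.04)

    def test_disk_inside_polygon(self):
        square = [(-5, -5), (5, -5), (5, 5), (-5, 5)]
        assert disk_polygon_area(square, 1.0) == pytest.approx(math.pi,
                                                               rel=1e-12)

    def test_half_disk(self):
        rect = [(0, -5), (5, -5), (5, 5), (0, 5)]
        assert disk_polygon_area(rect, 1.0) == pytest.approx(math.pi / 2,
                                                             rel=1e-9)


class TestWalkTo:
    def test_dest_in_start_tet(self, coarse_sphere):
        m = coarse_sphere
        k = m.containing_tet([0, 0, 0])
        assert walk_to(m, k, [0, 0, 0], m.tet_barycenter[k]) == k

    def test_dest_in_neighbor(self, coarse_sphere):
        m = coarse_sphere
        k = m.containing_tet([0, 0, 0])
        nb = int(m.tet_neighbors[k][m.tet_neighbors[k] >= 0][0])
        got = walk_to(m, k, m.tet_barycenter[k], m.tet_barycenter[nb])
        assert got == nb

    def test_far_hop_found(self, coarse_sphere):
        m = coarse_sphere
        k = m.containing_tet([0, 0, 0])
        dest = np.array([0.15e-6, 0.1e-6, -0.05e-6])
        got = walk_to(m, k, m.tet_barycenter[k], dest)
        assert got >= 0
        assert point_in_tet(m.vertices[m.tets[got]], dest, tol=1e-9)

    def test_no_jump_across_gap(self):
        """Two tet clusters separated by a void: the walk must return
        not-found rather than teleport (oracle: graph reachability)."""
        reg = np.array([[0, 0, 0], [1, 0, 0], [0.5, math.sqrt(3) / 2, 0],
                        [0.5, math.sqrt(3) / 6, math.sqrt(6) / 3]]) * 1e-7
        far = reg + np.array([3e-7, 0, 0])
        verts = np.vstack([reg, far])
        mesh = build_mesh(verts, np.array([[0, 1, 2, 3], [4, 5, 6, 7]]))
        dest = far.mean(axis=0)
        got = walk_to(mesh, 0, reg.mean(axis=0), dest)
        assert got == -1

    def test_result_always_contains_dest(self, fine_sphere):
        m = fine_sphere
        rng = np.random.default_rng(3)
        k0 = m.containing_tet([0, 0, 0])
        for _ in range(20):
            dest = rng.uniform(-0.12e-6, 0.12e-6, 3)
            got = walk_to(m, k0, m.tet_barycenter[k0], dest)
            if got >= 0:
                assert point_in_tet(m.vertices[m.tets[got]], dest, tol=1e-9)


class TestPositionValid:
    @pytest.fixture()
    def state(self, coarse_sphere):
        st = VesicleState(coarse_sphere)
        vt = VesicleType("sv", 40e-9, D=0.06e-12)
        a = st.add_vesicle(vt, [0, 0, 0])
        assert a is not None
        return st, vt, a

    def test_hard_core_exclusion(self, state):
        st, vt, a = state
        b = st.add_vesicle(vt, [41e-9, 0, 0])
        assert b is not None
        ok, _ = position_valid(st, b.id, np.array([39e-9, 0.0, 0.0]))
        assert not ok
        ok, omap = position_valid(st, b.id, np.array([45e-9, 0.0, 0.0]))
        assert ok and omap.complete

    def test_protrusion_past_surface_invalid(self, state):
        st, vt, a = state
        # center 19 nm inside the outermost vertex with 20 nm radius:
        # the sphere pokes through the faceted surface near that vertex
        m = st.mesh
        vmax = m.vertices[np.argmax(np.linalg.norm(m.vertices, axis=1))]
        R = np.linalg.norm(vmax)
        cand = vmax * (1.0 - 19e-9 / R)
        ok, omap = position_valid(st, a.id, cand)
        assert not ok
        assert omap.coverage_fraction < 1.0 - 1e-6

    def test_add_vesicle_rejects_contact(self, state):
        st, vt, a = state
        assert st.add_vesicle(vt, [39e-9, 0, 0]) is None
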