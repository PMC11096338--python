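import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vesihybrid.diagnostics import (step_fraction_over, suggest_vesicle_dt,
                                    check_vesicle_dt, check_mesh_size,
                                    vesicle_dt_threshold,
                                    check_vesicle_dt_threshold,
                                    static_model_checks)
from vesihybrid.mesh import build_mesh
from vesihybrid.ssa import Reaction
from vesihybrid.vesicles import VesicleType
from tests.test_mesh import REG_TET


class TestStepFractionOver:
    def test_one_rms_distance(self):
        # d = sqrt(6 D dt): fraction = 1 - F(3; 3) ~ 0.3916
        D, dt = 0.06e-12, 1e-3
        d = math.sqrt(6 * D * dt)
        assert step_fraction_over(d, D, dt) == pytest.approx(0.3916, abs=1e-4)

    def test_limits(self):
        assert step_fraction_over(0.0, 1e-12, 1e-3) == 1.0
        assert step_fraction_over(1.0, 1e-12, 1e-3) == pytest.approx(0.0)

    def test_matches_empirical_step_lengths(self):
        D, dt = 0.06e-12, 1e-3
        rng = np.random.default_rng(0)
        n = 200_000
        steps = np.linalg.norm(
            rng.standard_normal((n, 3)) * math.sqrt(2 * D * dt), axis=1)
        for d in (10e-9, 19e-9, 30e-9):
            frac = step_fraction_over(d, D, dt)
            emp = (steps > d).mean()
            se = math.sqrt(frac * (1 - frac) / n)
            assert abs(emp - frac) <= 3 * se

    @given(st.floats(1e-9, 1e-6), st.floats(1e-15, 1e-11),
           st.floats(1e-5, 1e-1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_d_and_dt(self, d, D, dt):
        f = step_fraction_over(d, D, dt)
        assert step_fraction_over(d * 1.1, D, dt) <= f
        assert step_fraction_over(d, D, dt * 1.2) >= f

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            step_fraction_over(-1e-9, 1e-12, 1e-3)


class TestCheckVesicleDt:
    def test_synaptic_vesicle_defaults_no_warning(self):
        # 40 nm vesicles at 0.06 um^2/s, dt = 1 ms: fraction over 80 nm
        # is ~1.6e-11, far below the 5% trigger
        vts = [VesicleType("a", 40e-9, 0.06e-12),
               VesicleType("b", 40e-9, 0.06e-12)]
        assert check_vesicle_dt(vts, 1e-3) == []
        assert step_fraction_over(80e-9, 0.06e-12, 1e-3) < 1e-9

    def test_rms_two_diameters_warns_with_suggestion(self):
        # dt such that RMS step = 2 x (own + smallest other) / 2
        D = 0.06e-12
        d_crit = 80e-9
        dt = (2 * d_crit) ** 2 / (6 * D)      # RMS = 2 d_crit
        vts = [VesicleType("a", 40e-9, D), VesicleType("b", 40e-9, D)]
        frac = step_fraction_over(d_crit, D, dt)
        assert frac > 0.5                      # far above the trigger
        warns = check_vesicle_dt(vts, dt)
        assert len(warns) == 2
        assert warns[0].code == "vesicle-step-too-long"

    def test_suggested_dt_satisfies_limit(self):
        D, d = 0.06e-12, 80e-9
        dt_ok = suggest_vesicle_dt(d, D)
        assert step_fraction_over(d, D, dt_ok) <= 0.05 + 1e-9

    def test_zero_diffusion_no_warning(self):
        assert check_vesicle_dt([VesicleType("a", 40e-9, 0.0)], 10.0) == []


class TestCheckMeshSize:
    def _mesh_of_sizes(self, sizes):
        verts, tets = [], []
        for i, s in enumerate(sizes):
            verts.append(REG_TET * s + np.array([i * 1e-5, 0, 0]))
            tets.append(np.arange(4) + 4 * i)
        return build_mesh(np.vstack(verts), np.array(tets))

    def test_healthy_mesh_no_warning(self):
        mesh = self._mesh_of_sizes([50e-9] * 10)
        assert check_mesh_size(mesh) == []

    def test_scaling_error_caught(self):
        # a mesh accidentally interpreted 1000x too small
        mesh = self._mesh_of_sizes([50e-12] * 10)
        warns = check_mesh_size(mesh)
        assert len(warns) == 1
        assert warns[0].code == "mesh-tets-too-small"

    def test_exactly_ten_percent_is_not_flagged(self):
        mesh = self._mesh_of_sizes([10e-9] + [50e-9] * 9)
        assert check_mesh_size(mesh) == []     # strict > 10%
        mesh2 = self._mesh_of_sizes([10e-9] * 2 + [50e-9] * 8)
        assert len(check_mesh_size(mesh2)) == 1


class TestVesicleDtThreshold:
    def test_formula_value(self):
        # r_tet = 20 nm, D = 0.06 um^2/s: dt_theta = r^2/(15 D) ~ 4.44e-4
        mesh = build_mesh(REG_TET, np.array([[0, 1, 2, 3]]))
        # scale so that the mean tet volume equals a 20 nm-radius sphere
        r_tet = 20e-9
        target_v = 4 / 3 * math.pi * r_tet ** 3
        scale = (target_v / mesh.tet_volume[0]) ** (1 / 3)
        mesh2 = build_mesh(REG_TET * scale, np.array([[0, 1, 2, 3]]))
        got = vesicle_dt_threshold(mesh2, 0.06e-12)
        assert got == pytest.approx((20e-9) ** 2 / (15 * 0.06e-12),
                                    rel=1e-6)
        assert got == pytest.approx(4.44e-4, rel=1e-2)

    def test_doubling_d_halves_threshold(self, coarse_sphere):
        a = vesicle_dt_threshold(coarse_sphere, 1e-13)
        b = vesicle_dt_threshold(coarse_sphere, 2e-13)
        assert b == pytest.approx(a / 2)

    def test_warns_above_threshold(self, coarse_sphere):
        vt = VesicleType("a", 40e-9, 0.06e-12)
        dt_theta = vesicle_dt_threshold(coarse_sphere, vt.D)
        assert check_vesicle_dt_threshold(coarse_sphere, [vt],
                                          dt_theta * 0.5) == []
        warns = check_vesicle_dt_threshold(coarse_sphere, [vt],
                                           dt_theta * 2)
        assert warns and warns[0].code == "vesicle-dt-above-threshold"


class TestStaticChecks:
    def test_produce_only_species_flagged(self):
        rx = [Reaction("r1", 1.0, reactants={"A": 1}, products={"C": 1})]
        warns = static_model_checks(reactions=rx)
        assert any(w.code == "produce-only-species" and "'C'" in w.message
                   for w in warns)

    def test_raft_larger_than_mesh(self, coarse_sphere):
        warns = static_model_checks(mesh=coarse_sphere,
                                    raft_radii=[1e-6])
        assert any(w.code == "raft-larger-than-mesh" for w in warns)
        assert static_model_checks(mesh=coarse_sphere,
                                   raft_radii=[50e-9]) == []

    def test_surface_diffusion_randomizing_position(self, coarse_sphere):
        vt = VesicleType("a", 40e-9, 0.0)
        # RMS angular step sqrt(2 D dt)/r > pi
        D_hot = (math.pi * vt.radius) ** 2 / (2 * 1e-3) * 1.1
        warns = static_model_checks(vesicle_types=[vt],
                                    surface_D={"S": D_hot}, dt=1e-3)
        assert any(w.code == "surface-D-too-high" for w in warns)
        assert static_model_checks(vesicle_types=[vt],
                                   surface_D={"S": D_hot / 4},
                                   dt=1e-3) == []

    def test_rate_outlier_three_decades(self):
        rx = [Reaction(f"r{i}", 1.0, reactants={"A": 1}) for i in range(4)]
        rx.append(Reaction("hot", 1e5, reactants={"B": 1}))
        warns = static_model_checks(reactions=rx)
        assert any(w.code == "rate-outlier" and "hot" in w.message
                   for w in warns)
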