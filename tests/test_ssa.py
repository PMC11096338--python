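import math

import numpy as np
import pytest

from vesihybrid.ssa import (AVOGADRO, Species, Reaction, TetSsa,
                            corrected_diffusion_rate,
                            corrected_reaction_propensity,
                            second_order_rate, diffusion_occupancy,
                            RATE_CAP_FRACTION)
from vesihybrid.mesh import make_box_mesh


class TestCorrectedDiffusionRate:
    def test_zero_occupancy_is_classic_rate(self):
        d = corrected_diffusion_rate(1e-12, 1e-14, 1e-21, 1e-7)
        assert d == pytest.approx(1e-12 * 1e-14 / (1e-21 * 1e-7))

    def test_halved_volume_doubles_rate(self):
        d0 = corrected_diffusion_rate(1e-12, 1e-14, 1e-21, 1e-7)
        d1 = corrected_diffusion_rate(1e-12, 1e-14, 0.5e-21, 1e-7)
        assert d1 == pytest.approx(2 * d0)

    def test_vanishing_volume_capped(self):
        v_full = 1e-21
        capped = corrected_diffusion_rate(1e-12, 1e-14, 0.0, 1e-7,
                                          V_full=v_full)
        at_floor = corrected_diffusion_rate(
            1e-12, 1e-14, RATE_CAP_FRACTION * v_full, 1e-7)
        assert capped == pytest.approx(at_floor)
        assert math.isfinite(capped)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            corrected_diffusion_rate(-1e-12, 1e-14, 1e-21, 1e-7)
        with pytest.raises(ValueError):
            corrected_diffusion_rate(1e-12, 1e-14, -1e-21, 1e-7)


class TestCorrectedReactionPropensity:
    def test_second_order_femtoliter_example(self):
        # K = 1e6 / M / s in V* = 1 fL with one molecule of each reactant
        r = Reaction("ab", 1e6, reactants={"A": 1, "B": 1})
        p = corrected_reaction_propensity(r, {"A": 1, "B": 1}, 1e-18)
        assert p == pytest.approx(1e6 / (AVOGADRO * 1e-15), rel=1e-12)
        assert p == pytest.approx(1.661e-3, rel=1e-3)

    def test_halved_volume_doubles_propensity(self):
        r = Reaction("ab", 1e6, reactants={"A": 1, "B": 1})
        p1 = corrected_reaction_propensity(r, {"A": 3, "B": 2}, 1e-18)
        p2 = corrected_reaction_propensity(r, {"A": 3, "B": 2}, 0.5e-18)
        assert p2 == pytest.approx(2 * p1)

    def test_unimolecular_unaffected_by_volume(self):
        r = Reaction("a", 5.0, reactants={"A": 1})
        for v in (1e-18, 1e-21, 0.0):
            assert corrected_reaction_propensity(r, {"A": 7}, v) == \
                pytest.approx(35.0)

    def test_identical_pair_counting(self):
        r = Reaction("aa", 1e6, reactants={"A": 2})
        p = corrected_reaction_propensity(r, {"A": 5}, 1e-18)
        c = second_order_rate(1e6, 1e-18)
        assert p == pytest.approx(c * 10)

    def test_zero_volume_zero_propensity(self):
        r = Reaction("ab", 1e6, reactants={"A": 1, "B": 1})
        assert corrected_reaction_propensity(r, {"A": 1, "B": 1}, 0.0) == 0.0

    def test_order_above_two_rejected(self):
        with pytest.raises(ValueError):
            Reaction("bad", 1.0, reactants={"A": 2, "B": 1})


class TestAdvance:
    def test_pure_death_mean(self, small_box, rng):
        n0, k, t = 1000, 5.0, 0.2
        ssa = TetSsa(small_box, [Species("A"), Species("B")],
                     [Reaction("d", k, reactants={"A": 1},
                               products={"B": 1}, compartment="comp")])
        ssa.distribute("A", n0, rng, "comp")
        ssa.advance(t, rng)
        p = math.exp(-k * t)
        se = math.sqrt(n0 * p * (1 - p))
        assert abs(ssa.total("A") - n0 * p) <= 3 * se
        assert ssa.total("A") + ssa.total("B") == n0      # mass conserved

    def test_empty_system_advances_time(self, small_box, rng):
        ssa = TetSsa(small_box, [Species("A", D=1e-12)])
        ssa.advance(1.0, rng)
        assert ssa.time == 1.0

    def test_time_cannot_go_backward(self, small_box, rng):
        ssa = TetSsa(small_box, [])
        ssa.advance(0.5, rng)
        with pytest.raises(ValueError):
            ssa.advance(0.4, rng)

    def test_diffusion_equilibrates_to_volume(self, rng):
        mesh = make_box_mesh([2e-7, 1e-7, 1e-7], 7e-8, seed=1)
        ssa = TetSsa(mesh, [Species("X", D=1e-12)])
        ssa.counts[0, 0] = 3000
        ssa.advance(0.01, rng)
        p = ssa.counts[:, 0] / 3000
        pv = mesh.tet_volume / mesh.total_volume
        # multinomial-scale agreement per tet
        se = np.sqrt(pv * (1 - pv) / 3000)
        assert (np.abs(p - pv) < 4 * se + 0.01).all()

    def test_blocked_destination_never_entered(self, rng):
        mesh = make_box_mesh([2e-7, 1e-7, 1e-7], 7e-8, seed=1)
        ssa = TetSsa(mesh, [Species("X", D=1e-12)])
        occ = np.zeros(mesh.n_tets)
        occ[0] = mesh.tet_volume[0]          # tet 0 fully overlapped
        ssa.set_occupancy(occ)
        ssa.counts[1, 0] = 500
        ssa.advance(0.005, rng)
        assert ssa.counts[0, 0] == 0

    def test_second_order_well_mixed_rate_law(self, rng):
        """A + B -> C in a meshed volume with fast diffusion follows the
        integrated second-order law."""
        mesh = make_box_mesh([1.5e-7] * 3, 8e-8, seed=2)
        V = mesh.total_volume
        K = 1e7
        n0 = 60
        c = K / (AVOGADRO * V * 1e3)
        reps = 60
        t_end = 0.3 / (c * n0)
        left = []
        for rep in range(reps):
            ssa = TetSsa(mesh, [Species("A", D=1e-11), Species("B", D=1e-11),
                                Species("C")],
                         [Reaction("ab", K, reactants={"A": 1, "B": 1},
                                   products={"C": 1}, compartment="comp")])
            ssa.distribute("A", n0, rng, "comp")
            ssa.distribute("B", n0, rng, "comp")
            ssa.advance(t_end, rng)
            left.append(ssa.total("A"))
        mean = np.mean(left)
        expect = 1.0 / (1.0 / n0 + c * t_end)
        se = np.std(left, ddof=1) / math.sqrt(reps)
        assert abs(mean - expect) <= 3.5 * se


class TestDiffusionOccupancy:
    def test_matches_event_engine(self, rng):
        """The vectorized pure-diffusion sampler and the event-loop SSA
        agree on the stationary per-tet occupancy."""
        mesh = make_box_mesh([2e-7, 1e-7, 1e-7], 7e-8, seed=1)
        v_star = mesh.tet_volume.copy()
        v_star[0] *= 0.5                        # partial occupancy in tet 0
        p_fast = diffusion_occupancy(mesh, v_star, 1e-12, 4000, rng,
                                     relax_rounds=300, sample_rounds=3000)
        ssa = TetSsa(mesh, [Species("X", D=1e-12)])
        ssa.set_occupancy(mesh.tet_volume - v_star)
        ssa.distribute("X", 4000, rng, "comp")
        # time-average occupancy over snapshots
        acc = np.zeros(mesh.n_tets)
        n_snap = 60
        for i in range(n_snap):
            ssa.advance(ssa.time + 2e-4, rng)
            acc += ssa.counts[:, 0]
        p_slow = acc / acc.sum()
        p_expect = v_star / v_star.sum()
        assert np.abs(p_fast - p_expect).max() < 0.02
        assert np.abs(p_slow - p_expect).max() < 0.02
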