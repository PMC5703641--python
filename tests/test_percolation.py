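"""Flory-Stockmayer analytics and the random-network calibration."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

import latticegel as lg
from latticegel.percolation import PhiCSample, lattice_kd


class TestSolveBinding:
    def test_infinite_affinity_limit(self):
        eq = lg.solve_binding(1.0, 1.0, 1e-12)
        assert eq.ab == pytest.approx(1.0, rel=1e-5)
        assert eq.x_a == pytest.approx(1.0, rel=1e-5)

    def test_weak_binding_limit(self):
        a, b, kd = 1e-4, 2e-4, 10.0
        eq = lg.solve_binding(a, b, kd)
        assert eq.ab == pytest.approx(a * b / kd, rel=1e-3)

    def test_mass_action_residual_on_random_inputs(self, rng):
        """Substituting [ab] back into the K_d quotient recovers K_d."""
        for _ in range(1000):
            a, b = rng.uniform(1e-6, 10.0, size=2)
            kd = rng.uniform(1e-6, 10.0)
            eq = lg.solve_binding(a, b, kd)
            assert 0 <= eq.ab <= min(a, b) + 1e-12
            assert abs(eq.residual()) <= 1e-10 * kd

    def test_closed_form_matches_numeric_quadratic(self, rng):
        for _ in range(1000):
            a, b = rng.uniform(1e-3, 5.0, size=2)
            kd = rng.uniform(1e-3, 5.0)
            eq = lg.solve_binding(a, b, kd)
            roots = np.roots([1.0, -(a + b + kd), a * b])
            physical = min(roots)
            assert eq.ab == pytest.approx(float(physical), rel=1e-10)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            lg.solve_binding(-1.0, 1.0, 1.0)


class TestFsEpsilon:
    @pytest.mark.parametrize(
        "va,vb,xa,xb,expected",
        [(5, 5, 0.25, 0.25, 1.0), (3, 3, 0.5, 0.5, 1.0), (1, 5, 1.0, 1.0, 0.0)],
    )
    def test_known_values(self, va, vb, xa, xb, expected):
        assert lg.fs_epsilon(va, vb, xa, xb) == pytest.approx(expected)


class TestFsGelPoint:
    def test_symmetric_5_5_closed_form(self):
        """lambda = 16: x_c = 0.25, [a]_c = K_d x_c/(1-x_c)^2 = (4/9) K_d."""
        assert lg.fs_gel_point(5, 5, 1.0) == pytest.approx(4 / 9, rel=1e-12)
        assert lg.fs_gel_point(5, 5, 0.3) == pytest.approx(0.3 * 4 / 9, rel=1e-12)

    def test_epsilon_equals_one_at_gel_point(self, rng):
        """Self-consistency to 1e-8 for random valences and affinities."""
        for _ in range(50):
            va = int(rng.integers(2, 9))
            vb = int(rng.integers(2, 9))
            if (va - 1) * (vb - 1) <= 1:
                continue
            kd = float(rng.uniform(1e-4, 2.0))
            ac = lg.fs_gel_point(va, vb, kd)
            eq = lg.solve_binding(ac, ac, kd)
            assert lg.fs_epsilon(va, vb, eq.x_a, eq.x_b) == pytest.approx(1.0, abs=1e-8)

    def test_equal_mode_matches_numeric_root_find(self, rng):
        """Closed form vs direct root of epsilon([a]) - 1 = 0."""
        for va, vb, kd in [(5, 5, 1.0), (3, 7, 0.25), (7, 7, 0.01), (2, 4, 2.0)]:
            ac = lg.fs_gel_point(va, vb, kd)

            def eps_on_diagonal(a):
                eq = lg.solve_binding(a, a, kd)
                return lg.fs_epsilon(va, vb, eq.x_a, eq.x_b) - 1.0

            ac_num = brentq(eps_on_diagonal, 1e-12, 100 * (kd + 1), xtol=1e-14)
            assert ac == pytest.approx(ac_num, rel=1e-8)

    def test_fixed_b_mode_consistent_with_equal_mode(self):
        """The fixed-[b] mode evaluated at [b] = [a]_c returns the same point."""
        kd = 0.5
        ac = lg.fs_gel_point(5, 5, kd)
        ac_fixed = lg.fs_gel_point(5, 5, kd, b_total=ac)
        assert ac_fixed == pytest.approx(ac, rel=1e-8)

    def test_monovalent_never_gels(self):
        assert lg.fs_gel_point(1, 5, 1.0) is None
        assert lg.fs_gel_point(2, 2, 1.0) is None

    def test_infinite_valence_limit(self):
        assert lg.fs_gel_point(100, 100, 1.0) < lg.fs_gel_point(5, 5, 1.0)
        assert lg.fs_gel_point(1000, 1000, 1.0) < 1e-2


class TestLatticeKd:
    def test_dilute_limit(self):
        assert lattice_kd(-2.0) == pytest.approx(math.exp(-2.0) / 6.0, rel=1e-12)

    def test_finite_box_matches_full_enumeration(self, tiny_pair):
        """The reduced two-particle form against the exhaustive oracle."""
        res = lg.exact_enumeration(tiny_pair)
        p = res.p_bound
        omega = 8
        kd_enum = (1 - p) ** 2 / (omega * p)
        assert lattice_kd(-2.0, L=2) == pytest.approx(kd_enum, rel=1e-10)

    def test_finite_box_converges_to_dilute_limit(self):
        """Finite-box K_d approaches e^u/6 with an O(1/Omega) correction."""
        k6 = lattice_kd(-2.0, L=6)
        k12 = lattice_kd(-2.0, L=12)
        k24 = lattice_kd(-2.0, L=24)
        k_inf = lattice_kd(-2.0)
        assert abs(k24 - k_inf) < abs(k12 - k_inf) < abs(k6 - k_inf)
        assert k24 == pytest.approx(k_inf, rel=0.01)


class TestRandomNetwork:
    def test_no_bonds_gives_isolated_molecules(self):
        s = lg.random_network_phi_c(5, 5, 2400, 0.0, seed=0, replicates=3)
        assert s.mean == pytest.approx(1 / 480)

    def test_full_binding_connects_nearly_everything(self):
        s = lg.random_network_phi_c(5, 5, 2400, 1.0, seed=0, replicates=5)
        assert s.mean > 0.95

    def test_subcritical_vs_supercritical_scaling(self):
        """phi_c stays O(1/M) below the FS threshold, O(1) above."""
        sub = lg.random_network_phi_c(5, 5, 2400, 0.15, seed=1, replicates=10)
        sup = lg.random_network_phi_c(5, 5, 2400, 0.40, seed=1, replicates=10)
        assert sub.mean < 0.06
        assert sup.mean > 0.6

    def test_monotone_in_bound_fraction(self):
        rng = np.random.default_rng(3)
        means = [
            lg.random_network_phi_c(5, 5, 2400, x, seed=rng, replicates=30).mean
            for x in (0.1, 0.2, 0.3, 0.4, 0.6)
        ]
        diffs = np.diff(means)
        assert np.all(diffs > -0.02)  # monotone within noise

    def test_infeasible_stoichiometry(self):
        with pytest.raises(ValueError):
            lg.random_network_phi_c(5, 5, 4, 0.5)


class TestPhiCCCalibration:
    def test_phi_cc_near_017_for_all_valences(self):
        """Calibrated phi_cc ~= 0.17 irrespective of valence."""
        est = lg.estimate_phi_cc((3, 5, 7), 2400, replicates=30, seed=0)
        for v, phi in est.per_valence.items():
            assert phi == pytest.approx(0.17, abs=0.04), f"V={v}"
        # valence independence: spread well below the absolute level
        spread = max(est.per_valence.values()) - min(est.per_valence.values())
        assert spread < 0.04

    def test_finite_size_scaling_direction(self):
        """phi_cc is a finite-size quantity: at the critical point the
        largest-cluster fraction shrinks slowly as the network grows, so the
        calibration is meaningful only at the simulation's own domain count
        (which is why the node count is matched to the lattice runs)."""
        a = lg.estimate_phi_cc((5,), 2400, replicates=40, seed=1).mean
        b = lg.estimate_phi_cc((5,), 4800, replicates=40, seed=2).mean
        assert b < a
        assert 0.06 < b < a < 0.22

    def test_grid_must_bracket_critical_x(self):
        with pytest.raises(ValueError):
            lg.estimate_phi_cc((5,), 2400, 5, 0, x_grid=np.array([0.5, 0.6]))


class TestGelPointFromSweep:
    def test_first_crossing(self):
        sweep = [(1e-3, 0.01), (2e-3, 0.05), (3e-3, 0.30), (4e-3, 0.80)]
        assert lg.gel_point_from_sweep(sweep) == pytest.approx(3e-3)

    def test_no_crossing_sentinel(self):
        assert lg.gel_point_from_sweep([(1e-3, 0.05), (2e-3, 0.10)]) is None

    def test_unsorted_sweep_rejected(self):
        with pytest.raises(ValueError):
            lg.gel_point_from_sweep([(2e-3, 0.1), (1e-3, 0.2)])

    def test_synthetic_sigmoid_recovered_within_grid_step(self):
        concs = np.linspace(1e-3, 9e-3, 17)
        mid = 5e-3
        phis = 1 / (1 + np.exp(-(concs - mid) / 4e-4))
        cg = lg.gel_point_from_sweep(list(zip(concs, phis)), phi_cc=0.5)
        assert abs(cg - mid) <= (concs[1] - concs[0]) + 1e-12


class TestCStar:
    def test_equal_gel_points_zero_cooperativity(self):
        res = lg.c_star(0.01, 0.01)
        assert res.c_star == pytest.approx(1.0)
        assert res.label == "zero"

    def test_labels(self):
        assert lg.c_star(0.005, 0.01).label == "positive"
        assert lg.c_star(0.05, 0.01).label == "negative"

    def test_sentinels_propagate(self):
        assert lg.c_star(None, 0.01).label == "undefined"
        assert lg.c_star(0.01, None).c_star is None
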