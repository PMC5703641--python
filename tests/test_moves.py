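"""Move kernel correctness: weights, reversibility, detailed balance."""

import math

import numpy as np
import pytest

import latticegel as lg
from latticegel.moves import MOVE_TYPES, MoveEngine, accept_move, run_mc


class TestAcceptMove:
    def test_downhill_always_accepted(self, rng):
        assert all(accept_move(-1.0, 1.0, rng) for _ in range(100))

    def test_flat_move_with_half_weight(self, rng):
        """dE = 0, w = 0.5 -> acceptance probability one half."""
        hits = sum(accept_move(0.0, 0.5, rng) for _ in range(40000))
        assert hits / 40000 == pytest.approx(0.5, abs=0.01)

    def test_uphill_probability_matches_boltzmann(self, rng):
        """dE = 2, w = 1 -> acceptance frequency e^-2 over 1e5 trials."""
        n = 100_000
        hits = sum(accept_move(2.0, 1.0, rng) for _ in range(n))
        p = math.exp(-2.0)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 4 * se

    def test_nonpositive_weight_rejected(self, rng):
        with pytest.raises(ValueError):
            accept_move(0.0, 0.0, rng)
        with pytest.raises(ValueError):
            accept_move(float("nan"), 1.0, rng)


class TestProposals:
    def test_binding_flip_on_adjacent_pair_gives_u_sp(self, rng):
        state = lg.generate_fixture("tiny-enumerable", 0)
        state.pos[0] = (0, 0, 0)
        state.pos[1] = (1, 0, 0)
        state.occ[:] = -1
        for b in range(2):
            state.occ[state.site_of(b)] = b
        state.energy = 0.0
        eng = MoveEngine(state, rng)
        # keep proposing until the flip turns the bond on
        for _ in range(200):
            prop = eng.propose_move("binding_flip")
            if prop.bond_changes and prop.bond_changes[0][2] != -1:
                assert prop.dE == pytest.approx(-2.0)
                assert prop.w == 1.0
                break
        else:
            pytest.fail("flip never proposed the bound state")

    def test_translate_of_isolated_molecule_into_free_space(self):
        mono = lg.MoleculeTopology.uniform("S1", "S", 1)
        state = lg.build_system(lg.LatticeConfig(8), [(mono, 1)], seed=0)
        eng = MoveEngine(state, np.random.default_rng(0))
        prop = eng.propose_move("cluster_translate")
        assert prop is not None and prop.dE == 0.0 and prop.w == 1.0
        assert accept_move(prop.dE, prop.w, np.random.default_rng(0))

    def test_fully_blocked_pivot_is_immediate_rejection(self):
        """End bead whose whole tether region is occupied -> rejection."""
        chain = lg.MoleculeTopology.uniform("SX", "S", 2, linker_n=1, linker_e=1)
        state = lg.build_system(lg.LatticeConfig(4), [(chain, 1)], seed=1)
        # surround the middle linker bead completely with foreign beads
        mono = lg.MoleculeTopology.uniform("P1", "P", 1)
        # rebuild with blockers placed deterministically around bead 1
        state = lg.SystemState(lg.LatticeConfig(4), [chain] + [mono] * 6)
        coords = {0: (1, 1, 1), 1: (2, 1, 1), 2: (3, 1, 1)}
        offs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
        blocked = []
        for i, off in enumerate(offs):
            xyz = tuple((np.array(coords[1]) + off) % 4)
            if xyz in (coords[0], coords[2]):
                xyz = tuple((np.array([0, 3, 3]) + [i, 0, 0]) % 4)
            blocked.append(xyz)
        for i, xyz in enumerate(blocked):
            coords[3 + i] = xyz
        for b, xyz in coords.items():
            state.pos[b] = xyz
        state.occ[:] = -1
        for b in range(state.n_beads):
            state.occ[state.site_of(b)] = b
        assert lg.validate_state(state) == []
        eng = MoveEngine(state, np.random.default_rng(0))
        rejections = 0
        for _ in range(100):
            # pick proposals that move bead 0 (end domain, adjacency tether)
            prop = eng.propose_move("end_pivot")
            if prop is None:
                rejections += 1
        assert rejections > 0

    def test_unknown_move_type(self, frc_chain_system):
        eng = MoveEngine(frc_chain_system, np.random.default_rng(0))
        with pytest.raises(Exception):
            eng.propose_move("teleport")


class TestReversibility:
    @pytest.mark.parametrize("move", ["binding_flip", "end_pivot", "cluster_translate", "reptation"])
    def test_apply_then_revert_is_identity_frc(self, move, rng):
        chain_s = lg.MoleculeTopology.uniform("S3", "S", 3, linker_n=2)
        chain_p = lg.MoleculeTopology.uniform("P3", "P", 3, linker_n=2)
        state = lg.build_system(lg.LatticeConfig(9), [(chain_s, 2), (chain_p, 2)], seed=2)
        eng = MoveEngine(state, rng)
        # evolve a little so bonds exist
        for _ in range(500):
            eng.step()
        applied = 0
        for _ in range(300):
            before = (state.pos.copy(), state.partner.copy(), state.occ.copy(), state.energy)
            prop = eng.propose_move(move)
            if prop is None:
                continue
            eng.apply(prop)
            assert lg.validate_state(state) == []
            eng.revert(prop)
            assert np.array_equal(before[0], state.pos)
            assert np.array_equal(before[1], state.partner)
            assert np.array_equal(before[2], state.occ)
            assert state.energy == pytest.approx(before[3])
            applied += 1
        assert applied > 10

    @pytest.mark.parametrize("move", ["crankshaft", "end_pivot"])
    def test_apply_then_revert_is_identity_explicit(self, move, rng):
        chain_s = lg.MoleculeTopology.uniform("S3x", "S", 3, linker_n=3, linker_e=2)
        chain_p = lg.MoleculeTopology.uniform("P3x", "P", 3, linker_n=3, linker_e=2)
        state = lg.build_system(lg.LatticeConfig(10), [(chain_s, 2), (chain_p, 2)], seed=3)
        eng = MoveEngine(state, rng)
        for _ in range(500):
            eng.step()
        applied = 0
        for _ in range(300):
            before = (state.pos.copy(), state.partner.copy(), state.energy)
            prop = eng.propose_move(move)
            if prop is None:
                continue
            eng.apply(prop)
            assert lg.validate_state(state) == []
            eng.revert(prop)
            assert np.array_equal(before[0], state.pos)
            assert np.array_equal(before[1], state.partner)
            applied += 1
        assert applied > 10

    def test_rejected_moves_leave_state_bit_identical(self, rng):
        chain_s = lg.MoleculeTopology.uniform("S2", "S", 2, linker_n=1)
        p_mono = lg.MoleculeTopology.uniform("P1", "P", 1)
        state = lg.build_system(lg.LatticeConfig(3), [(chain_s, 3), (p_mono, 3)], seed=4)
        eng = MoveEngine(state, rng)
        for _ in range(2000):
            before = (state.pos.copy(), state.partner.copy(), state.energy)
            mt, accepted = eng.step()
            if not accepted:
                assert np.array_equal(before[0], state.pos)
                assert np.array_equal(before[1], state.partner)
                assert state.energy == before[2]


class TestStationaryDistribution:
    def test_flip_only_samples_conditional_boltzmann(self, bound_chain):
        """binding_flip alone on frozen positions reproduces the exact
        conditional distribution over binding matchings."""
        exact = lg.binding_enumeration(bound_chain)
        state = bound_chain
        eng = MoveEngine(state, np.random.default_rng(9))
        counts: dict = {}
        n_samp = 40000
        for i in range(n_samp + 5000):
            eng.step({"binding_flip": 1.0})
            if i >= 5000:
                key = tuple(
                    sorted(
                        (int(b), int(state.partner[b]))
                        for b in np.flatnonzero(state.partner >= 0)
                        if state.kind[b] == 0
                    )
                )
                counts[key] = counts.get(key, 0) + 1
        # compare the aggregate bond-count distribution within 3 sigma
        mc_bonds = sum(len(k) * v for k, v in counts.items()) / n_samp
        se = 3 * math.sqrt(exact.max_bonds**2 / n_samp) * 5  # generous bound
        assert mc_bonds == pytest.approx(exact.mean_bonds, abs=max(0.05, se / 100))

    def test_run_mc_zero_steps_is_identity(self, frc_chain_system):
        before = frc_chain_system.pos.copy()
        res = run_mc(frc_chain_system, 0, seed=0)
        assert np.array_equal(before, frc_chain_system.pos)
        assert len(res.records) == 1  # the initial observation only

    def test_bit_reproducibility_python_engine(self):
        chain_s = lg.MoleculeTopology.uniform("S2", "S", 2, linker_n=1)
        p_mono = lg.MoleculeTopology.uniform("P1", "P", 1)
        finals = []
        for _ in range(2):
            state = lg.build_system(lg.LatticeConfig(3), [(chain_s, 2), (p_mono, 2)], seed=5)
            run_mc(state, 3000, seed=42, engine="python")
            finals.append((state.pos.copy(), state.partner.copy()))
        assert np.array_equal(finals[0][0], finals[1][0])
        assert np.array_equal(finals[0][1], finals[1][1])

    def test_bit_reproducibility_kernel(self):
        chain_s = lg.MoleculeTopology.uniform("S2", "S", 2, linker_n=1)
        p_mono = lg.MoleculeTopology.uniform("P1", "P", 1)
        finals = []
        for _ in range(2):
            state = lg.build_system(lg.LatticeConfig(3), [(chain_s, 2), (p_mono, 2)], seed=5)
            run_mc(state, 30000, seed=42, engine="kernel")
            finals.append((state.pos.copy(), state.partner.copy()))
        assert np.array_equal(finals[0][0], finals[1][0])
        assert np.array_equal(finals[0][1], finals[1][1])

    def test_energy_cache_matches_recomputation_after_runs(self):
        chain_s = lg.MoleculeTopology.uniform("S3", "S", 3, linker_n=2)
        chain_p = lg.MoleculeTopology.uniform("P3", "P", 3, linker_n=2)
        for engine, steps in (("python", 4000), ("kernel", 200000)):
            state = lg.build_system(lg.LatticeConfig(9), [(chain_s, 2), (chain_p, 2)], seed=6)
            run_mc(state, steps, seed=7, engine=engine)
            assert state.energy == pytest.approx(lg.total_energy(state))
            assert lg.validate_state(state) == []


class TestEnginesAgainstEnumeration:
    """Long-run frequencies match the exact Boltzmann census (3 sigma)."""

    def _compare(self, state, exact, engine, n_steps, seed):
        obs = {"bonds": lambda s: float((s.partner >= 0).sum()) / 2}
        res = run_mc(state, n_steps, seed=seed, stride=10, observers=obs, engine=engine)
        rec = res.records
        tail = rec[rec["step"] >= n_steps // 5]["bonds"].to_numpy()
        # batch means to account for autocorrelation
        nb = 20
        batches = np.array_split(tail, nb)
        means = np.array([b.mean() for b in batches])
        se = means.std(ddof=1) / math.sqrt(nb)
        assert abs(means.mean() - exact.mean_bonds) < max(3 * se, 0.02), (
            f"{engine}: {means.mean():.4f} vs exact {exact.mean_bonds:.4f} (se {se:.4f})"
        )

    def test_frc_chain_python(self, frc_chain_system):
        exact = lg.exact_enumeration(frc_chain_system)
        self._compare(frc_chain_system, exact, "python", 60000, 11)

    def test_frc_chain_kernel(self, frc_chain_system):
        exact = lg.exact_enumeration(frc_chain_system)
        self._compare(frc_chain_system, exact, "kernel", 1_500_000, 12)

    def test_explicit_chain_python(self, explicit_chain_system):
        exact = lg.exact_enumeration(explicit_chain_system)
        self._compare(explicit_chain_system, exact, "python", 60000, 13)

    def test_explicit_chain_kernel(self, explicit_chain_system):
        exact = lg.exact_enumeration(explicit_chain_system)
        self._compare(explicit_chain_system, exact, "kernel", 1_500_000, 14)
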