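"""Lattice world: geometry, topologies, building, energy, validation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import latticegel as lg
from latticegel.lattice import (
    FACE_OFFSETS,
    KIND_L,
    KIND_P,
    KIND_S,
    chebyshev,
    face_adjacent,
    min_image,
)


class TestLatticeConfig:
    def test_site_count_and_wrap(self):
        cfg = lg.LatticeConfig(5)
        assert cfg.n_sites == 125
        assert np.array_equal(cfg.wrap(np.array([5, -1, 7])), [0, 4, 2])

    def test_neighbor_count_face_connectivity(self):
        assert len(lg.LatticeConfig(5).neighbor_sites(np.array([0, 0, 0]))) == 6
        # on L = 2 opposite images coincide, leaving 3 distinct neighbors
        assert len(lg.LatticeConfig(2).neighbor_sites(np.array([0, 0, 0]))) == 3

    def test_rejects_degenerate_boxes(self):
        with pytest.raises(ValueError):
            lg.LatticeConfig(1)

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(2, 20), st.tuples(st.integers(-40, 40), st.integers(-40, 40), st.integers(-40, 40)))
    def test_min_image_is_nearest_displacement(self, L, d):
        folded = min_image(np.array(d), L)
        assert np.all(folded >= -L // 2) and np.all(folded < L - L // 2)
        assert np.all((folded - np.array(d)) % L == 0)


class TestMoleculeTopology:
    def test_linker_counts_and_bead_layout(self):
        topo = lg.MoleculeTopology.uniform("A", "S", 3, linker_n=5, linker_e=2)
        assert topo.n_beads == 3 + 2 * 2
        kinds = topo.bead_kinds()
        assert list(kinds) == [KIND_S, KIND_L, KIND_L, KIND_S, KIND_L, KIND_L, KIND_S]
        assert list(topo.domain_slots()) == [0, 3, 6]

    def test_linker_flavors(self):
        assert lg.Linker(5, 0).implicit_cap == 5  # FRC: one square well
        assert lg.Linker(5, 5).implicit_cap == 0  # SARC: adjacency chain
        assert lg.Linker(5, 2).implicit_cap == 3  # hybrid

    def test_invalid_topologies_rejected(self):
        with pytest.raises(ValueError):
            lg.Linker(0)
        with pytest.raises(ValueError):
            lg.Linker(3, 4)
        with pytest.raises(ValueError):
            lg.MoleculeTopology("A", "S", 2, ())  # missing linker

    def test_tether_pattern_hybrid(self):
        topo = lg.MoleculeTopology.uniform("A", "S", 2, linker_n=5, linker_e=2)
        # D0 -adj- l1 -adj- l2 -cap3- D1
        assert topo.tethers() == [(0, 1, 0), (1, 2, 0), (2, 3, 3)]


class TestBuildSystem:
    def test_single_monomer_any_box(self):
        mono = lg.MoleculeTopology.uniform("S1", "S", 1)
        state = lg.build_system(lg.LatticeConfig(2), [(mono, 1)], seed=0)
        assert state.n_beads == 1
        assert state.energy == 0.0
        assert lg.validate_state(state) == []

    def test_paper_scale_counts_and_concentration(self):
        # 2.4e3 domains at valence 5 = 480 chains; concentration = 2400 / L^3
        va = lg.MoleculeTopology.uniform("A", "S", 5, linker_n=5)
        vb = lg.MoleculeTopology.uniform("B", "P", 5, linker_n=5)
        L = 50
        state = lg.build_system(lg.LatticeConfig(L), [(va, 240), (vb, 240)], seed=0)
        assert state.n_molecules == 480
        n_domains = int(np.sum(state.kind != KIND_L))
        assert n_domains == 2400
        assert n_domains / L**3 == pytest.approx(2400 / 125000)
        assert lg.validate_state(state) == []

    def test_overfull_box_is_capacity_error(self):
        mono = lg.MoleculeTopology.uniform("S1", "S", 1)
        with pytest.raises(lg.CapacityError):
            lg.build_system(lg.LatticeConfig(2), [(mono, 10)], seed=0)

    def test_all_domains_start_unbound_and_dispersed(self, rng):
        va = lg.MoleculeTopology.uniform("A", "S", 3, linker_n=2, linker_e=1)
        state = lg.build_system(lg.LatticeConfig(12), [(va, 20)], seed=7)
        assert np.all(state.partner == -1)
        assert lg.validate_state(state) == []

    def test_tether_cap_must_fit_box(self):
        long_linker = lg.MoleculeTopology.uniform("A", "S", 2, linker_n=5)
        with pytest.raises(ValueError, match="box side"):
            lg.build_system(lg.LatticeConfig(8), [(long_linker, 1)], seed=0)


class TestEnergy:
    def _bound_pair_state(self, bind=True):
        state = lg.generate_fixture("tiny-enumerable", 0)
        state.pos[0] = (0, 0, 0)
        state.pos[1] = (1, 0, 0)
        state.occ[:] = -1
        for b in range(2):
            state.occ[state.site_of(b)] = b
        if bind:
            state.partner[:] = [1, 0]
        state.energy = lg.total_energy(state)
        return state

    def test_two_bound_pairs_give_minus_four(self, bound_chain):
        assert lg.total_energy(bound_chain) == pytest.approx(-4.0)

    def test_adjacency_without_bound_flag_is_zero(self):
        state = self._bound_pair_state(bind=False)
        assert lg.total_energy(state) == 0.0

    def test_bound_adjacent_pair_is_u_sp(self):
        state = self._bound_pair_state(bind=True)
        assert lg.total_energy(state) == pytest.approx(-2.0)

    def test_random_state_matches_brute_force_pair_loop(self, rng):
        va = lg.MoleculeTopology.uniform("A", "S", 3, linker_n=2)
        vb = lg.MoleculeTopology.uniform("B", "P", 3, linker_n=2)
        inter = lg.InteractionModel(
            u_sp=-2.0,
            contact=np.array([[0.3, 0.0, -0.1], [0.0, 0.2, 0.0], [-0.1, 0.0, 0.1]]),
        )
        state = lg.build_system(
            lg.LatticeConfig(8), [(va, 4), (vb, 4)], seed=3, interaction=inter
        )
        # wire up a few bonds by brute search over adjacent S-P pairs
        s_doms = [b for b in state.domain_beads if state.kind[b] == KIND_S]
        p_doms = [b for b in state.domain_beads if state.kind[b] == KIND_P]
        for sd in s_doms:
            if state.partner[sd] >= 0:
                continue
            for pd in p_doms:
                if state.partner[pd] < 0 and face_adjacent(
                    state.pos[sd], state.pos[pd], state.L
                ):
                    state.partner[sd], state.partner[pd] = pd, sd
                    break
        # independent O(B^2) oracle
        expected = 0.0
        for i in range(state.n_beads):
            for j in range(i + 1, state.n_beads):
                if not face_adjacent(state.pos[i], state.pos[j], state.L):
                    continue
                if state.partner[i] == j:
                    expected += inter.u_sp
                else:
                    expected += inter.contact[state.kind[i], state.kind[j]]
        assert lg.total_energy(state) == pytest.approx(expected)

    def test_non_adjacent_bond_is_integrity_error(self):
        state = self._bound_pair_state(bind=True)
        state.set_bead(1, np.array([0, 1, 1]))  # diagonal: not face adjacent
        with pytest.raises(lg.StateIntegrityError):
            lg.total_energy(state)


class TestValidateState:
    def test_fresh_system_is_clean(self, frc_chain_system):
        assert lg.validate_state(frc_chain_system) == []

    def test_double_occupancy_detected(self, tiny_pair):
        tiny_pair.pos[1] = tiny_pair.pos[0]
        report = lg.validate_state(tiny_pair)
        assert any("occupancy" in p for p in report)

    def test_energy_drift_detected(self, bound_chain):
        bound_chain.energy += 1.0
        report = lg.validate_state(bound_chain)
        assert any("drift" in p for p in report)

    def test_broken_tether_detected(self):
        state = lg.build_system(
            lg.LatticeConfig(7),
            [(lg.MoleculeTopology.uniform("S2", "S", 2, linker_n=1), 1)],
            seed=0,
        )
        far = (state.pos[0] + np.array([3, 0, 0])) % 7
        if state.occ[state.config.site_index(far)] >= 0:
            far = (far + np.array([0, 1, 0])) % 7
        state.set_bead(1, far)
        assert any("tether" in p for p in lg.validate_state(state))
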