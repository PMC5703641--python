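"""Exhaustive enumeration of tiny lattice systems.

Independent oracle for the Monte Carlo kernel: every valid microstate
(bead placement x binding matching) of a small system is visited and
weighted by exp(-E), giving exact Boltzmann expectations to compare
against long-run sampling frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .lattice import (
    KIND_L,
    KIND_P,
    KIND_S,
    LatticeError,
    SystemState,
    face_adjacent,
)


class EnumerationCapError(LatticeError):
    """The microstate space exceeds the enumeration cap."""


@dataclass
class EnumerationResult:
    """Boltzmann-weighted census of all valid microstates."""

    Z: float
    n_microstates: int
    mean_energy: float
    mean_bonds: float
    max_bonds: int
    state_probs: dict | None = None

    @property
    def p_bound(self) -> float:
        """Probability-weighted bound fraction of the scarcer domain type."""
        return self.mean_bonds / self.max_bonds if self.max_bonds else 0.0


def _matchings(
    s_doms: list[int],
    adjacency: dict[int, list[int]],
    taken: set[int],
    idx: int,
    bonds: tuple,
) -> list[tuple]:
    """All partial matchings of S domains onto adjacent free P domains."""
    if idx == len(s_doms):
        return [bonds]
    d = s_doms[idx]
    out = _matchings(s_doms, adjacency, taken, idx + 1, bonds)  # d unbound
    for p in adjacency.get(d, []):
        if p in taken:
            continue
        taken.add(p)
        out.extend(_matchings(s_doms, adjacency, taken, idx + 1, bonds + ((d, p),)))
        taken.remove(p)
    return out


def exact_enumeration(
    state: SystemState,
    cap: int = 10**7,
    keep_states: bool = False,
) -> EnumerationResult:
    """Enumerate all placements and binding assignments of ``state``'s system.

    The current coordinates of ``state`` are ignored; only its topologies,
    box, and interaction model matter.  Raises
    :class:`EnumerationCapError` when more than ``cap`` microstates would be
    visited.
    """
    cfg = state.config
    L = cfg.L
    inter = state.interaction
    n_mol = state.n_molecules
    visited = 0

    kinds = state.kind
    n_s = int(np.sum(kinds == KIND_S))
    n_p = int(np.sum(kinds == KIND_P))
    max_bonds = min(n_s, n_p)

    sites = [np.array([x, y, z]) for x in range(L) for y in range(L) for z in range(L)]

    Z = 0.0
    e_acc = 0.0
    b_acc = 0.0
    n_states = 0
    probs: dict = {}

    pos = {}
    occ: dict[int, int] = {}

    def contact_energy() -> float:
        if not inter.has_nonspecific:
            return 0.0
        e = 0.0
        beads = sorted(pos)
        for ii, i in enumerate(beads):
            for j in beads[ii + 1 :]:
                if face_adjacent(pos[i], pos[j], L):
                    e += inter.contact[kinds[i], kinds[j]]
        return e

    def account_placement() -> None:
        nonlocal Z, e_acc, b_acc, n_states, visited
        # adjacency of S domains to P domains for this placement
        s_doms = [b for b in pos if kinds[b] == KIND_S]
        adjacency = {
            d: [
                p for p in pos
                if kinds[p] == KIND_P and face_adjacent(pos[d], pos[p], L)
            ]
            for d in s_doms
        }
        base_contact = contact_energy()
        for bonds in _matchings(s_doms, adjacency, set(), 0, ()):
            visited += 1
            if visited > cap:
                raise EnumerationCapError(f"microstate count exceeds cap {cap}")
            energy = inter.u_sp * len(bonds) + base_contact
            if inter.has_nonspecific:
                # bound pairs carry u_sp instead of their contact term
                for d, p in bonds:
                    energy -= inter.contact[kinds[d], kinds[p]]
            w = math.exp(-energy)
            Z += w
            e_acc += w * energy
            b_acc += w * len(bonds)
            n_states += 1
            if keep_states:
                key = (
                    tuple(tuple(int(v) for v in pos[b]) for b in sorted(pos)),
                    tuple(sorted(bonds)),
                )
                probs[key] = probs.get(key, 0.0) + w

    def place_molecule(m: int) -> None:
        if m == n_mol:
            account_placement()
            return
        topo = state.topologies[m]
        base = int(state.mol_start[m])
        nb = int(state.mol_len[m])
        caps = {}  # slot -> list of (earlier slot, cap)
        for a, b, cap in topo.tethers():
            caps.setdefault(max(a, b), []).append((min(a, b), cap))

        def place_slot(slot: int) -> None:
            bead = base + slot
            if slot == nb:
                place_molecule(m + 1)
                return
            for xyz in sites:
                si = cfg.site_index(xyz)
                if si in occ:
                    continue
                ok = True
                for other_slot, cap in caps.get(slot, []):
                    other_xyz = pos[base + other_slot]
                    d = np.abs(
                        ((xyz - other_xyz) + L // 2) % L - L // 2
                    )
                    if cap == 0:
                        if int(d.sum()) != 1:
                            ok = False
                            break
                    elif int(d.max()) > cap:
                        ok = False
                        break
                if not ok:
                    continue
                pos[bead] = xyz
                occ[si] = bead
                place_slot(slot + 1)
                del pos[bead]
                del occ[si]

        place_slot(0)

    place_molecule(0)
    if keep_states:
        probs = {k: v / Z for k, v in probs.items()}
    return EnumerationResult(
        Z=Z,
        n_microstates=n_states,
        mean_energy=e_acc / Z,
        mean_bonds=b_acc / Z,
        max_bonds=max_bonds,
        state_probs=probs if keep_states else None,
    )


def binding_enumeration(state: SystemState) -> EnumerationResult:
    """Boltzmann census over binding matchings at *fixed* bead positions.

    Oracle for the invariant that binding_flip alone samples the exact
    conditional distribution over binding assignments.
    """
    inter = state.interaction
    kinds = state.kind
    L = state.L
    s_doms = [int(b) for b in np.flatnonzero(kinds == KIND_S)]
    p_doms = [int(b) for b in np.flatnonzero(kinds == KIND_P)]
    adjacency = {
        d: [p for p in p_doms if face_adjacent(state.pos[d], state.pos[p], L)]
        for d in s_doms
    }
    Z = 0.0
    e_acc = 0.0
    b_acc = 0.0
    probs: dict = {}
    n_states = 0
    for bonds in _matchings(s_doms, adjacency, set(), 0, ()):
        energy = inter.u_sp * len(bonds)
        w = math.exp(-energy)
        Z += w
        e_acc += w * energy
        b_acc += w * len(bonds)
        probs[tuple(sorted(bonds))] = w
        n_states += 1
    return EnumerationResult(
        Z=Z,
        n_microstates=n_states,
        mean_energy=e_acc / Z,
        mean_bonds=b_acc / Z,
        max_bonds=min(len(s_doms), len(p_doms)),
        state_probs={k: v / Z for k, v in probs.items()},
    )
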