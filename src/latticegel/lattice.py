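"""Cubic-lattice world: geometry, molecule topologies, interactions, system state.

The model lives on an L x L x L cubic lattice with periodic boundary
conditions.  Each SH3 domain, PRM, or explicitly modeled linker bead occupies
exactly one lattice site.  Interaction domains (S = SH3, P = PRM) form 1:1
bound complexes only when they sit on adjacent sites *and* the binding flag is
set; adjacency alone contributes no energy under the default interaction
model (u_SP = -2 k_B*T, all other pair energies zero).

Linkers between consecutive domains of a chain come in three flavors:

* fully implicit (Flory-random-coil-like, effective solvation volume ~ 0):
  a tether of length ``n`` that occupies no sites; the two tethered beads may
  not move further apart than ``n`` under the Chebyshev (max-norm) metric --
  the "cubic infinite square well".
* fully explicit (self-avoiding-coil-like, positive solvation volume):
  ``n`` volume-excluding beads, each face-adjacent to its neighbors along
  the chain.
* hybrid: ``e`` explicit beads placed contiguously after the upstream domain,
  with the remaining span of ``n - e`` sites treated as one implicit square
  well between the last explicit bead and the downstream domain.

Coordinates are integer triples in [0, L)^3; distances use the minimum-image
convention.  "Adjacent" means face adjacency (6 neighbors; 3 distinct sites
when L = 2 because opposite images coincide).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# bead kind codes
KIND_S = 0
KIND_P = 1
KIND_L = 2
KIND_LETTERS = ("S", "P", "L")
KIND_CODES = {"S": KIND_S, "P": KIND_P, "L": KIND_L}

#: face-neighbor offsets on the cubic lattice
FACE_OFFSETS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=np.int64,
)


class LatticeError(Exception):
    """Base class for lattice-model errors."""


class CapacityError(LatticeError):
    """Requested packing cannot be placed on the lattice."""


class StateIntegrityError(LatticeError):
    """The system state violates a structural invariant."""


@dataclass(frozen=True)
class LatticeConfig:
    """Cubic simulation box.

    Parameters
    ----------
    L : int
        Box side length in lattice units (>= 2).
    periodic : bool
        Periodic boundaries; the model assumes these, so only True is valid.
    connectivity : str
        Neighbor definition for contacts; only face (6-neighbor) connectivity
        is implemented.
    """

    L: int
    periodic: bool = True
    connectivity: str = "face"

    def __post_init__(self) -> None:
        if self.L < 2:
            raise ValueError("box side L must be >= 2")
        if not self.periodic:
            raise ValueError("only periodic boundaries are supported")
        if self.connectivity != "face":
            raise ValueError("only face (6-neighbor) connectivity is supported")

    @property
    def n_sites(self) -> int:
        return self.L**3

    def wrap(self, xyz: np.ndarray) -> np.ndarray:
        return np.mod(xyz, self.L)

    def site_index(self, xyz: np.ndarray) -> int:
        x, y, z = (int(v) % self.L for v in xyz)
        return (x * self.L + y) * self.L + z

    def neighbor_sites(self, xyz: np.ndarray) -> list[np.ndarray]:
        """Distinct face-adjacent sites of ``xyz`` (3 when L == 2, else 6)."""
        offs = FACE_OFFSETS[::2] if self.L == 2 else FACE_OFFSETS
        return [self.wrap(np.asarray(xyz) + o) for o in offs]


def min_image(delta: np.ndarray, L: int) -> np.ndarray:
    """Per-axis displacement folded into [-L/2, L/2)."""
    return (np.asarray(delta) + L // 2) % L - L // 2


def chebyshev(a: np.ndarray, b: np.ndarray, L: int) -> int:
    return int(np.max(np.abs(min_image(np.asarray(a) - np.asarray(b), L))))


def face_adjacent(a: np.ndarray, b: np.ndarray, L: int) -> bool:
    d = np.abs(min_image(np.asarray(a) - np.asarray(b), L))
    return int(d.sum()) == 1


@dataclass(frozen=True)
class Linker:
    """One inter-domain linker: total span ``n`` sites, ``e`` explicit beads."""

    n: int
    e: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("linker length n must be >= 1")
        if not 0 <= self.e <= self.n:
            raise ValueError("explicit bead count must satisfy 0 <= e <= n")

    @property
    def implicit_cap(self) -> int:
        """Span of the trailing implicit segment (0 means face adjacency)."""
        return self.n - self.e


@dataclass(frozen=True)
class MoleculeTopology:
    """Species definition: a linear chain of ``valence`` interaction domains.

    ``domain_kind`` is "S" for poly-SH3-like and "P" for poly-PRM-like
    species.  ``linkers`` holds the valence - 1 linkers in chain order.
    """

    label: str
    domain_kind: str
    valence: int
    linkers: tuple[Linker, ...] = ()

    def __post_init__(self) -> None:
        if self.domain_kind not in ("S", "P"):
            raise ValueError("domain_kind must be 'S' or 'P'")
        if self.valence < 1:
            raise ValueError("valence must be >= 1")
        if len(self.linkers) != self.valence - 1:
            raise ValueError("need exactly valence - 1 linkers")

    @classmethod
    def uniform(
        cls, label: str, domain_kind: str, valence: int, linker_n: int = 0, linker_e: int = 0
    ) -> "MoleculeTopology":
        """Chain with identical linkers (poly-SH3/poly-PRM-style chains)."""
        linkers = tuple(Linker(linker_n, linker_e) for _ in range(valence - 1))
        return cls(label, domain_kind, valence, linkers)

    @property
    def n_beads(self) -> int:
        return self.valence + sum(lk.e for lk in self.linkers)

    @property
    def uniform_linker(self) -> Linker | None:
        """The common linker if all linkers are identical (None otherwise)."""
        if not self.linkers:
            return None
        first = self.linkers[0]
        return first if all(lk == first for lk in self.linkers) else None

    def bead_kinds(self) -> np.ndarray:
        """Bead kind codes in slot order: D0, linker0 beads, D1, ..."""
        dk = KIND_CODES[self.domain_kind]
        kinds = [dk]
        for lk in self.linkers:
            kinds.extend([KIND_L] * lk.e)
            kinds.append(dk)
        return np.array(kinds, dtype=np.int8)

    def domain_slots(self) -> np.ndarray:
        """Offsets of the interaction domains within the molecule block."""
        slots, off = [0], 0
        for lk in self.linkers:
            off += lk.e + 1
            slots.append(off)
        return np.array(slots, dtype=np.int64)

    def tethers(self) -> list[tuple[int, int, int]]:
        """(slot_a, slot_b, cap) constraints; cap 0 = face adjacency,
        cap m >= 1 = Chebyshev square well of half-width m."""
        out = []
        off = 0
        for lk in self.linkers:
            prev_dom = off
            if lk.e == 0:
                out.append((prev_dom, prev_dom + 1, lk.n))
            else:
                for i in range(lk.e):
                    out.append((off + i, off + i + 1, 0))
                out.append((off + lk.e, off + lk.e + 1, lk.implicit_cap))
            off += lk.e + 1
        return out


@dataclass
class InteractionModel:
    """Contact energies in units of k_B*T.

    ``u_sp`` is the specific S-P binding energy, paid once per *bound*
    adjacent S-P pair.  ``contact`` is an optional symmetric 3x3 matrix of
    nonspecific nearest-neighbor energies (indexed by kind codes S, P, L),
    paid for every adjacent bead pair that is not a bound complex; it is zero
    in the default model.
    """

    u_sp: float = -2.0
    contact: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.contact is not None:
            c = np.asarray(self.contact, dtype=float)
            if c.shape != (3, 3) or not np.allclose(c, c.T):
                raise ValueError("contact matrix must be symmetric 3x3")
            self.contact = c

    @property
    def has_nonspecific(self) -> bool:
        return self.contact is not None and bool(np.any(self.contact != 0.0))


class SystemState:
    """Full microstate of one lattice simulation.

    Array-backed so the reference move engine and the compiled kernel operate
    on the same storage.  Beads of molecule ``m`` occupy the contiguous index
    range ``mol_start[m] : mol_start[m] + mol_len[m]`` in chain-slot order.
    """

    def __init__(
        self,
        config: LatticeConfig,
        topologies: list[MoleculeTopology],
        interaction: InteractionModel | None = None,
    ):
        self.config = config
        self.interaction = interaction if interaction is not None else InteractionModel()
        self.topologies = list(topologies)

        n_mol = len(self.topologies)
        lengths = [t.n_beads for t in self.topologies]
        n_beads = int(sum(lengths))
        if n_beads > config.n_sites:
            raise CapacityError(
                f"{n_beads} beads cannot fit on {config.n_sites} sites"
            )

        self.n_molecules = n_mol
        self.n_beads = n_beads
        self.mol_len = np.array(lengths, dtype=np.int64)
        self.mol_start = np.concatenate(([0], np.cumsum(self.mol_len)[:-1])).astype(np.int64)

        self.pos = np.zeros((n_beads, 3), dtype=np.int64)
        self.kind = np.concatenate([t.bead_kinds() for t in self.topologies]) if n_beads else np.zeros(0, np.int8)
        self.mol = np.repeat(np.arange(n_mol, dtype=np.int64), self.mol_len)
        self.partner = np.full(n_beads, -1, dtype=np.int64)
        self.occ = np.full(config.n_sites, -1, dtype=np.int64)
        self.energy = 0.0

        # tether tables: up to two constraints per bead
        self.teth_n = np.zeros(n_beads, dtype=np.int8)
        self.teth_other = np.full((n_beads, 2), -1, dtype=np.int64)
        self.teth_cap = np.zeros((n_beads, 2), dtype=np.int64)
        for m, topo in enumerate(self.topologies):
            base = self.mol_start[m]
            for a, b, cap in topo.tethers():
                for u, v in ((base + a, base + b), (base + b, base + a)):
                    k = self.teth_n[u]
                    if k >= 2:
                        raise StateIntegrityError("bead with more than two tethers")
                    self.teth_other[u, k] = v
                    self.teth_cap[u, k] = cap
                    self.teth_n[u] = k + 1

        # minimum-image square wells (and uniform offset proposals) need the
        # box to exceed the tether diameter on every axis
        max_cap = int(self.teth_cap.max()) if n_beads else 0
        if 2 * max_cap + 1 > config.L:
            raise ValueError(
                f"tether span {max_cap} needs box side >= {2 * max_cap + 1} "
                f"(got L={config.L})"
            )

        self.domain_beads = np.flatnonzero(self.kind != KIND_L).astype(np.int64)
        self.end_beads = np.flatnonzero(self.teth_n == 1).astype(np.int64)
        self.mid_beads = np.flatnonzero(self.teth_n == 2).astype(np.int64)

    # -- geometry helpers -------------------------------------------------
    @property
    def L(self) -> int:
        return self.config.L

    def site_of(self, bead: int) -> int:
        return self.config.site_index(self.pos[bead])

    def set_bead(self, bead: int, xyz: np.ndarray) -> None:
        """Place ``bead`` at ``xyz`` updating occupancy (no checks)."""
        self.occ[self.site_of(bead)] = -1
        self.pos[bead] = self.config.wrap(np.asarray(xyz))
        self.occ[self.site_of(bead)] = bead

    def tether_ok(self, bead: int) -> bool:
        for k in range(self.teth_n[bead]):
            other = self.teth_other[bead, k]
            cap = self.teth_cap[bead, k]
            if cap == 0:
                if not face_adjacent(self.pos[bead], self.pos[other], self.L):
                    return False
            elif chebyshev(self.pos[bead], self.pos[other], self.L) > cap:
                return False
        return True

    def bound_pairs(self) -> list[tuple[int, int]]:
        out = []
        for i in np.flatnonzero(self.partner >= 0):
            j = self.partner[i]
            if i < j:
                out.append((int(i), int(j)))
        return out

    def copy(self) -> "SystemState":
        new = SystemState.__new__(SystemState)
        new.config = self.config
        new.interaction = self.interaction
        new.topologies = list(self.topologies)
        for name in ("mol_len", "mol_start", "pos", "kind", "mol", "partner",
                     "occ", "teth_n", "teth_other", "teth_cap",
                     "domain_beads", "end_beads", "mid_beads"):
            setattr(new, name, getattr(self, name).copy())
        new.n_molecules = self.n_molecules
        new.n_beads = self.n_beads
        new.energy = self.energy
        return new


def total_energy(state: SystemState, *, check: bool = True) -> float:
    """System energy in k_B*T from a from-scratch pass over the state.

    Sum of ``u_sp`` over bound adjacent S-P pairs plus any configured
    nonspecific contact terms.  Raises :class:`StateIntegrityError` when the
    binding map is inconsistent (non-adjacent or non-complementary bonds).
    """
    inter = state.interaction
    e = 0.0
    for i, j in state.bound_pairs():
        if check:
            kinds = {int(state.kind[i]), int(state.kind[j])}
            if kinds != {KIND_S, KIND_P}:
                raise StateIntegrityError(f"bond {i}-{j} is not S-P")
            if not face_adjacent(state.pos[i], state.pos[j], state.L):
                raise StateIntegrityError(f"bond {i}-{j} joins non-adjacent sites")
        e += inter.u_sp
    if inter.has_nonspecific:
        seen = set()
        for i in range(state.n_beads):
            for site in state.config.neighbor_sites(state.pos[i]):
                j = state.occ[state.config.site_index(site)]
                if j < 0 or j == i:
                    continue
                key = (min(i, int(j)), max(i, int(j)))
                if key in seen:
                    continue
                seen.add(key)
                if state.partner[key[0]] == key[1]:
                    continue  # bound pairs carry u_sp only
                e += inter.contact[state.kind[key[0]], state.kind[key[1]]]
    return e


def validate_state(state: SystemState) -> list[str]:
    """Diagnostic pass over every structural invariant; [] when valid."""
    problems: list[str] = []
    # occupancy <-> positions
    sites = [state.site_of(i) for i in range(state.n_beads)]
    if len(set(sites)) != len(sites):
        problems.append("double occupancy: two beads share a lattice site")
    occ_nonempty = np.flatnonzero(state.occ >= 0)
    if sorted(int(state.occ[s]) for s in occ_nonempty) != sorted(range(state.n_beads)) or any(
        state.occ[s] >= 0 and sites[state.occ[s]] != s for s in occ_nonempty
    ):
        problems.append("occupancy index out of sync with bead positions")
    # binding map
    for i in range(state.n_beads):
        p = int(state.partner[i])
        if p < 0:
            continue
        if state.kind[i] == KIND_L:
            problems.append(f"linker bead {i} carries a bond")
        elif state.partner[p] != i:
            problems.append(f"asymmetric bond {i}->{p}")
        elif {int(state.kind[i]), int(state.kind[p])} != {KIND_S, KIND_P}:
            problems.append(f"non-complementary bond {i}-{p}")
        elif not face_adjacent(state.pos[i], state.pos[p], state.L):
            problems.append(f"bond {i}-{p} joins non-adjacent sites")
        elif state.mol[i] == state.mol[p]:
            # not forbidden physically, but impossible for single-kind chains
            pass
    # tethers
    for i in range(state.n_beads):
        if not state.tether_ok(i):
            problems.append(f"tether constraint broken at bead {i}")
    # cached energy
    try:
        fresh = total_energy(state, check=False)
        if abs(fresh - state.energy) > 1e-9:
            problems.append(
                f"energy cache drift: cached {state.energy}, recomputed {fresh}"
            )
    except StateIntegrityError as exc:  # pragma: no cover - reported above
        problems.append(str(exc))
    return problems


def build_system(
    config: LatticeConfig,
    species_counts: list[tuple[MoleculeTopology, int]],
    seed: int | np.random.Generator = 0,
    interaction: InteractionModel | None = None,
    max_retries: int = 500,
) -> SystemState:
    """Place molecules at random without overlap; all domains start unbound.

    Sequential random insertion: each chain is grown bead by bead (domains
    inside their tether wells, explicit beads on free adjacent sites) and the
    whole molecule is retried on a dead end.  Raises :class:`CapacityError`
    when a molecule cannot be placed within ``max_retries`` attempts.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    topologies: list[MoleculeTopology] = []
    for topo, count in species_counts:
        topologies.extend([topo] * count)
    state = SystemState(config, topologies, interaction)
    L = config.L

    for m, topo in enumerate(state.topologies):
        base = int(state.mol_start[m])
        placed = False
        for _ in range(max_retries):
            trial_sites: list[int] = []
            ok = True
            # head domain anywhere free
            xyz = rng.integers(0, L, size=3)
            if state.occ[config.site_index(xyz)] >= 0:
                continue
            coords = [xyz]
            trial_sites.append(config.site_index(xyz))
            state.occ[trial_sites[-1]] = base  # provisional
            slot = 0
            for lk in topo.linkers:
                for _b in range(lk.e):
                    cands = [
                        s for s in config.neighbor_sites(coords[-1])
                        if state.occ[config.site_index(s)] < 0
                    ]
                    if not cands:
                        ok = False
                        break
                    xyz = cands[rng.integers(len(cands))]
                    slot += 1
                    coords.append(xyz)
                    trial_sites.append(config.site_index(xyz))
                    state.occ[trial_sites[-1]] = base + slot
                if not ok:
                    break
                cap = lk.implicit_cap
                if cap == 0:
                    cands = [
                        s for s in config.neighbor_sites(coords[-1])
                        if state.occ[config.site_index(s)] < 0
                    ]
                else:
                    cands = []
                    anchor = coords[-1]
                    for dx in range(-cap, cap + 1):
                        for dy in range(-cap, cap + 1):
                            for dz in range(-cap, cap + 1):
                                s = config.wrap(anchor + np.array([dx, dy, dz]))
                                if state.occ[config.site_index(s)] < 0:
                                    cands.append(s)
                if not cands:
                    ok = False
                    break
                xyz = cands[rng.integers(len(cands))]
                slot += 1
                coords.append(xyz)
                trial_sites.append(config.site_index(xyz))
                state.occ[trial_sites[-1]] = base + slot
            if ok:
                for s_off, c in enumerate(coords):
                    state.pos[base + s_off] = c
                placed = True
                break
            for s in trial_sites:
                state.occ[s] = -1
        if not placed:
            for s in np.flatnonzero(state.occ >= 0):
                if state.occ[s] >= base:
                    state.occ[s] = -1
            raise CapacityError(
                f"could not place molecule {m} ({topo.label}) after "
                f"{max_retries} attempts; density too high"
            )
    state.energy = 0.0
    return state
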