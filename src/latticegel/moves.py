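"""Metropolis-Hastings kernel: the five lattice moves and the run loop.

Moves
-----
binding_flip
    Redraw the interaction state of a random domain in place (w = 1).
end_pivot
    Relocate a singly tethered end bead anywhere inside its tether region
    and redraw its interaction state if it is a domain (w = N_p / N_c).
crankshaft
    Relocate a doubly tethered bead inside the intersection of both tether
    regions, redrawing the interaction state for domains (w = N_p / N_c).
cluster_translate
    Rigid unit-vector translation of one connected binding network; creates
    and destroys nothing, so it is accepted whenever it is steric-overlap
    free.
reptation
    Slither a chain: remove an end domain plus its linker and append it at
    the other end with a random admissible conformation and interaction
    state (w = N_p V_p / (N_c V_c)).

``N_c`` / ``N_p`` count the admissible interaction states of the moved
domain (the unbound state plus each free complementary domain on a distinct
adjacent site) at the current / proposed position; ``V_c`` / ``V_p`` count
the admissible conformations of the reptated segment at the vacated /
target chain end.  A proposal that lands any bead on an occupied site is an
immediate rejection.  Accepted or not, every elementary attempt counts as
one Monte Carlo step; acceptance follows min{1, w * exp(-dE)}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .lattice import (
    KIND_L,
    KIND_P,
    KIND_S,
    LatticeError,
    SystemState,
    chebyshev,
    min_image,
    total_energy,
)

MOVE_TYPES = ("binding_flip", "end_pivot", "crankshaft", "cluster_translate", "reptation")


class MoveError(LatticeError):
    """Unknown or inapplicable move type."""


@dataclass
class MoveProposal:
    """One attempted move, with everything needed to apply and revert it."""

    move_type: str
    beads: np.ndarray  # beads whose position changes, in application order
    old_pos: np.ndarray
    new_pos: np.ndarray
    # (domain, old_partner, new_partner) triples; -1 means unbound
    bond_changes: list[tuple[int, int, int]] = field(default_factory=list)
    dE: float = 0.0
    w: float = 1.0
    n_c: int = 1
    n_p: int = 1
    v_c: int = 1
    v_p: int = 1


def accept_move(dE: float, w: float, rng: np.random.Generator) -> bool:
    """Modified Metropolis criterion min{1, w * exp(-dE)} (energies in k_B*T).

    Consumes exactly one uniform variate when the probability is < 1.
    """
    if not w > 0:
        raise ValueError("Hastings weight w must be positive")
    if not math.isfinite(dE):
        raise ValueError("dE must be finite")
    p = w * math.exp(-dE)
    if p >= 1.0:
        return True
    return rng.random() < p


class MoveEngine:
    """Reference (pure-Python) proposal/apply/revert machinery.

    Exact but slow; production sweeps go through the compiled kernel in
    :mod:`latticegel._kernel`, which is validated against this engine and the
    exact-enumeration oracle on tiny systems.
    """

    def __init__(self, state: SystemState, rng: np.random.Generator | int = 0):
        self.state = state
        self.rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        self._rept_mols = self._reptation_eligible()

    # ------------------------------------------------------------------
    def _reptation_eligible(self) -> np.ndarray:
        """Molecules reptation can act on: valence >= 2, identical linkers."""
        out = []
        for m, topo in enumerate(self.state.topologies):
            if topo.valence >= 2 and topo.uniform_linker is not None:
                out.append(m)
        return np.array(out, dtype=np.int64)

    def applicable_moves(self, include_explicit_reptation: bool = False) -> list[str]:
        s = self.state
        moves = []
        if len(s.domain_beads):
            moves.append("binding_flip")
        if len(s.end_beads):
            moves.append("end_pivot")
        if len(s.mid_beads):
            moves.append("crankshaft")
        moves.append("cluster_translate")
        rept = [
            m for m in self._rept_mols
            if include_explicit_reptation or s.topologies[m].uniform_linker.e == 0
        ]
        if rept:
            moves.append("reptation")
        return moves

    # -- shared helpers --------------------------------------------------
    def _binding_options(self, dom: int, at_pos: np.ndarray) -> list[int]:
        """Free complementary domains on distinct sites adjacent to ``at_pos``.

        The mover's own current partner counts as free (its bond is broken by
        the move under consideration).
        """
        s = self.state
        want = KIND_P if s.kind[dom] == KIND_S else KIND_S
        own = s.partner[dom]
        opts = []
        for site in s.config.neighbor_sites(at_pos):
            j = s.occ[s.config.site_index(site)]
            if j < 0 or j == dom:
                continue
            if s.kind[j] != want:
                continue
            if s.partner[j] == -1 or s.partner[j] == dom or j == own:
                opts.append(int(j))
        return opts

    def _draw_binding(self, dom: int, at_pos: np.ndarray) -> tuple[int, int]:
        """Uniform draw over the N admissible states; returns (partner, N)."""
        opts = self._binding_options(dom, at_pos)
        n = 1 + len(opts)
        j = int(self.rng.integers(n))
        return (-1 if j == 0 else opts[j - 1]), n

    def _bond_dE(self, changes: list[tuple[int, int, int]]) -> float:
        u = self.state.interaction.u_sp
        return sum(u * ((new != -1) - (old != -1)) for _, old, new in changes)

    def _implicit_candidates_1(self, anchor: np.ndarray, cap: int) -> np.ndarray:
        """Uniform site inside one tether region of ``anchor``."""
        if cap == 0:
            sites = self.state.config.neighbor_sites(anchor)
            return sites[int(self.rng.integers(len(sites)))]
        off = self.rng.integers(-cap, cap + 1, size=3)
        return self.state.config.wrap(anchor + off)

    def _candidates_2(self, p1: np.ndarray, c1: int, p2: np.ndarray, c2: int) -> np.ndarray:
        """Uniform site in the intersection of two tether regions."""
        s = self.state
        L = s.L
        if c1 > 0 and c2 > 0:
            # intersection of two Chebyshev cubes is a per-axis product set
            new = np.zeros(3, dtype=np.int64)
            for ax in range(3):
                vals = [
                    (p1[ax] + d) % L
                    for d in range(-c1, c1 + 1)
                    if abs(int(min_image(np.array([p1[ax] + d - p2[ax]]), L)[0])) <= c2
                ]
                new[ax] = vals[int(self.rng.integers(len(vals)))]
            return new
        if c2 == 0 and c1 != 0:
            p1, c1, p2, c2 = p2, c2, p1, c1
        cands = [
            site for site in s.config.neighbor_sites(p1)
            if (c2 == 0 and sum(abs(min_image(site - p2, L))) == 1)
            or (c2 > 0 and chebyshev(site, p2, L) <= c2)
        ]
        return cands[int(self.rng.integers(len(cands)))]

    # -- proposals -------------------------------------------------------
    def propose_move(self, move_type: str) -> MoveProposal | None:
        """Build one proposal; ``None`` is an immediate (steric) rejection."""
        if move_type == "binding_flip":
            return self._propose_flip()
        if move_type == "end_pivot":
            return self._propose_pivot()
        if move_type == "crankshaft":
            return self._propose_crankshaft()
        if move_type == "cluster_translate":
            return self._propose_translate()
        if move_type == "reptation":
            return self._propose_reptation()
        raise MoveError(f"unknown move type {move_type!r}")

    def _propose_flip(self) -> MoveProposal:
        s = self.state
        if not len(s.domain_beads):
            raise MoveError("binding_flip needs at least one domain")
        dom = int(s.domain_beads[self.rng.integers(len(s.domain_beads))])
        new_partner, n = self._draw_binding(dom, s.pos[dom])
        old_partner = int(s.partner[dom])
        changes = [] if new_partner == old_partner else [(dom, old_partner, new_partner)]
        empty = np.zeros((0, 3), dtype=np.int64)
        return MoveProposal(
            "binding_flip", np.zeros(0, np.int64), empty, empty,
            changes, self._bond_dE(changes), 1.0, n, n,
        )

    def _move_one_bead(self, move_type: str, bead: int, new_xyz: np.ndarray) -> MoveProposal | None:
        s = self.state
        new_xyz = s.config.wrap(new_xyz)
        tgt = s.occ[s.config.site_index(new_xyz)]
        if tgt >= 0 and tgt != bead:
            return None  # steric rejection
        changes: list[tuple[int, int, int]] = []
        n_c = n_p = 1
        if s.kind[bead] != KIND_L:
            n_c = 1 + len(self._binding_options(bead, s.pos[bead]))
            new_partner, n_p = self._draw_binding(bead, new_xyz)
            old_partner = int(s.partner[bead])
            if new_partner != old_partner or not np.array_equal(new_xyz, s.pos[bead]):
                # a bond only survives the move if the partner stays adjacent;
                # simplest consistent rule: the move always redraws the state.
                changes = [(bead, old_partner, new_partner)]
        prop = MoveProposal(
            move_type,
            np.array([bead], dtype=np.int64),
            s.pos[[bead]].copy(),
            new_xyz[None, :].copy(),
            changes,
            0.0,
            n_p / n_c,
            n_c,
            n_p,
        )
        prop.dE = self._bond_dE(changes) + self._contact_dE(prop)
        return prop

    def _propose_pivot(self) -> MoveProposal | None:
        s = self.state
        if not len(s.end_beads):
            raise MoveError("end_pivot inapplicable: no singly tethered beads")
        bead = int(s.end_beads[self.rng.integers(len(s.end_beads))])
        anchor = s.pos[int(s.teth_other[bead, 0])]
        cap = int(s.teth_cap[bead, 0])
        new_xyz = self._implicit_candidates_1(anchor, cap)
        return self._move_one_bead("end_pivot", bead, new_xyz)

    def _propose_crankshaft(self) -> MoveProposal | None:
        s = self.state
        if not len(s.mid_beads):
            raise MoveError("crankshaft inapplicable: no doubly tethered beads")
        bead = int(s.mid_beads[self.rng.integers(len(s.mid_beads))])
        j1, j2 = int(s.teth_other[bead, 0]), int(s.teth_other[bead, 1])
        c1, c2 = int(s.teth_cap[bead, 0]), int(s.teth_cap[bead, 1])
        new_xyz = self._candidates_2(s.pos[j1], c1, s.pos[j2], c2)
        return self._move_one_bead("crankshaft", bead, new_xyz)

    def cluster_of(self, mol: int) -> list[int]:
        """Molecules connected to ``mol`` through intermolecular bonds."""
        s = self.state
        seen = {mol}
        stack = [mol]
        while stack:
            m = stack.pop()
            lo, hi = s.mol_start[m], s.mol_start[m] + s.mol_len[m]
            for b in range(lo, hi):
                p = s.partner[b]
                if p >= 0:
                    pm = int(s.mol[p])
                    if pm not in seen:
                        seen.add(pm)
                        stack.append(pm)
        return sorted(seen)

    def _propose_translate(self) -> MoveProposal | None:
        s = self.state
        m0 = int(self.rng.integers(s.n_molecules))
        cluster = self.cluster_of(m0)
        direction = np.zeros(3, dtype=np.int64)
        ax = int(self.rng.integers(3))
        direction[ax] = 1 if self.rng.integers(2) else -1
        beads = np.concatenate(
            [np.arange(s.mol_start[m], s.mol_start[m] + s.mol_len[m]) for m in cluster]
        ).astype(np.int64)
        in_cluster = np.zeros(s.n_beads, dtype=bool)
        in_cluster[beads] = True
        new_pos = s.config.wrap(s.pos[beads] + direction)
        for xyz in new_pos:
            tgt = s.occ[s.config.site_index(xyz)]
            if tgt >= 0 and not in_cluster[tgt]:
                return None
        prop = MoveProposal(
            "cluster_translate", beads, s.pos[beads].copy(), new_pos, [], 0.0, 1.0
        )
        prop.dE = self._contact_dE(prop)
        return prop

    def _segment_conformations(
        self, anchor: np.ndarray, steps: list[int], exclude: set[int], limit: int | None = None
    ) -> list[list[np.ndarray]]:
        """All placements of a chain segment grown from ``anchor``.

        ``steps`` holds one tether cap per new bead (0 = face adjacency).
        Sites occupied by beads not in ``exclude`` block the path, as do
        earlier beads of the partial segment.
        """
        s = self.state
        L = s.L
        if len(steps) == 1 and steps[0] > 0:
            # single implicit-tethered domain: free sites in a Chebyshev ball
            cap = steps[0]
            ax, ay, az = (int(v) for v in anchor)
            out = []
            for dx in range(-cap, cap + 1):
                for dy in range(-cap, cap + 1):
                    for dz in range(-cap, cap + 1):
                        x, y, z = (ax + dx) % L, (ay + dy) % L, (az + dz) % L
                        j = s.occ[(x * L + y) * L + z]
                        if j < 0 or int(j) in exclude:
                            out.append([np.array([x, y, z], dtype=np.int64)])
            return out
        results: list[list[np.ndarray]] = []

        def free(site: np.ndarray, taken: list[np.ndarray]) -> bool:
            occ = s.occ[s.config.site_index(site)]
            if occ >= 0 and int(occ) not in exclude:
                return False
            return all(not np.array_equal(site, t) for t in taken)

        def grow(prev: np.ndarray, depth: int, taken: list[np.ndarray]) -> None:
            if limit is not None and len(results) >= limit:
                return
            cap = steps[depth]
            if cap == 0:
                cands = s.config.neighbor_sites(prev)
            else:
                cands = [
                    s.config.wrap(prev + np.array([dx, dy, dz]))
                    for dx in range(-cap, cap + 1)
                    for dy in range(-cap, cap + 1)
                    for dz in range(-cap, cap + 1)
                ]
            for c in cands:
                if not free(c, taken):
                    continue
                if depth == len(steps) - 1:
                    results.append(taken + [c])
                else:
                    grow(c, depth + 1, taken + [c])

        grow(anchor, 0, [])
        return results

    def _propose_reptation(self, include_explicit: bool = False) -> MoveProposal | None:
        s = self.state
        elig = [
            m for m in self._rept_mols
            if include_explicit or s.topologies[m].uniform_linker.e == 0
        ]
        if not elig:
            raise MoveError("reptation inapplicable: no eligible molecules")
        m = int(elig[int(self.rng.integers(len(elig)))])
        topo = s.topologies[m]
        lk = topo.uniform_linker
        stride = lk.e + 1
        base = int(s.mol_start[m])
        nb = int(s.mol_len[m])
        head_removal = bool(self.rng.integers(2))

        # constraint pattern for one linker+domain segment grown off an anchor:
        # e adjacency steps (the explicit beads sit next to the upstream
        # domain) then one implicit step of span n-e for the domain itself.
        tail_steps = [0] * lk.e + [lk.implicit_cap]
        # grown backwards from the downstream anchor the pattern reverses
        head_steps = [lk.implicit_cap] + [0] * lk.e

        if head_removal:
            seg = list(range(base, base + stride))          # D0 + its linker
            dom_old = base
            anchor_p = s.pos[base + nb - 1]                 # append after tail
            anchor_c = s.pos[base + stride]                 # D1 anchors old end
            place_steps, count_steps = tail_steps, head_steps
        else:
            seg = list(range(base + nb - stride, base + nb))  # linker + D_{V-1}
            dom_old = base + nb - 1
            anchor_p = s.pos[base]
            anchor_c = s.pos[base + nb - stride - 1]
            place_steps, count_steps = head_steps, tail_steps

        exclude = set(seg)
        placements = self._segment_conformations(anchor_p, place_steps, exclude)
        v_p = len(placements)
        if v_p == 0:
            return None
        choice = placements[int(self.rng.integers(v_p))]
        v_c = len(self._segment_conformations(anchor_c, count_steps, exclude))
        # segment coordinates in chain order (linker beads then domain when
        # appending at the tail; domain then linker when appending at head)
        if head_removal:
            new_seg_coords = choice                          # l1..le, D_new
            dom_new_xyz = choice[-1]
        else:
            new_seg_coords = choice[::-1]                    # D_new, l1..le
            dom_new_xyz = choice[-1]

        n_c = 1 + len(self._binding_options(dom_old, s.pos[dom_old]))
        new_partner, n_p = self._draw_binding(dom_old, dom_new_xyz)

        # full-molecule position shuffle: shift every slot by one segment
        beads = np.arange(base, base + nb, dtype=np.int64)
        old_block = s.pos[beads].copy()
        new_block = old_block.copy()
        if head_removal:
            new_block[: nb - stride] = old_block[stride:]
            new_block[nb - stride:] = np.array(new_seg_coords)
        else:
            new_block[stride:] = old_block[: nb - stride]
            new_block[:stride] = np.array(new_seg_coords)

        # bonds follow their bead through the slot shift; expressed as a
        # full old->new partner mapping over the molecule's domain slots
        dom_beads = [base + slot for slot in range(0, nb, stride)]
        old_p = {b: int(s.partner[b]) for b in dom_beads}
        changes = []
        for k, b in enumerate(dom_beads):
            if head_removal:
                new = new_partner if k == len(dom_beads) - 1 else old_p[dom_beads[k + 1]]
            else:
                new = new_partner if k == 0 else old_p[dom_beads[k - 1]]
            changes.append((b, old_p[b], new))

        prop = MoveProposal(
            "reptation", beads, old_block, new_block, changes,
            0.0, (n_p * v_p) / (n_c * v_c), n_c, n_p, v_c, v_p,
        )
        prop.dE = self._bond_dE(changes) + self._contact_dE(prop)
        return prop

    # -- energy for nonspecific models -----------------------------------
    def _contact_dE(self, prop: MoveProposal) -> float:
        """Nonspecific contact-energy change (zero under the default model).

        Computed by apply/recompute/revert; only exercised when a nonzero
        contact matrix is configured, which restricts this engine to small
        systems anyway.
        """
        if not self.state.interaction.has_nonspecific:
            return 0.0
        before = total_energy(self.state, check=False)
        self.apply(prop)  # prop.dE is still 0 here, so cached energy is safe
        after = total_energy(self.state, check=False)
        self.revert(prop)
        return after - before - self._bond_dE(prop.bond_changes)

    # -- application -----------------------------------------------------
    def _apply_geometry(self, prop: MoveProposal) -> None:
        s = self.state
        for b in prop.beads:
            s.occ[s.config.site_index(s.pos[b])] = -1
        for b, xyz in zip(prop.beads, prop.new_pos):
            s.pos[b] = xyz
        for b in prop.beads:
            s.occ[s.config.site_index(s.pos[b])] = b

    def _revert_geometry(self, prop: MoveProposal) -> None:
        s = self.state
        for b in prop.beads:
            s.occ[s.config.site_index(s.pos[b])] = -1
        for b, xyz in zip(prop.beads, prop.old_pos):
            s.pos[b] = xyz
        for b in prop.beads:
            s.occ[s.config.site_index(s.pos[b])] = b

    def apply(self, prop: MoveProposal) -> None:
        s = self.state
        self._apply_geometry(prop)
        for dom, old, new in prop.bond_changes:
            if old >= 0 and s.partner[old] == dom:
                s.partner[old] = -1
            s.partner[dom] = -1
        for dom, old, new in prop.bond_changes:
            if new >= 0:
                s.partner[dom] = new
                s.partner[new] = dom
        s.energy += prop.dE

    def revert(self, prop: MoveProposal) -> None:
        s = self.state
        self._revert_geometry(prop)
        for dom, old, new in prop.bond_changes:
            if new >= 0 and s.partner[new] == dom:
                s.partner[new] = -1
            s.partner[dom] = -1
        for dom, old, new in prop.bond_changes:
            if old >= 0:
                s.partner[dom] = old
                s.partner[old] = dom
        s.energy -= prop.dE

    # -- stepping --------------------------------------------------------
    def step(self, schedule: dict[str, float] | None = None) -> tuple[str, bool]:
        """One elementary attempt; returns (move_type, accepted)."""
        moves = self.applicable_moves()
        if schedule:
            moves = [m for m in moves if schedule.get(m, 0.0) > 0]
            weights = np.array([schedule[m] for m in moves], dtype=float)
        else:
            weights = np.ones(len(moves))
        weights = weights / weights.sum()
        mt = moves[int(self.rng.choice(len(moves), p=weights))]
        prop = self.propose_move(mt)
        if prop is None:
            return mt, False
        if accept_move(prop.dE, prop.w, self.rng):
            self.apply(prop)
            return mt, True
        return mt, False


@dataclass
class MCResult:
    """Trajectory summaries from :func:`run_mc`."""

    records: pd.DataFrame
    acceptance: pd.DataFrame
    means: dict[str, float]
    n_steps: int
    engine: str

    def mean(self, name: str) -> float:
        return self.means[name]


def _default_observers() -> dict[str, Callable[[SystemState], float]]:
    from .order_params import density_parameter, largest_cluster_fraction

    return {
        "energy": lambda s: s.energy,
        "phi_c": lambda s: largest_cluster_fraction(s)[0],
        "n_largest": lambda s: largest_cluster_fraction(s)[1].largest_size,
        "rho": lambda s: density_parameter(s),
        "rg": lambda s: density_parameter(s, return_rg=True)[1],
    }


def run_mc(
    state: SystemState,
    n_steps: int,
    seed: int = 0,
    schedule: dict[str, float] | None = None,
    observers: dict[str, Callable[[SystemState], float]] | None = None,
    stride: int | None = None,
    engine: str = "auto",
    average_fraction: float = 0.5,
) -> MCResult:
    """Evolve ``state`` in place for ``n_steps`` elementary attempts.

    One "step" is one attempted elementary move.  Observer outputs are
    recorded every ``stride`` steps; reported means are ensemble averages
    over the final ``average_fraction`` of the trajectory (last half by
    default).  Bit-reproducible for a fixed (seed, schedule, engine).

    ``engine`` is "python" (reference), "kernel" (numba) or "auto" (kernel
    when the interaction model allows it).
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    if stride is None:
        stride = max(1, n_steps // 200)
    observers = observers if observers is not None else _default_observers()

    if engine == "auto":
        engine = "python" if state.interaction.has_nonspecific else "kernel"
    if engine == "kernel" and state.interaction.has_nonspecific:
        raise ValueError("the compiled kernel supports the default (specific-only) model")

    rows = []
    acc = {m: [0, 0] for m in MOVE_TYPES}

    def record(step: int) -> None:
        row = {"step": step}
        for name, fn in observers.items():
            row[name] = fn(state)
        rows.append(row)

    record(0)
    if n_steps > 0 and engine == "python":
        eng = MoveEngine(state, np.random.default_rng(seed))
        for step in range(1, n_steps + 1):
            mt, ok = eng.step(schedule)
            acc[mt][0] += 1
            acc[mt][1] += ok
            if step % stride == 0 or step == n_steps:
                record(step)
    elif n_steps > 0:
        from ._kernel import run_kernel_chunk, seed_kernel, kernel_args, schedule_probs

        seed_kernel(seed)
        args = kernel_args(state)
        probs = schedule_probs(state, schedule)
        att = np.zeros(5, dtype=np.int64)
        accn = np.zeros(5, dtype=np.int64)
        done = 0
        while done < n_steps:
            chunk = min(stride, n_steps - done)
            state.energy = run_kernel_chunk(
                *args, probs, chunk, state.energy, att, accn
            )
            done += chunk
            record(done)
        for i, m in enumerate(MOVE_TYPES):
            acc[m][0] = int(att[i])
            acc[m][1] = int(accn[i])

    records = pd.DataFrame(rows)
    acceptance = pd.DataFrame(
        {
            "move": list(acc),
            "attempts": [v[0] for v in acc.values()],
            "accepted": [v[1] for v in acc.values()],
        }
    )
    acceptance["rate"] = np.where(
        acceptance["attempts"] > 0, acceptance["accepted"] / acceptance["attempts"].clip(lower=1), np.nan
    )
    cutoff = n_steps * (1.0 - average_fraction)
    tail = records[records["step"] >= cutoff] if len(records) else records
    means = {
        name: float(tail[name].mean()) for name in records.columns if name != "step"
    } if len(tail) else {}
    return MCResult(records, acceptance, means, n_steps, engine)
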