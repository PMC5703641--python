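"""Orchestration of the computational experiments.

Concentration sweeps titrate the domain concentration by resizing the box
at a fixed molecule count; affinity sweeps stack such sweeps into a
two-parameter phase diagram.  Each sweep point runs replicate Monte Carlo
trajectories, averages phi_c and rho over the final half of each, applies
the gel (phi_c > phi_cc) and density (rho > rho_cutoff) cutoffs, and flags
points whose split-half phi_c means disagree beyond two standard errors so
non-equilibrated points are never silently averaged.

Scale defaults: the production profile of record is 2.4e3 domains evolved
for 5e9 elementary moves per point; the package's default test profile uses
<= 240 domains and <= 1e8 steps, which preserves every qualitative feature
measured here (sigmoidal phi_c, the rho onset, cooperativity orderings)
with larger finite-size shifts.  docs/methods.md discusses the tradeoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .lattice import InteractionModel, LatticeConfig, MoleculeTopology, build_system
from .moves import run_mc
from .order_params import droplet_radius, phase_boundaries
from .percolation import gel_point_from_sweep


@dataclass(frozen=True)
class SpeciesSpec:
    """One chain species of a sweep: valence, linker and copy number."""

    kind: str
    valence: int
    linker_n: int = 0
    linker_e: int = 0
    count: int = 1
    label: str | None = None

    def topology(self) -> MoleculeTopology:
        return MoleculeTopology.uniform(
            self.label or f"poly{self.kind}{self.valence}",
            self.kind,
            self.valence,
            self.linker_n,
            self.linker_e,
        )


@dataclass(frozen=True)
class SweepSpec:
    """A concentration sweep at fixed molecule count.

    ``box_lengths`` must be sorted ascending (concentrations descending);
    ``affinity`` is the magnitude of the S-P contact energy in k_B*T.
    """

    species: tuple[SpeciesSpec, ...]
    affinity: float = 2.0
    box_lengths: tuple[int, ...] = (24, 28, 32, 38, 44)
    steps: int = 10**6
    replicates: int = 1
    seed: int = 0
    stride: int | None = None
    phi_cc: float = 0.17
    rho_cutoff: float = 1.08
    engine: str = "auto"
    schedule: dict | None = None

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("at least one species is required")
        if not self.box_lengths or tuple(sorted(self.box_lengths)) != tuple(self.box_lengths):
            raise ValueError("box_lengths must be non-empty and sorted ascending")
        if self.affinity < 0:
            raise ValueError("affinity is a magnitude; give it as a positive number")

    @property
    def n_domains(self) -> int:
        return sum(s.valence * s.count for s in self.species)

    @property
    def n_molecules(self) -> int:
        return sum(s.count for s in self.species)


def _point_seed(base: int, *indices: int) -> int:
    ss = np.random.SeedSequence([int(base) & 0x7FFFFFFF, *[int(i) for i in indices]])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def run_point(spec: SweepSpec, L: int, replicate: int = 0) -> dict:
    """One (box length, replicate) Monte Carlo run reduced to summary stats."""
    seed = _point_seed(spec.seed, L, replicate)
    state = build_system(
        LatticeConfig(L),
        [(s.topology(), s.count) for s in spec.species],
        seed=seed,
        interaction=InteractionModel(u_sp=-spec.affinity),
    )
    result = run_mc(
        state,
        spec.steps,
        seed=seed + 1,
        schedule=spec.schedule,
        stride=spec.stride,
        engine=spec.engine,
    )
    rec = result.records
    tail = rec[rec["step"] >= spec.steps / 2]
    q3 = tail[tail["step"] < 3 * spec.steps / 4]["phi_c"]
    q4 = tail[tail["step"] >= 3 * spec.steps / 4]["phi_c"]
    se = np.sqrt(
        q3.var(ddof=1) / max(len(q3), 1) + q4.var(ddof=1) / max(len(q4), 1)
    ) if len(q3) > 1 and len(q4) > 1 else np.nan
    equilibrated = bool(
        np.isnan(se) or se == 0 or abs(q3.mean() - q4.mean()) <= 2 * se
    )
    n_mol = spec.n_molecules
    return {
        "L": L,
        "replicate": replicate,
        "seed": seed,
        "affinity": spec.affinity,
        "conc_domains": spec.n_domains / L**3,
        "conc_polymers": n_mol / L**3,
        "phi_c": result.mean("phi_c"),
        "rho": result.mean("rho"),
        "rg": result.mean("rg"),
        "n_largest": result.mean("n_largest"),
        "energy": result.mean("energy"),
        "equilibrated": equilibrated,
        "steps": spec.steps,
    }


def sweep_concentration(spec: SweepSpec, refine: bool = False, max_refine: int = 8) -> pd.DataFrame:
    """Replicate-averaged sweep over box lengths (one row per box length).

    With ``refine=True`` the box-length grid is bisected around the phi_cc
    crossing until neighboring lengths differ by one lattice unit, mirroring
    the incremental refinement of the production protocol.
    """
    boxes = list(spec.box_lengths)
    rows = _run_boxes(spec, boxes)
    if refine:
        for _ in range(max_refine):
            cross = _crossing_gap(rows, spec.phi_cc)
            if cross is None:
                break
            lo, hi = cross
            if hi - lo <= 1:
                break
            mid = (lo + hi) // 2
            rows = pd.concat([rows, _run_boxes(spec, [mid])], ignore_index=True)
            rows = rows.sort_values("L", ignore_index=True)
    rows = rows.sort_values("conc_domains", ignore_index=True)
    rows["gel"] = rows["phi_c"] > spec.phi_cc
    rows["two_phase"] = rows["rho"] > spec.rho_cutoff
    return rows


def _run_boxes(spec: SweepSpec, boxes: list[int]) -> pd.DataFrame:
    rows = []
    for L in boxes:
        reps = [run_point(spec, L, r) for r in range(spec.replicates)]
        df = pd.DataFrame(reps)
        agg = df.drop(columns=["replicate", "seed"]).mean(numeric_only=True).to_dict()
        agg["L"] = L
        agg["equilibrated"] = bool(df["equilibrated"].all())
        agg["replicates"] = spec.replicates
        rows.append(agg)
    return pd.DataFrame(rows)


def _crossing_gap(rows: pd.DataFrame, phi_cc: float) -> tuple[int, int] | None:
    """Adjacent box lengths bracketing the gel crossing (L sorted ascending)."""
    srt = rows.sort_values("L", ignore_index=True)
    gels = srt["phi_c"] > phi_cc
    for i in range(len(srt) - 1):
        # concentration falls with L, so a gel->sol flip marks the crossing
        if gels[i] != gels[i + 1]:
            return int(srt["L"][i]), int(srt["L"][i + 1])
    return None


def gel_point_of_sweep(sweep: pd.DataFrame, phi_cc: float = 0.17) -> float | None:
    """c_g (domains/site) read from a sweep table's phi_c crossings."""
    pairs = sweep.sort_values("conc_domains")[["conc_domains", "phi_c"]].to_numpy()
    return gel_point_from_sweep([(c, p) for c, p in pairs], phi_cc)


@dataclass
class PhaseDiagram:
    """Assembled two-parameter (affinity x concentration) diagram."""

    points: pd.DataFrame
    per_affinity: pd.DataFrame
    critical_affinity: float | None
    warnings: list[str] = field(default_factory=list)


def map_phase_diagram(spec: SweepSpec, affinities: tuple[float, ...]) -> PhaseDiagram:
    """Stack concentration sweeps over an affinity grid into a phase diagram.

    Two-phase points are detected by rho > rho_cutoff; their coexistence
    concentrations come from the dense-sphere ansatz applied to the
    ensemble-mean largest-network size and radius of gyration.  The critical
    affinity is the lowest grid affinity with a detected two-phase interval.
    """
    if list(affinities) != sorted(affinities):
        raise ValueError("affinity grid must be sorted ascending")
    all_rows = []
    summaries = []
    warnings: list[str] = []
    n_mol = spec.n_molecules
    for aff in affinities:
        sw = sweep_concentration(replace(spec, affinity=float(aff)))
        sw["c_sl"] = np.nan
        sw["c_sh"] = np.nan
        for i, row in sw.iterrows():
            if not row["two_phase"]:
                continue
            n_net = int(round(row["n_largest"]))
            if n_net <= 0:
                continue
            try:
                sol = droplet_radius(n_mol, n_net, int(row["L"]), float(row["rg"]))
                c_sl, c_sh = phase_boundaries(n_mol, n_net, int(row["L"]), sol.r_n)
            except Exception as exc:  # no admissible root: report, keep NaN
                warnings.append(f"affinity {aff}, L={row['L']}: {exc}")
                continue
            sw.loc[i, "c_sl"] = c_sl
            sw.loc[i, "c_sh"] = c_sh
        gels = sw.sort_values("conc_domains")
        if not gels["gel"].to_numpy().all() and not (~gels["gel"].to_numpy()).all():
            flips = np.diff(gels["gel"].to_numpy().astype(int))
            if np.sum(flips != 0) > 1:
                warnings.append(
                    f"affinity {aff}: non-monotone gel flags across concentration"
                )
        two = sw[sw["two_phase"]]
        summaries.append(
            {
                "affinity": aff,
                "any_two_phase": bool(len(two)),
                "c_sl": float(two["c_sl"].min()) if len(two) else np.nan,
                "c_sh": float(two["c_sh"].max()) if len(two) else np.nan,
                "c_g": gel_point_of_sweep(sw, spec.phi_cc),
                "two_phase_width": float(len(two)),
            }
        )
        all_rows.append(sw)
    points = pd.concat(all_rows, ignore_index=True)
    per_aff = pd.DataFrame(summaries)
    crit = per_aff[per_aff["any_two_phase"]]["affinity"]
    widths = per_aff["two_phase_width"].to_numpy()
    if np.any(np.diff(widths) < 0):
        warnings.append("two-phase interval does not widen monotonically with affinity")
    return PhaseDiagram(
        points,
        per_aff,
        float(crit.min()) if len(crit) else None,
        warnings,
    )


def expand_box(state, new_L: int):
    """Re-embed a state in a larger box (dense-phase initialization mode).

    Used to seed production runs from a pre-equilibrated condensed state:
    equilibrate at high concentration in a small box, then expand the
    lattice boundary to reach the target concentration.  For molecules
    spanning the periodic boundary the first domain picks the image to
    keep; every other bead is re-wrapped by minimum image from it.  Bonds
    whose partners end up non-adjacent after re-imaging (molecules whose
    kept images separate) are cleared.
    """
    from .lattice import LatticeConfig, SystemState, face_adjacent, min_image, total_energy

    if new_L < state.L:
        raise ValueError("the box can only be expanded")
    new = SystemState(LatticeConfig(new_L), state.topologies, state.interaction)
    old_L = state.L
    for m in range(state.n_molecules):
        lo = int(state.mol_start[m])
        hi = lo + int(state.mol_len[m])
        ref = state.pos[lo]
        for b in range(lo, hi):
            new.pos[b] = (ref + min_image(state.pos[b] - ref, old_L)) % new_L
    new.occ[:] = -1
    for b in range(new.n_beads):
        site = new.site_of(b)
        if new.occ[site] >= 0:
            raise ValueError(
                "expansion produced overlapping molecule images; "
                "re-equilibrate the source state and retry"
            )
        new.occ[site] = b
    new.partner[:] = state.partner
    for b in range(new.n_beads):
        p = int(new.partner[b])
        if p > b and not face_adjacent(new.pos[b], new.pos[p], new_L):
            new.partner[b] = -1
            new.partner[p] = -1
    new.energy = total_energy(new)
    return new


# ---------------------------------------------------------------------------
# deterministic fixtures shared across the test suites


def generate_fixture(kind: str, seed: int = 0):
    """Miniature deterministic systems with known answers.

    ``tiny-enumerable``: one S and one P monomer on L = 2 (the enumeration
    oracle's system).  ``dense-ball``: 900 of 1000 single-bead molecules
    uniform in a radius-10 ball at the center of an L = 100 box, the rest
    uniform outside (the droplet-ansatz construction).  ``uniform-gas``:
    non-interacting monomers dispersed at random.  ``bound-chain``: ten
    molecules with one bound chain of three (phi_c = 0.3).
    """
    rng = np.random.default_rng(seed)
    if kind == "tiny-enumerable":
        s_mono = MoleculeTopology.uniform("S1", "S", 1)
        p_mono = MoleculeTopology.uniform("P1", "P", 1)
        return build_system(LatticeConfig(2), [(s_mono, 1), (p_mono, 1)], seed=rng)

    if kind == "dense-ball":
        # low-discrepancy filling so the construction realizes the
        # two-uniform-density ansatz with far less noise than iid sampling
        from scipy.stats import qmc

        n_total, n_network, L, radius = 1000, 900, 100, 10.0
        center = np.array([L / 2, L / 2, L / 2])
        sob = qmc.Sobol(3, scramble=False)
        pts = sob.random(8192) * 2 * radius - radius
        inside = pts[(pts**2).sum(axis=1) <= radius**2]
        dense = center + inside[:n_network]
        sob2 = qmc.Sobol(3, scramble=False)
        pts2 = sob2.random(512) * L
        outside = pts2[((pts2 - center) ** 2).sum(axis=1) > radius**2]
        dilute = outside[: n_total - n_network]
        coords = np.concatenate([dense, dilute])
        return {
            "coords": coords,
            "n_total": n_total,
            "n_network": n_network,
            "L": L,
            "radius": radius,
        }

    if kind == "uniform-gas":
        s_mono = MoleculeTopology.uniform("S1", "S", 1)
        return build_system(LatticeConfig(24), [(s_mono, 400)], seed=rng)

    if kind == "bound-chain":
        from .lattice import SystemState, total_energy

        a = MoleculeTopology.uniform("A2", "S", 2, linker_n=2)
        b = MoleculeTopology.uniform("B2", "P", 2, linker_n=2)
        state = SystemState(LatticeConfig(16), [a] * 5 + [b] * 5)
        # chain molecules 0 (S), 5 (P), 1 (S) adjacent along x; the other
        # seven parked on a distant grid, everyone's tether satisfied
        coords = {
            0: (8, 8, 8), 1: (8, 10, 8),       # mol 0
            2: (11, 8, 8), 3: (11, 10, 8),     # mol 1
            10: (9, 8, 8), 11: (10, 8, 8),     # mol 5
        }
        parked = [m for m in range(10) if m not in (0, 1, 5)]
        for i, m in enumerate(parked):
            base = int(state.mol_start[m])
            coords[base] = (2 * i, 0, 0)
            coords[base + 1] = (2 * i, 1, 0)
        for bead, xyz in coords.items():
            state.pos[bead] = xyz
        state.occ[:] = -1
        for bead in range(state.n_beads):
            state.occ[state.site_of(bead)] = bead
        state.partner[0], state.partner[10] = 10, 0
        state.partner[2], state.partner[11] = 11, 2
        state.energy = total_energy(state)
        return state

    raise ValueError(f"unknown fixture kind {kind!r}")
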