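"""Plain-text configuration and snapshot formats.

Configurations are YAML; snapshots are whitespace-separated tables with one
row per bead (molecule id, bead slot, kind letter, x, y, z, bound partner
bead id or -1) preceded by a two-line header carrying the box side and the
step number.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .lattice import (
    KIND_LETTERS,
    InteractionModel,
    LatticeConfig,
    MoleculeTopology,
    SystemState,
    build_system,
    validate_state,
)

SNAPSHOT_COLUMNS = ["mol", "slot", "kind", "x", "y", "z", "partner"]


def write_snapshot(state: SystemState, path: str | Path, step: int = 0) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# L {state.L}\n# step {step}\n")
        fh.write("# " + " ".join(SNAPSHOT_COLUMNS) + "\n")
        for m in range(state.n_molecules):
            base = int(state.mol_start[m])
            for slot in range(int(state.mol_len[m])):
                b = base + slot
                x, y, z = (int(v) for v in state.pos[b])
                fh.write(
                    f"{m} {slot} {KIND_LETTERS[state.kind[b]]} "
                    f"{x} {y} {z} {int(state.partner[b])}\n"
                )


def read_snapshot(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Snapshot table plus its header metadata ({'L': ..., 'step': ...})."""
    path = Path(path)
    meta = {}
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            parts = line[1:].split()
            if len(parts) == 2 and parts[0] in ("L", "step"):
                meta[parts[0]] = int(parts[1])
    df = pd.read_csv(
        path, sep=r"\s+", comment="#", names=SNAPSHOT_COLUMNS, header=None
    )
    if "L" not in meta:
        raise ValueError(f"snapshot {path} is missing the box-side header")
    meta.setdefault("step", 0)
    return df, meta


def load_state_from_snapshot(
    path: str | Path,
    topologies: list[MoleculeTopology],
    interaction: InteractionModel | None = None,
) -> SystemState:
    """Rebuild a full system state from a snapshot and its topologies."""
    df, meta = read_snapshot(path)
    state = SystemState(LatticeConfig(meta["L"]), topologies, interaction)
    if len(df) != state.n_beads:
        raise ValueError("snapshot bead count does not match the topologies")
    order = df.sort_values(["mol", "slot"]).reset_index(drop=True)
    state.pos[:] = order[["x", "y", "z"]].to_numpy(dtype=np.int64)
    state.partner[:] = order["partner"].to_numpy(dtype=np.int64)
    state.occ[:] = -1
    for b in range(state.n_beads):
        state.occ[state.site_of(b)] = b
    from .lattice import total_energy

    state.energy = total_energy(state)
    problems = validate_state(state)
    if problems:
        raise ValueError(f"snapshot state is invalid: {problems[:3]}")
    return state


# ---------------------------------------------------------------------------
# simulation configs


def topology_from_dict(d: dict) -> tuple[MoleculeTopology, int]:
    topo = MoleculeTopology.uniform(
        label=d.get("label", d["kind"]),
        domain_kind=d["kind"],
        valence=int(d["valence"]),
        linker_n=int(d.get("linker_n", 0)),
        linker_e=int(d.get("linker_e", 0)),
    )
    return topo, int(d.get("count", 1))


def load_config(path: str | Path) -> dict:
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("configuration must be a mapping")
    return cfg


def build_from_config(cfg: dict) -> tuple[SystemState, dict]:
    """System state plus run parameters from a parsed configuration.

    Recognized keys: ``box`` (L), ``species`` (list of {label, kind, valence,
    linker_n, linker_e, count}), ``affinity`` (k_B*T, positive; or ``u_sp``
    directly), ``steps``, ``stride``, ``seed``.
    """
    L = int(cfg["box"])
    species = [topology_from_dict(d) for d in cfg["species"]]
    if "u_sp" in cfg:
        u_sp = float(cfg["u_sp"])
    else:
        u_sp = -abs(float(cfg.get("affinity", 2.0)))
    seed = int(cfg.get("seed", 0))
    state = build_system(
        LatticeConfig(L), species, seed=seed, interaction=InteractionModel(u_sp=u_sp)
    )
    run = {
        "steps": int(cfg.get("steps", 10**5)),
        "stride": cfg.get("stride"),
        "seed": seed,
    }
    return state, run
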