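"""Sequence-level characterization of disordered linkers.

Charge metrics (FCR, NCPR), the Delta statistic that scores a linker's
inter-residue distance profile against a Flory-random-coil reference, the
Delta-regime classification into effective-solvation-volume classes, and the
residue <-> lattice-site length mapping (one lattice site spans about seven
linker residues).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
POSITIVE_RESIDUES = frozenset("RK")
NEGATIVE_RESIDUES = frozenset("DE")  # histidine is treated as neutral

RESIDUES_PER_SITE = 7


@dataclass(frozen=True)
class ChargeMetrics:
    """Fraction of charged residues and net charge per residue."""

    fcr: float
    ncpr: float
    f_plus: float
    f_minus: float
    length: int


def charge_metrics(sequence: str, on_unknown: str = "error") -> ChargeMetrics:
    """FCR = f+ + f- and NCPR = f+ - f- of an amino-acid sequence.

    f+ counts Arg and Lys, f- counts Asp and Glu, each normalized by
    sequence length.  ``on_unknown`` is "error" (default) or "skip"
    (drop unrecognized letters from both the counts and the length,
    with a warning).
    """
    seq = sequence.strip().upper()
    if not seq:
        raise ValueError("empty sequence")
    unknown = [c for c in seq if c not in AMINO_ACIDS]
    if unknown:
        if on_unknown == "error":
            raise ValueError(f"unknown residue letters: {sorted(set(unknown))}")
        if on_unknown != "skip":
            raise ValueError("on_unknown must be 'error' or 'skip'")
        warnings.warn(
            f"skipping {len(unknown)} unrecognized residues", stacklevel=2
        )
        seq = "".join(c for c in seq if c in AMINO_ACIDS)
        if not seq:
            raise ValueError("no recognized residues in sequence")
    n = len(seq)
    n_plus = sum(seq.count(c) for c in POSITIVE_RESIDUES)
    n_minus = sum(seq.count(c) for c in NEGATIVE_RESIDUES)
    f_plus, f_minus = n_plus / n, n_minus / n
    return ChargeMetrics(f_plus + f_minus, f_plus - f_minus, f_plus, f_minus, n)


@dataclass
class DistanceProfile:
    """Mean spatial separation <R_k> versus sequence separation k.

    ``n_residues`` is the chain length N; k runs over 1..N-1 for a full
    profile (any increasing sub-grid is accepted, but Delta requires the
    profile and reference to share one grid).
    """

    k: np.ndarray
    r: np.ndarray
    n_residues: int

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=int)
        self.r = np.asarray(self.r, dtype=float)
        if self.k.shape != self.r.shape or self.k.ndim != 1:
            raise ValueError("k and <R_k> must be matching 1-D arrays")
        if len(self.k) == 0:
            raise ValueError("empty profile")
        if np.any(np.diff(self.k) <= 0):
            raise ValueError("k must be strictly increasing")
        if self.k[0] < 1 or self.k[-1] > self.n_residues - 1:
            raise ValueError("k must lie within 1..N-1")
        if np.any(self.r <= 0):
            raise ValueError("mean separations must be positive")

    @classmethod
    def from_file(cls, path: str | Path, n_residues: int | None = None) -> "DistanceProfile":
        """Two-column plain text: k and <R_k> (comments with '#')."""
        data = np.loadtxt(path, ndmin=2)
        if data.shape[1] < 2:
            raise ValueError("profile file needs two columns: k, <R_k>")
        k = data[:, 0].astype(int)
        n = n_residues if n_residues is not None else int(k[-1]) + 1
        return cls(k, data[:, 1], n)

    def to_file(self, path: str | Path) -> None:
        np.savetxt(path, np.column_stack([self.k, self.r]), fmt=["%d", "%.8g"],
                   header=f"N={self.n_residues}  columns: k <R_k>")


def frc_reference_profile(n_residues: int, prefactor: float = 1.0) -> DistanceProfile:
    """Synthetic ideal-chain reference profile, <R_k> = prefactor * sqrt(k).

    Testing placeholder only: real Flory-random-coil references come from
    chain-ensemble simulations and are supplied as input files.
    """
    k = np.arange(1, n_residues)
    return DistanceProfile(k, prefactor * np.sqrt(k), n_residues)


def delta_parameter(
    profile: DistanceProfile,
    reference: DistanceProfile,
    normalization: str = "residues",
) -> float:
    """Mean signed relative deviation of a profile from its FRC reference.

    Delta = (1/N) * sum_k (<R_k> - <R_k^FRC>) / <R_k^FRC>, summing over all
    shared sequence separations.  ``normalization`` divides by the residue
    count N (default) or by the number of summed separations
    ("separations"); compact chains give Delta < 0, expanded chains > 0.
    """
    if not np.array_equal(profile.k, reference.k):
        raise ValueError("profile and reference are on different k grids")
    if profile.n_residues != reference.n_residues:
        raise ValueError("profile and reference chain lengths differ")
    terms = (profile.r - reference.r) / reference.r
    if normalization == "residues":
        denom = profile.n_residues
    elif normalization == "separations":
        denom = len(profile.k)
    else:
        raise ValueError("normalization must be 'residues' or 'separations'")
    return float(terms.sum() / denom)


REGIME_BOUNDARY = 0.1


def classify_linker_regime(delta: float) -> str:
    """Effective-solvation-volume regime from Delta.

    Delta < -0.1 -> "negative_ves" (self-attracting, compact linkers);
    -0.1 <= Delta <= 0.1 -> "near_zero_ves" (FRC-like);
    Delta > 0.1 -> "positive_ves" (self-avoiding, expanded linkers).
    The middle interval is closed on both sides.
    """
    if not np.isfinite(delta):
        raise ValueError("Delta must be finite")
    if delta < -REGIME_BOUNDARY:
        return "negative_ves"
    if delta <= REGIME_BOUNDARY:
        return "near_zero_ves"
    return "positive_ves"


def residues_to_lattice(n_residues: int) -> int:
    """Linker length in lattice sites, n = round(N / 7), at least 1."""
    if n_residues < 1:
        raise ValueError("need at least one residue")
    return max(1, round(n_residues / RESIDUES_PER_SITE))


def lattice_to_residues(n_sites: int) -> int:
    """Approximate residue count of an n-site linker, N = 7 n."""
    if n_sites < 1:
        raise ValueError("need at least one lattice site")
    return RESIDUES_PER_SITE * n_sites


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def analyze_sequences(
    fasta_path: str | Path,
    profile_path: str | Path | None = None,
    reference_path: str | Path | None = None,
    on_unknown: str = "error",
    normalization: str = "residues",
) -> pd.DataFrame:
    """Per-sequence FCR/NCPR (and Delta + regime when profiles are given)."""
    rows = []
    delta = regime = None
    if profile_path is not None and reference_path is not None:
        profile = DistanceProfile.from_file(profile_path)
        reference = DistanceProfile.from_file(reference_path)
        delta = delta_parameter(profile, reference, normalization)
        regime = classify_linker_regime(delta)
    for name, seq in read_fasta(fasta_path):
        cm = charge_metrics(seq, on_unknown)
        rows.append(
            {
                "id": name,
                "length": cm.length,
                "fcr": cm.fcr,
                "ncpr": cm.ncpr,
                "lattice_sites": residues_to_lattice(cm.length),
                "delta": delta,
                "regime": regime,
                "delta_normalization": normalization if delta is not None else None,
            }
        )
    return pd.DataFrame(rows)
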