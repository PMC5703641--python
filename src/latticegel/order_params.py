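"""Order parameters for gelation and phase separation, and phase boundaries.

Gelation is tracked through phi_c, the fraction of molecules in the single
largest bound cluster of the molecule graph (nodes = molecules, edge =
at least one intermolecular bound S-P pair).  Phase separation is tracked
through rho = R_lattice / R_g^proteins, the ratio of the radius of gyration
a uniformly dispersed system would have to the actual radius of gyration of
all protein beads.  rho ~ 1 means dispersed; rho >> 1 means condensed; the
operational two-phase cutoff is rho > 1.08 and the operational gel cutoff is
phi_c > 0.17 (the percolation value calibrated by the random-network model).

Coexistence concentrations are extracted by assuming the dense phase is a
uniform-density sphere of radius r_N and the dilute phase fills the rest of
the box uniformly; r_N solves a quintic in r derived from requiring the
two-density ansatz to reproduce the measured radius of gyration (see
docs/methods.md for the derivation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .lattice import LatticeError, SystemState


class DropletError(LatticeError):
    """No admissible droplet radius."""


# ---------------------------------------------------------------------------
# binding network and phi_c


class _DSU:
    """Union-find over molecule ids."""

    def __init__(self, n: int):
        self.parent = list(range(n))
        self.size = [1] * n

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]


@dataclass
class BindingNetwork:
    """Molecules as nodes; intermolecular bound domain pairs as edges."""

    n_molecules: int
    edges: frozenset
    component_sizes: tuple[int, ...]

    @property
    def largest_size(self) -> int:
        return max(self.component_sizes) if self.component_sizes else 0

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_molecules))
        g.add_edges_from(self.edges)
        return g


def binding_network_from_arrays(mol: np.ndarray, partner: np.ndarray, n_molecules: int) -> BindingNetwork:
    edges = set()
    dsu = _DSU(n_molecules)
    for i in np.flatnonzero(partner >= 0):
        j = int(partner[i])
        if i < j:
            mi, mj = int(mol[i]), int(mol[j])
            if mi != mj:
                edges.add((min(mi, mj), max(mi, mj)))
                dsu.union(mi, mj)
    comp: dict[int, int] = {}
    for m in range(n_molecules):
        r = dsu.find(m)
        comp[r] = comp.get(r, 0) + 1
    return BindingNetwork(n_molecules, frozenset(edges), tuple(sorted(comp.values(), reverse=True)))


def largest_cluster_fraction(state: SystemState) -> tuple[float, BindingNetwork]:
    """phi_c = |largest connected component| / N_T and the network itself."""
    net = binding_network_from_arrays(state.mol, state.partner, state.n_molecules)
    if state.n_molecules == 0:
        return 0.0, net
    return net.largest_size / state.n_molecules, net


# ---------------------------------------------------------------------------
# density parameter rho


def lattice_radius(L: int, reference: str = "cube_discrete") -> float:
    """Radius of gyration of a uniform dispersion over the box.

    ``cube_discrete``: exact over the L^3 lattice sites (default);
    ``cube``: continuum solid cube, L/2;
    ``sphere``: sphere of equal volume to the box.
    """
    if reference == "cube_discrete":
        return math.sqrt(3 * (L**2 - 1) / 12.0)
    if reference == "cube":
        return L / 2.0
    if reference == "sphere":
        r = (3.0 / (4.0 * math.pi)) ** (1.0 / 3.0) * L
        return math.sqrt(3.0 / 5.0) * r
    raise ValueError(f"unknown reference {reference!r}")


def periodic_center_of_mass(pos: np.ndarray, L: int) -> np.ndarray:
    """Center of mass under periodic boundaries via the circular mean.

    Each axis is embedded on a circle so a droplet spanning the boundary is
    measured at its true center rather than smeared across the box.
    """
    theta = pos * (2.0 * np.pi / L)
    mean_cos = np.cos(theta).mean(axis=0)
    mean_sin = np.sin(theta).mean(axis=0)
    ang = np.arctan2(mean_sin, mean_cos)
    return (ang * L / (2.0 * np.pi)) % L


def radius_of_gyration(pos: np.ndarray, L: int) -> float:
    """R_g of beads under the minimum-image convention about the circular COM."""
    pos = np.asarray(pos, dtype=float)
    if len(pos) == 0:
        raise ValueError("radius of gyration of an empty bead set")
    com = periodic_center_of_mass(pos, L)
    d = (pos - com + L / 2.0) % L - L / 2.0
    return float(np.sqrt((d**2).sum(axis=1).mean()))


def density_parameter(
    state: SystemState,
    reference: str = "cube_discrete",
    return_rg: bool = False,
):
    """rho = R_lattice / R_g over all domain and explicit-linker beads."""
    if state.n_beads < 2:
        raise ValueError("rho is undefined for fewer than two beads")
    rg = radius_of_gyration(state.pos, state.L)
    if rg == 0.0:
        raise ValueError("rho is undefined when all beads coincide (R_g = 0)")
    rho = lattice_radius(state.L, reference) / rg
    return (rho, rg) if return_rg else rho


# ---------------------------------------------------------------------------
# droplet radius and phase boundaries


@dataclass
class DropletSolution:
    r_n: float | None
    all_real_roots: tuple[float, ...]
    residual: float


def _droplet_poly(n_total: int, n_network: int, L: int, r_g: float) -> np.ndarray:
    """Quintic for the dense-sphere radius from the two-density ansatz.

    With N_N molecules uniform in a sphere of radius r and N_T - N_N uniform
    over the rest of the box, the system R_g^2 about the common center is
    N_T R_g^2 = N_N (3/5) r^2
             + (N_T - N_N) [L^5/4 - (4/5) pi r^5] / [L^3 - (4/3) pi r^3].
    Clearing the denominator gives
    -(4/5) pi N_T r^5 + (4/3) pi N_T R_g^2 r^3 + (3/5) N_N L^3 r^2
      + (N_T - N_N) L^5 / 4 - N_T R_g^2 L^3 = 0.
    """
    nt, nn = float(n_total), float(n_network)
    return np.array(
        [
            -(4.0 / 5.0) * math.pi * nt,
            0.0,
            (4.0 / 3.0) * math.pi * nt * r_g**2,
            (3.0 / 5.0) * nn * L**3,
            0.0,
            (nt - nn) * L**5 / 4.0 - nt * r_g**2 * L**3,
        ]
    )


def droplet_radius(n_total: int, n_network: int, L: int, r_g: float) -> DropletSolution:
    """Radius of the dense (polymer-rich) sphere.

    Returns the real root of the ansatz quintic that fits inside the box
    (droplet volume below the box volume).  ``n_network = 0`` returns a
    no-droplet sentinel (``r_n = None``).  Raises :class:`DropletError`
    when no admissible root exists, listing every real root.
    """
    if not 0 <= n_network <= n_total:
        raise ValueError("need 0 <= N_N <= N_T")
    if r_g <= 0 or L <= 0:
        raise ValueError("R_g and L must be positive")
    if n_network == 0:
        return DropletSolution(None, (), 0.0)
    coeffs = _droplet_poly(n_total, n_network, L, r_g)
    roots = np.roots(coeffs)
    scale = np.max(np.abs(coeffs))
    real = sorted(
        float(r.real) for r in roots if abs(r.imag) <= 1e-8 * max(1.0, abs(r))
    )
    r_max = (3.0 * L**3 / (4.0 * math.pi)) ** (1.0 / 3.0)
    admissible = [r for r in real if 0.0 < r < r_max]
    if not admissible:
        raise DropletError(
            f"no droplet radius in (0, {r_max:.3f}); real roots: {real}"
        )
    if len(admissible) > 1:
        # prefer roots whose dense phase is actually denser than the dilute one
        def dense_excess(r: float) -> float:
            c_sh = 3.0 * n_network / (4.0 * math.pi * r**3)
            c_sl = (n_total - n_network) / (L**3 - (4.0 / 3.0) * math.pi * r**3)
            return c_sh - c_sl

        physical = [r for r in admissible if dense_excess(r) > 0]
        admissible = physical or admissible
    r_n = admissible[-1] if len(admissible) > 1 else admissible[0]
    residual = abs(float(np.polyval(coeffs, r_n))) / (scale * max(1.0, r_n) ** 5)
    return DropletSolution(r_n, tuple(real), residual)


def phase_boundaries(
    n_total: int, n_network: int, L: int, r_n: float | None
) -> tuple[float, float | None]:
    """Coexisting concentrations (molecules per site) of the two phases.

    c_sh = 3 N_N / (4 pi r_N^3) inside the dense sphere;
    c_sl = (N_T - N_N) / (L^3 - (4/3) pi r_N^3) across the remainder.
    With no droplet (``r_n`` None) the single phase has c_sl = N_T / L^3 and
    c_sh is None.
    """
    if r_n is None or n_network == 0:
        return n_total / L**3, None
    v_drop = (4.0 / 3.0) * math.pi * r_n**3
    if v_drop >= L**3:
        raise DropletError("droplet volume exceeds the box")
    c_sh = 3.0 * n_network / (4.0 * math.pi * r_n**3)
    c_sl = (n_total - n_network) / (L**3 - v_drop)
    return c_sl, c_sh


# ---------------------------------------------------------------------------
# regime classification and bundled metrics


@dataclass
class PhaseMetrics:
    """Per-configuration (or ensemble-mean) order parameters."""

    phi_c: float
    rho: float
    n_total: int
    n_network: int
    r_g: float
    r_n: float | None = None
    c_sl: float | None = None
    c_sh: float | None = None
    gel: bool | None = None
    two_phase: bool | None = None
    phi_cc: float = 0.17
    rho_cutoff: float = 1.08


def classify_regime(
    phi_c: float, rho: float, phi_cc: float = 0.17, rho_cutoff: float = 1.08
) -> tuple[str, str]:
    """("gel"|"sol", "two-phase"|"one-phase") under the configured cutoffs."""
    if not (math.isfinite(phi_c) and math.isfinite(rho)):
        raise ValueError("phi_c and rho must be finite")
    gel = "gel" if phi_c > phi_cc else "sol"
    phase = "two-phase" if rho > rho_cutoff else "one-phase"
    return gel, phase


def phase_metrics(
    state: SystemState, phi_cc: float = 0.17, rho_cutoff: float = 1.08
) -> PhaseMetrics:
    """Assemble every order parameter for one configuration."""
    phi_c, net = largest_cluster_fraction(state)
    rho, rg = density_parameter(state, return_rg=True)
    n_n = net.largest_size
    gel, phase = classify_regime(phi_c, rho, phi_cc, rho_cutoff)
    metrics = PhaseMetrics(
        phi_c=phi_c,
        rho=rho,
        n_total=state.n_molecules,
        n_network=n_n,
        r_g=rg,
        gel=(gel == "gel"),
        two_phase=(phase == "two-phase"),
        phi_cc=phi_cc,
        rho_cutoff=rho_cutoff,
    )
    if metrics.two_phase and n_n > 0:
        sol = droplet_radius(state.n_molecules, n_n, state.L, rg)
        metrics.r_n = sol.r_n
        metrics.c_sl, metrics.c_sh = phase_boundaries(
            state.n_molecules, n_n, state.L, sol.r_n
        )
    return metrics
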