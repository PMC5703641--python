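"""Flory-Stockmayer gelation analytics and the random-network calibration.

For a two-component system of chains carrying V_a domains of type a and
V_b domains of type b, a pre-formed network grows on average by
epsilon = (V_a - 1) x_a (V_b - 1) x_b new chains per added chain, where
x_a, x_b are bound fractions set by mass action,

    K_d = ([a] - [ab]) ([b] - [ab]) / [ab].

epsilon >= 1 marks the percolation (gel) threshold.  The critical bound
fraction of a symmetric system is x_c = 1/(V - 1).  The module also builds
the random bipartite binding networks used to translate the analytic
threshold into a critical largest-cluster fraction phi_cc (~= 0.17,
insensitive to valence), and forms the cooperativity ratio
c* = c_g,sim / c_g,FS that classifies global cooperativity.

Concentration units are lattice units throughout: domains per site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar


@dataclass
class BindingEquilibrium:
    """1:1 binding equilibrium between domain pools a and b."""

    a_total: float
    b_total: float
    kd: float
    ab: float

    @property
    def x_a(self) -> float:
        return self.ab / self.a_total if self.a_total > 0 else 0.0

    @property
    def x_b(self) -> float:
        return self.ab / self.b_total if self.b_total > 0 else 0.0

    def residual(self) -> float:
        """K_d minus the mass-action quotient at the solved [ab]."""
        if self.ab == 0.0:
            return 0.0
        return self.kd - (self.a_total - self.ab) * (self.b_total - self.ab) / self.ab


def solve_binding(a_total: float, b_total: float, kd: float) -> BindingEquilibrium:
    """Physical root of the binding quadratic ([ab] <= min([a], [b]))."""
    if a_total < 0 or b_total < 0:
        raise ValueError("concentrations must be nonnegative")
    if kd <= 0:
        raise ValueError("K_d must be positive")
    s = a_total + b_total + kd
    disc = s * s - 4.0 * a_total * b_total
    ab = 0.5 * (s - math.sqrt(max(disc, 0.0)))
    ab = min(ab, a_total, b_total)
    return BindingEquilibrium(a_total, b_total, kd, max(ab, 0.0))


def fs_epsilon(v_a: int, v_b: int, x_a: float, x_b: float) -> float:
    """Network growth factor epsilon = (V_a - 1) x_a (V_b - 1) x_b."""
    if v_a < 1 or v_b < 1:
        raise ValueError("valences must be >= 1")
    if not (0 <= x_a <= 1 and 0 <= x_b <= 1):
        raise ValueError("bound fractions must lie in [0, 1]")
    return (v_a - 1) * x_a * (v_b - 1) * x_b


def _epsilon_at(a: float, b: float, kd: float, v_a: int, v_b: int) -> float:
    eq = solve_binding(a, b, kd)
    return fs_epsilon(v_a, v_b, eq.x_a, eq.x_b)


def fs_gel_point(
    v_a: int,
    v_b: int,
    kd: float,
    b_total: float | None = None,
) -> float | None:
    """Critical concentration [a]_c (domains/site) where epsilon = 1.

    With ``b_total`` given, solves epsilon([a]) = 1 numerically for the gel
    onset (the lower crossing).  Without it, uses the equal-concentration
    ([a] = [b]) closed form

        x_c = 1/sqrt(lambda),  [a]_c = K_d sqrt(lambda) / (sqrt(lambda)-1)^2,

    with lambda = (V_a - 1)(V_b - 1); the closed form agrees with the
    numeric root-find to 1e-8 relative (enforced by tests).  Returns None
    when lambda <= 1 (gelation impossible).
    """
    lam = (v_a - 1) * (v_b - 1)
    if lam <= 1:
        return None
    if kd <= 0:
        raise ValueError("K_d must be positive")
    if b_total is None:
        sq = math.sqrt(lam)
        return kd * sq / (sq - 1.0) ** 2

    # epsilon([a]) rises from 0, peaks, and decays (x_b -> 1 but x_a -> 0);
    # the gel onset is the lower crossing of 1.
    hi = max(10.0 * (b_total + kd), 1.0)
    res = minimize_scalar(
        lambda a: -_epsilon_at(a, b_total, kd, v_a, v_b),
        bounds=(1e-12, hi),
        method="bounded",
    )
    a_peak = float(res.x)
    if _epsilon_at(a_peak, b_total, kd, v_a, v_b) < 1.0:
        return None
    return float(
        brentq(
            lambda a: _epsilon_at(a, b_total, kd, v_a, v_b) - 1.0,
            1e-14,
            a_peak,
            xtol=1e-14,
            rtol=1e-12,
        )
    )


def lattice_kd(u_sp: float, L: int | None = None) -> float:
    """Dissociation constant (domains/site) matched to a lattice affinity.

    From the two-particle partition function on the periodic cubic lattice
    (translation-reduced form of the exact-enumeration oracle): one particle
    fixed, the other has Omega - 1 placements of which A are adjacent
    (A = 6, or 3 when L = 2), and each adjacent placement adds a bound state
    of weight exp(-u).  Then P_bound = A e^{-u} / (Omega - 1 + A e^{-u}) and

        K_d = (1 - P)^2 / (Omega P) --> e^{u} / 6  as  Omega -> infinity.

    ``L=None`` returns the infinite-dilution limit.
    """
    if L is None:
        return math.exp(u_sp) / 6.0
    omega = L**3
    adj = 3 if L == 2 else 6
    z = (omega - 1) + adj * math.exp(-u_sp)
    p = adj * math.exp(-u_sp) / z
    return (1.0 - p) ** 2 / (omega * p)


# ---------------------------------------------------------------------------
# random bipartite network model


@dataclass
class PhiCSample:
    """Replicated largest-cluster fractions of the random network model."""

    mean: float
    values: np.ndarray

    @property
    def se(self) -> float:
        n = len(self.values)
        return float(self.values.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")


def random_network_phi_c(
    v_a: int,
    v_b: int,
    n_domains: int,
    x: float,
    seed: int | np.random.Generator = 0,
    replicates: int = 1,
) -> PhiCSample:
    """Largest-cluster molecule fraction of random bipartite binding networks.

    ``n_domains`` total domains are split stoichiometrically: n/2 of type a
    grouped into molecules of valence ``v_a`` and n/2 of type b into
    molecules of valence ``v_b``.  Each a-domain binds with probability
    ``x`` to a uniformly chosen b-domain that has no partner yet; clusters
    are measured on the molecule graph.
    """
    if not 0 <= x <= 1:
        raise ValueError("bound fraction x must lie in [0, 1]")
    half = n_domains // 2
    n_mol_a, n_mol_b = half // v_a, half // v_b
    if n_mol_a < 1 or n_mol_b < 1:
        raise ValueError(
            f"{n_domains} domains cannot form even one molecule per side at "
            f"valences {v_a} and {v_b}"
        )
    # valences that do not divide n/2 exactly use the largest whole-molecule
    # count (e.g. 2400 domains at V=7 -> 171 molecules per side)
    half_a, half_b = n_mol_a * v_a, n_mol_b * v_b
    from .order_params import _DSU

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_mol = n_mol_a + n_mol_b
    vals = np.empty(replicates)
    for rep in range(replicates):
        dsu = _DSU(n_mol)
        free_b = list(range(half_b))
        draws = rng.random(half_a)
        for a_dom in range(half_a):
            if draws[a_dom] >= x or not free_b:
                continue
            k = int(rng.integers(len(free_b)))
            b_dom = free_b[k]
            free_b[k] = free_b[-1]
            free_b.pop()
            dsu.union(a_dom // v_a, n_mol_a + b_dom // v_b)
        largest = max(dsu.size[dsu.find(m)] for m in range(n_mol))
        vals[rep] = largest / n_mol
    return PhiCSample(float(vals.mean()), vals)


@dataclass
class PhiCCEstimate:
    """Critical largest-cluster fraction per valence and overall."""

    per_valence: dict[int, float]
    mean: float
    curves: dict[int, tuple[np.ndarray, np.ndarray]]


def estimate_phi_cc(
    valences=(3, 5, 7),
    n_domains: int = 2400,
    replicates: int = 50,
    seed: int = 0,
    x_grid: np.ndarray | None = None,
) -> PhiCCEstimate:
    """phi_cc: the phi_c(x) sigmoid read off at the critical bound fraction.

    For each symmetric valence V the sigmoid is evaluated on a grid of bound
    fractions and interpolated at x_c = 1/(V - 1); the calibrated
    value is ~0.17 irrespective of valence.
    """
    rng = np.random.default_rng(seed)
    per: dict[int, float] = {}
    curves: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for v in valences:
        x_c = 1.0 / (v - 1)
        if x_grid is None:
            lo, hi = max(0.02, x_c - 0.12), min(0.98, x_c + 0.12)
            grid = np.linspace(lo, hi, 9)
        else:
            grid = np.asarray(x_grid, dtype=float)
        if not (grid.min() <= x_c <= grid.max()):
            raise ValueError("x grid does not bracket the critical bound fraction")
        phis = np.array(
            [
                random_network_phi_c(v, v, n_domains, x, rng, replicates).mean
                for x in grid
            ]
        )
        per[v] = float(np.interp(x_c, grid, phis))
        curves[v] = (grid, phis)
    return PhiCCEstimate(per, float(np.mean(list(per.values()))), curves)


# ---------------------------------------------------------------------------
# gel points from sweeps and the cooperativity ratio


def gel_point_from_sweep(sweep, phi_cc: float = 0.17) -> float | None:
    """Lowest concentration in an ordered sweep with phi_c > phi_cc.

    ``sweep`` is an iterable of (concentration, phi_c) pairs sorted by
    concentration; returns None when the threshold is never crossed.
    """
    prev = -math.inf
    for conc, phi in sweep:
        if conc < prev:
            raise ValueError("sweep must be sorted by concentration")
        prev = conc
        if phi > phi_cc:
            return float(conc)
    return None


@dataclass
class CooperativityResult:
    """c* = c_g,sim / c_g,FS and its qualitative reading."""

    c_g_sim: float | None
    c_g_fs: float | None
    c_star: float | None
    label: str

    COOPERATIVITY = {
        "positive": "gel point below the Flory-Stockmayer threshold",
        "zero": "gel point at the Flory-Stockmayer threshold",
        "negative": "gel point above the Flory-Stockmayer threshold",
        "undefined": "one or both gel points missing",
    }


def c_star(c_g_sim: float | None, c_g_fs: float | None, rtol: float = 1e-9) -> CooperativityResult:
    """Cooperativity ratio; sentinel (None) gel points propagate."""
    if c_g_sim is None or c_g_fs is None:
        return CooperativityResult(c_g_sim, c_g_fs, None, "undefined")
    if c_g_sim <= 0 or c_g_fs <= 0:
        raise ValueError("gel points must be positive")
    ratio = c_g_sim / c_g_fs
    if math.isclose(ratio, 1.0, rel_tol=rtol):
        label = "zero"
    elif ratio < 1.0:
        label = "positive"
    else:
        label = "negative"
    return CooperativityResult(c_g_sim, c_g_fs, ratio, label)
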