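# Methods

`latticegel` models linear multivalent proteins — chains of folded
interaction domains (SH3-like, "S") or short linear motifs (PRM-like, "P")
joined by disordered linkers — on a periodic cubic lattice, and asks when
such systems form system-spanning physically crosslinked networks (gels)
and when that gelation is driven by a density (phase-separation)
transition.

## Lattice model

Every domain and every explicitly modeled linker bead occupies one lattice
site; two beads never share a site.  "Adjacent" means face adjacency
(6 neighbors; on an L = 2 box opposite images coincide, leaving 3 distinct
neighbors, and all move and energy machinery deduplicates accordingly).
An S and a P domain on adjacent sites form a 1:1 complex *only when their
binding flag is set*; the bound pair contributes u_SP = -2 k_BT by default
(a value in the range of measured SH3/proline-rich-motif affinities).  All
other nearest-neighbor energies are zero by default; a symmetric
nonspecific contact matrix can be configured, in which case bound pairs
carry u_SP in place of their contact term.

Linkers interpolate between two stylized limits through the pair
(n, e) — total span n lattice sites, e of them explicit:

* e = 0: a Flory-random-coil-like tether (effective solvation volume
  v_es ~ 0).  The two tethered beads are confined to a cubic infinite
  square well: their Chebyshev (max-norm) separation never exceeds n.
  The cube-shaped well is the natural lattice reading of a "cubic" square
  well; the metric is isolated in one helper should a different convention
  ever be needed.
* e = n: a self-avoiding-coil-like linker (v_es > 0): n volume-excluding
  beads, consecutive beads face-adjacent.
* 0 < e < n: hybrid.  The explicit beads are placed contiguously after the
  upstream domain and the remaining span n - e is one implicit square well
  between the last explicit bead and the downstream domain.  Each implicit
  run is an independent well; nothing couples wells across an explicit
  bead.  The mapping to real chains uses N ~= 7 n residues per linker.

Boxes must satisfy L >= 2*cap + 1 for every implicit span.  Beyond keeping
the minimum-image well unambiguous, this guarantees that the uniform
offset proposals used by the moves cover every site of a well exactly once
— with a smaller box, wrapped offsets would alias some sites twice and
silently bias sampling (this failure mode is why the constructor enforces
the bound rather than documenting it).

## Monte Carlo

Five elementary moves evolve the system; each attempt is one "step":

1. **binding_flip** — redraw the interaction state of a random domain in
   place, uniformly over its N admissible states (unbound, plus each free
   complementary domain on a distinct adjacent site).  N is identical
   before and after, so w = 1.
2. **end_pivot** — move a singly tethered end bead to a site drawn
   uniformly from its tether region; domains also redraw their interaction
   state.  w = N_p / N_c.
3. **crankshaft** — the same for a doubly tethered bead, drawing from the
   intersection of both tether regions.  Two Chebyshev wells intersect in
   a per-axis product set, so the draw is O(1); mixed adjacency/well
   constraints enumerate at most six candidates.  w = N_p / N_c.
4. **cluster_translate** — translate an entire connected binding network
   by a random unit lattice vector.  No bonds or linkers change, so the
   move is accepted unless it overlaps a bead outside the cluster.
5. **reptation** — remove an end domain plus its linker and append it at
   the other end, drawing uniformly from the V_p admissible segment
   conformations there and redrawing the interaction state.
   w = (N_p V_p) / (N_c V_c), with V_c counted at the vacated end with the
   segment removed.  The product grouping (as opposed to, say,
   N_p V_c / (N_c V_p)) is the one under which proposal probabilities
   cancel exactly in the detailed-balance ledger, and the
   enumeration-oracle tests confirm it.

Any proposal that lands a bead on an occupied site is an immediate
rejection.  Acceptance follows the Metropolis-Hastings rule
min{1, w exp(-dE)} with energies in k_BT.

The move schedule is uniform over the applicable move types (it affects
mixing only, not the stationary distribution — verified against exact
enumeration).  By default reptation is scheduled only for chains with
fully implicit linkers; for chains with explicit beads the enumeration of
segment conformations grows as 6^e and pivot/crankshaft/translation
already move every bead, so the default schedule omits it there.  The
reference engine implements general-e reptation for completeness.

Two implementations share the state arrays: a plain-Python reference
engine (propose / apply / revert, with bit-exact reversibility) and a
numba kernel used by `run_mc` for production sweeps.  Both are validated
against exhaustive enumeration of tiny systems: every valid (placement x
binding matching) microstate is Boltzmann-weighted and long-run sampling
frequencies must match within statistical error.  For the one-S + one-P
monomer pair on L = 2, the closed-form census is Z = 32 + 24 + 24 e^2 and
P(bound) = 24 e^2/(56 + 24 e^2) ~= 0.760.

Trajectories report observer series (energy, phi_c, rho, largest-network
size) on a stride, and ensemble means over the final half of the run; a
split-half comparison of phi_c (third vs fourth quarter, two combined
standard errors) flags non-equilibrated points rather than averaging them
silently.

## Order parameters

* **phi_c** — fraction of molecules in the single largest cluster of the
  binding network (molecules as nodes, an edge when any intermolecular
  bound S-P pair exists).  Components come from union-find; the test suite
  cross-checks against networkx traversal.
* **rho** = R_lattice / R_g, with R_g the radius of gyration of *all*
  domain and explicit-linker beads and R_lattice the radius of gyration of
  a uniform dispersion over the box, computed exactly over the discrete
  sites: R_lattice = sqrt(3 (L^2 - 1)/12) (the continuum L/2 and a
  sphere-equivalent reference are selectable).  The center of mass is the
  per-axis circular mean, so droplets spanning the periodic boundary are
  measured at their true center.  rho ~ 1 means dispersed, rho >> 1
  condensed; the production two-phase cutoff is rho > 1.08.

  At small molecule counts the dispersed-limit rho sits visibly above 1
  (the circular-mean center chases chance clustering; ~1.07 at 48
  polymers, ~1.03 at 480), so the absolute 1.08 cutoff is meaningful only
  near the production scale.  The cutoff is a configuration value
  everywhere it is used.

* **Coexistence concentrations.**  Assuming the polymer-rich phase is a
  uniform-density sphere of radius r and the polymer-poor phase fills the
  rest of the box uniformly, the measured R_g fixes r through

      N_T R_g^2 = N_N (3/5) r^2
                + (N_T - N_N) [L^5/4 - (4/5) pi r^5] / [L^3 - (4/3) pi r^3],

  (second moments of a uniform ball and of a cube-minus-ball about the
  common center).  Clearing the denominator gives the quintic

      -(4/5) pi N_T r^5 + (4/3) pi N_T R_g^2 r^3 + (3/5) N_N L^3 r^2
      + (N_T - N_N) L^5/4 - N_T R_g^2 L^3 = 0,

  whose single admissible real root (0 < (4/3) pi r^3 < L^3; ties broken
  toward roots with a denser dense phase) is the droplet radius.  N_N is
  the molecule count of the largest cluster.  The phase boundaries follow
  as c_sh = 3 N_N/(4 pi r^3) and c_sl = (N_T - N_N)/(L^3 - (4/3) pi r^3),
  which conserve the molecule count exactly.  On constructed
  dense-ball-plus-dilute-background configurations (low-discrepancy
  filling so the construction realizes the ansatz rather than its
  sampling noise) the recovered radius is exact to ~0.1% and both
  concentrations to well under 5%.

* **Regimes.**  gel iff phi_c > phi_cc (default 0.17), two-phase iff
  rho > rho_cutoff (default 1.08); the four quadrants reproduce
  "gelation without phase separation" (gel, one-phase) versus "gelation
  driven by phase separation" (gel, two-phase).

## Percolation theory

For chains with V_a domains of type a and V_b of type b, mass action
K_d = ([a]-[ab])([b]-[ab])/[ab] fixes the bound fractions, and the
network-growth factor epsilon = (V_a - 1) x_a (V_b - 1) x_b reaches 1 at
the gel point.  The equal-concentration closed form is

    x_c = 1/sqrt(lambda),   [a]_c = K_d sqrt(lambda)/(sqrt(lambda) - 1)^2,
    lambda = (V_a - 1)(V_b - 1),

and the fixed-[b] mode solves epsilon([a]) = 1 numerically for the lower
crossing (epsilon is non-monotone in [a]: the b pool saturates).  Both
agree with an independent root-find to 1e-8 relative.

K_d matched to a lattice affinity comes from the two-particle partition
function on the lattice itself: with one particle fixed, Omega - 1
placements of the second, A = 6 adjacent, each adjacent placement adding a
bound state of weight e^{-u}; hence K_d -> e^{u}/6 domains/site in the
dilute limit (0.0226 at u = -2).  This avoids assuming any off-lattice
volume conversion.

**phi_cc calibration.**  The critical value of phi_c is read from random
bipartite binding networks: 2.4e3 domains split stoichiometrically into
whole molecules of valence V per side (valences that do not divide 1200
use the largest whole-molecule count), each a-domain binding with
probability x to a uniformly drawn free b-domain, clusters measured on the
molecule graph.  Evaluated at the critical bound fraction x_c = 1/(V-1),
the mean largest-cluster fraction is ~0.15-0.16 for V = 3, 5, 7 —
insensitive to valence, as expected at a percolation threshold.  This is
a *finite-size* quantity: at the critical point the largest-cluster
fraction decays slowly with network size (roughly as M^{-1/3} in the
molecule count), which is precisely why the network size is matched to
the lattice simulations' domain count.  The widely used operational
threshold 0.17 is the default phi_cc everywhere; the calibration routine
returns the estimate for any chosen size so users can match their own
scale.

**Cooperativity.**  c* = c_g,sim / c_g,FS compares the simulated gel point
(lowest concentration with phi_c > phi_cc) to the Flory-Stockmayer
prediction; c* < 1 is positive global cooperativity (phase separation
assists gelation), c* = 1 zero, c* > 1 negative.

## Experiment runner

Concentration is titrated by resizing the box at fixed molecule count
(so rho at high concentration is partly depressed by the shrinking box —
tables always carry L alongside rho to keep the artifact attributable).
Sweeps can bisect the box-length grid to single-lattice-unit resolution
around the gel crossing.  Affinity grids stack sweeps into a phase
diagram: two-phase points by the rho cutoff, coexistence concentrations
via the droplet ansatz applied to ensemble-mean N_N and R_g, critical
affinity as the lowest grid affinity with a detected two-phase interval,
and a monotone-width check across affinities reported as a warning rather
than an error.

### Problem sizes

The production profile of record for this class of models is 2.4e3
domains and 5e9 elementary moves per state point.  The package's default
test profile uses 240 domains (24 + 24 pentavalent chains) and 1e6-2e7
steps, except for the density-transition check, which keeps the full
2.4e3 domains (the rho > 1.08 cutoff needs the production-scale dispersed
baseline of ~1.03; at 240 domains the baseline already sits at ~1.07) and
reduces only the step count.  Two consequences, both visible in the test
expectations:

* Gel points measured at 48 molecules carry a granularity of one molecule
  in phi_c (~0.02) and finite-size shifts of order tens of percent; the
  cooperativity checks therefore assert orderings and inequalities
  (c* < 1 for implicit linkers at n = 5; higher gel points for explicit
  linkers; the non-monotone c*(n) profile) rather than curve values.
* Runs started from dispersed initial conditions approach condensation
  from below: with a reduced step budget, rho can only under-shoot its
  equilibrium value, so a detected density-transition onset is an upper
  bound on the true onset affinity.  The acceptance band for the onset is
  asymmetric for exactly this reason.
* The long-linker recovery of c* toward 1 cannot be read from gel-point
  crossings at the test profile: a span-10 tether in an L <= 33 box
  reaches a third of the box (erasing the long-linker penalty), while at
  the production molecule count the gel-range concentrations need far
  more steps than the profile budgets before anything percolates from a
  dispersed start.  The test asserts the mechanism instead: the density
  assist — rho above its own zero-affinity baseline at matched
  concentration — is present at n = 5 and has vanished by n = 10, the
  Flory-Stockmayer limit in which linkers contribute nothing.

## Sequence metrics

FCR = f+ + f- and NCPR = f+ - f- with f+ counting Arg/Lys and f-
counting Asp/Glu (histidine neutral), normalized by length — the rule
that reproduces the published counts for the fourteen 40-residue
benchmark sequences exactly.  The Delta statistic scores a linker's
inter-residue distance profile <R_k> against a Flory-random-coil
reference: Delta = (1/N) sum_k (<R_k> - <R_k^FRC>)/<R_k^FRC>.  The
normalizer is ambiguous between the residue count N and the number of
summed separations (N - 1); both are implemented, N is the default, and
outputs record the choice.  Regimes: Delta < -0.1 -> v_es < 0 (compact,
self-attracting); -0.1 <= Delta <= 0.1 -> v_es ~ 0 (FRC-like);
Delta > 0.1 -> v_es > 0 (expanded); the middle interval is closed on both
sides.  Reference profiles are inputs (they come from chain-ensemble
simulations outside this package's scope); a sqrt(k) ideal-chain
generator exists for testing only.  Linker lengths map to the lattice via
n = round(N/7), minimum 1.

## Known limitations

* Linkers with negative v_es (self-attracting) are out of scope: no
  attractive linker-linker or linker-domain terms are exercised by the
  shipped experiments, matching the model's focus on v_es >= 0.
* Move dynamics are not physical kinetics; only equilibrium averages are
  meaningful.
* Branched topologies are not representable (chains only).
* The compiled kernel covers the default interaction model; nonspecific
  contact matrices run on the reference engine and are practical only for
  small systems.
* Single-droplet assumption: the coexistence analysis presumes the dense
  phase is one sphere; multi-droplet coarsening states violate the ansatz
  and show up as inadmissible-root warnings rather than numbers.
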