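# latticegel

Coarse-grained lattice Monte Carlo and percolation analytics for the phase
behavior of **linear multivalent proteins** — chains of folded interaction
domains (e.g. SH3) or short linear motifs (e.g. proline-rich motifs) joined
by intrinsically disordered linkers.  Such proteins crosslink into
system-spanning networks (*gels*), and they can do so two ways: by a pure
connectivity (sol-gel) transition, or by first condensing into a dense
droplet whose interior concentration exceeds the gel point (*gelation
driven by phase separation*).  Which route a protein takes is controlled
largely by its linkers' effective solvation volumes, and that is what this
package lets you compute.

It is aimed at computational biophysicists studying biomolecular
condensates who want a fast, validated reference implementation of the
bead-tether lattice model, its order parameters, and the accompanying
Flory-Stockmayer theory.

## The model in brief

Chains of valence V live on a periodic cubic lattice, one site per domain
or explicit linker bead.  Complementary domains S and P on adjacent sites
form a 1:1 complex with energy u_SP = -2 k_BT *when their binding flag is
set*.  Linkers of span n sites carry e explicit volume-excluding beads:
e = 0 is a Flory-random-coil-like tether (a Chebyshev square well, zero
excluded volume), e = n a self-avoiding-coil-like linker, 0 < e < n a
hybrid.  A five-move Metropolis-Hastings kernel (binding flips, end
pivots, crankshafts, cluster translations, reptation) with Hastings
weights w preserves microscopic reversibility; acceptance is
min{1, w exp(-dE)}.

Two order parameters separate the transitions:

* `phi_c` — fraction of molecules in the largest bound cluster; gel when
  phi_c > phi_cc (0.17, calibrated by a random bipartite network model);
* `rho` = R_lattice / R_g — uniform-dispersion radius over the actual
  radius of gyration of all beads; two-phase when rho > 1.08.

Flory-Stockmayer theory supplies the reference gel point: with
lambda = (V_a-1)(V_b-1) and mass-action bound fractions,
[a]_c = K_d sqrt(lambda)/(sqrt(lambda)-1)^2 at equal concentrations, and
K_d = e^{u}/6 per site follows from exact two-particle enumeration on the
lattice.  The ratio c* = c_g,sim / c_g,FS measures global cooperativity:
c* < 1 means phase separation assists gelation.

## Worked example

```python
import latticegel as lg

# a 5:5 system: 24 poly-SH3 + 24 poly-PRM pentamers, implicit 5-site linkers
spec = lg.SweepSpec(
    species=(lg.SpeciesSpec("S", 5, linker_n=5, count=24),
             lg.SpeciesSpec("P", 5, linker_n=5, count=24)),
    affinity=2.0,                      # |u_SP| in k_BT
    box_lengths=(26, 29, 32, 36, 40, 46),
    steps=2_000_000, seed=7,
)
table = lg.sweep_concentration(spec)
print(table[["L", "conc_domains", "phi_c", "rho"]].round(4).to_string(index=False))

cg_sim = lg.gel_point_of_sweep(table) / 2   # per-type: [a] = total / 2
cg_fs = lg.fs_gel_point(5, 5, lg.lattice_kd(-2.0))
print(lg.c_star(cg_sim, cg_fs))
```

prints (seed 7, a ~1 minute run):

```
 L  conc_domains  phi_c    rho
46        0.0025 0.0586 1.0954
40        0.0038 0.0672 1.0901
36        0.0051 0.0893 1.0932
32        0.0073 0.1058 1.0909
29        0.0098 0.1460 1.0992
26        0.0137 0.1964 1.0938
CooperativityResult(c_g_sim=0.006827492034592627,
                    c_g_fs=0.010024835795304644,
                    c_star=0.6810577423911955, label='positive')
```

Reading: phi_c crosses the 0.17 percolation threshold at 1.37e-2 total
domains/site, i.e. 6.8e-3 type-a domains/site — below the
Flory-Stockmayer gel point (1.0e-2 at K_d = e^-2/6).  c* = 0.68 < 1 is
the positive-global-cooperativity signature of implicit (near-zero
excluded volume) linkers; at full production scale (2.4e3 domains, 5e9
steps) the same system shows c* well below this 48-molecule value.
Swapping the species to fully explicit linkers (`linker_e=5`) shifts the
crossing to several-fold higher concentration and pins rho at its
dispersed baseline: gelation without phase separation.

The same machinery is scriptable from the shell:

```bash
latticegel theory fs-gelpoint --va 5 --vb 5 --affinity 2
latticegel theory phicc --valences 3,5,7 --n 2400 --reps 50 --seed 1
latticegel seqmetrics --fasta linkers.fasta --out metrics.csv
latticegel simulate --config run.yaml --out out/
latticegel sweep --config sweep.yaml --out sweep.csv
```

Sequence-level linker characterization mirrors the lattice classes:
`charge_metrics` gives FCR/NCPR, `delta_parameter` scores an
inter-residue distance profile against a Flory-random-coil reference
(regimes at Delta = ±0.1 map to negative / near-zero / positive effective
solvation volume), and `residues_to_lattice` converts residue counts to
lattice spans (N ~= 7 n).

See `docs/methods.md` for the model's assumptions, the droplet-radius
derivation, calibration details, and known limitations.

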