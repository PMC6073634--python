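# gardsim

Stochastic simulation and analysis of **GARD** — the graded autocatalysis
replication domain model of mutually catalytic amphiphile assemblies — for
researchers studying compositional inheritance, autocatalytic sets and
protocell evolution in the origin-of-life context.

## The model

A molecular assembly (micelle or small vesicle) over a repertoire of `N_G`
amphiphile types is described by its compositional vector
**n** = (n_1, …, n_NG). Molecules enter and leave by single-molecule
exchange with the environment,

```
           k_f_i · ρ_i · N · C_i
A_i (out)  ─────────────────────▶  A_i (assembly)
           ◀─────────────────────
           k_b_i · n_i · C_i
```

where `N = Σ n_i`, `ρ_i` is the external concentration, and the catalytic
factor

```
C_i = 1 + (1/N) Σ_j β_ij n_j
```

encodes graded mutual catalysis: `β_ij` is the rate enhancement exerted by an
in-assembly molecule of type *j* on the exchange of type *i*. The `β` matrix
is drawn from a lognormal distribution (default μ = −4, σ = 4 on the natural
log scale), the standard heavy-tailed statistics of molecular recognition:
weak catalysis common, strong catalysis rare. Because `C_i` multiplies both
directions, catalysis is purely kinetic — it never shifts the exchange
equilibrium `K_i = k_f_i / k_b_i`.

The exchange network is simulated exactly (Gillespie direct method over the
`2·N_G` entry/exit channels, numba-accelerated). Reproduction is growth from
`N_MIN = N_MAX/2` to `N_MAX` followed by random fission into two halves
(multivariate hypergeometric). For favourable compositions the assembly grows
*homeostatically* — the direction of **n** is preserved — and fission then
yields two faithful progeny: **composomes**, quasi-stationary compositional
states that carry heritable information without any templating polymer.

On top of this core the package provides

- **Composome/compotype analysis** — cosine similarity `H`, time-correlation
  carpets, episode detection, greedy compotype clustering, entropy and
  restricted-repertoire (`N_MOL`) statistics, leading-eigenvector "canonical
  composome".
- **Information metrics** — exact multiset counts `C(N+N_G−1, N)` and
  compositional vs. sequence information in bits.
- **Evolution experiments** — constant-population reactors with takeover
  detection and logistic fits, environment-shift experiments
  (`ρ′ = 0.9·ρ + 0.1·n(target)`), single-compound depletion screens,
  error-catastrophe sweeps of `K_eq`.
- **Chiral GARD** — mirror-symmetric `β` over D/L enantiomer pairs,
  enantiomeric excess and antipode-similarity metrics.
- **P-GARD** — a dimer-level polymer extension with on-the-fly catalysis
  rules and monomer-equivalent bookkeeping.
- **Planetary calculators** — replicator capacity of an early-ocean surface
  layer and the implied lipid concentration.

## Worked example

```sh
$ cat run.toml
n_types = 100
n_max = 100
n_generations = 500
seed = 5

$ gard simulate --config run.toml --out trace.csv
500 generations, growth rate 5651 splits/time -> trace.csv

$ gard analyze trace.csv --out analysis
8 composome episode(s)
  C1: frequency 0.05, N_MOL 30
  C2: frequency 0.04, N_MOL 24
  C3: frequency 0.01, N_MOL 20
```

A 500-generation single-lineage run under the default kinetics found eight
composome episodes (runs of ≥ 5 consecutive generations with all pairwise
similarities H ≥ 0.9), clustering into three compotypes. Their restricted
repertoires (20–30 of the 100 environmental types) sit far below the
63.4 ± 3.1 expected of a random 100-molecule assembly — the repertoire
diminution that marks kinetically selected, heritable compositions. The
remaining ~90 % of generations are drift: this matrix reproduces only
intermittently, while other matrices lock into a single compotype for ≥ 93 %
of the run (try `seed = 8`).

```sh
$ gard info --n 100
compositions of N=100 over N_G=100: 4.53e+58
compositional information: 194.9 bits (sequential: 664.4)
random-assembly repertoire N_MOL: 63.4 +/- 3.1
replicators in 10^7 km^2 x 1 m at one per 1e-19 m^3: 1.0e+32
lipid concentration at 1e-5 volume fraction, 500 Da: 20.0 uM
```

The same operations are available as a library (`import gardsim`): see
`docs/methods.md` for the model details, parameter meanings and numerical
choices.

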