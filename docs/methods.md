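# Methods

## Model and assumptions

gardsim simulates a single well-stirred molecular assembly (and populations
thereof) exchanging amphiphiles with an environment of `N_G` molecule types.
The state is the integer compositional vector **n**; the only reactions in
the basic model are single-molecule entry and exit, with propensities

    forward_i  = k_f_i · ρ_i · N · C_i
    backward_i = k_b_i · n_i · C_i
    C_i        = 1 + (1/N) · Σ_j β_ij n_j .

Assumptions inherited from the model family: perfect mixing (no spatial
structure), a constant environment in infinite-supply mode, graded (never
zero, unless explicitly cut off or depleted) mutual catalysis, and a
catalytic factor that multiplies entry and exit identically, so that
catalysis accelerates equilibration without moving the equilibrium
`K_i = k_f_i / k_b_i`. Fission is instantaneous and random: the grown
assembly at `N_MAX` is partitioned without replacement into exact halves
(multivariate hypergeometric law), which presumes fission is driven
externally (shear, instability) rather than by composition.

The stochastic engine is the exact Gillespie direct method over the `2·N_G`
channels, implemented as numba kernels with an incrementally maintained
catalytic sum (O(N_G) per event). Event selection and waiting times consume
two uniforms per step from a `numpy` PCG64 generator, so every run is a pure
function of (state, parameters, seed).

## Parameters

| parameter | default | units | meaning / rationale |
|---|---|---|---|
| `N_G` | 100 | – | environmental repertoire size; 100 is the standard working point |
| `N_MAX` | 100 | molecules | size at fission; heritability requires `N_MAX ≤ N_G` |
| `N_MIN` | `N_MAX/2` | molecules | post-fission size (exact halves) |
| `μ, σ` | −4, 4 | ln units | lognormal statistics of `β`; heavy tail = rare strong catalysts |
| `k_f` | 1 | 1/(conc·time) | basal forward rate constant (sets the time unit) |
| `k_b` | 1 | 1/time | basal backward rate constant |
| `ρ_i` | 2 | conc | external concentration, equal for all types |
| similarity threshold | 0.9 | – | composome membership (all pairwise `H` within a run) |
| min episode length | 5 | generations | shortest run that counts as a composome |
| compotype threshold | 0.9 | – | first-fit episode clustering |
| classify threshold | 0.8 | – | reactor assembly→compotype assignment (below: drift) |

Time units are arbitrary; the rate constants set the scale, and reactor time
is reported in split events.

**Choice of the kinetic working point.** The published analyses of this model
family do not print `k_f`, `k_b`, `ρ`; we fix them once on physical grounds.
Amphiphile insertion into an assembly is strongly exergonic, so exchange must
be entry-dominated; we take `K_i ρ_i = 2`, i.e. the external concentration
sits above the per-type balance point, making net growth downhill at *every*
composition — including fully concentrated ones. At `K ρ = 1` a
single-type-dominated assembly performs an unbiased random walk in `N`
(entry and exit rates coincide because the catalytic factor multiplies
both), which stalls growth and occasionally dissolves the assembly entirely;
we regard that marginal regime as unphysical for a growth model, but it is
exactly what the error-catastrophe sweep probes from above. Exits at
`K ρ = 2` still account for a few percent of events — the compositional
mutations that let lineages move between composomes. Extinction (N → 0
during growth) is possible in principle for very small assemblies
(probability ≈ (1/2)^N_MIN per generation) and is reported as a
stalled-growth error; at the default `N_MIN = 50` it never occurs.

With the heavy-tailed `β` (mean element e^{μ+σ²/2} ≈ 55) catalysis dominates
the basal rates, so entry competition is decided by the relative `C_i`:
assemblies are attracted towards strongly mutually catalytic subnetworks
("communities") of the matrix, producing composomes with restricted
repertoires (`N_MOL` ≈ 15–30 versus 63.4 ± 3.1 for random assemblies) and
lowered entropy.

## Operations built on the core

- **Trace mode** follows one random progeny per fission for `G` generations,
  recording the composition at each split; the growth clock (splits per unit
  simulated time) is the fitness proxy used by the depletion screen.
- **Finite-supply equilibrium runs** disable fission and give each type an
  equal share of a molecular budget; effective concentrations track the
  remaining external count. With equal `K_i` and `ρ_i(0)` the late plateau
  has equal molar fractions (the catalytic factor cancels at equilibrium);
  the early transient is kinetically selected and composome-like. The
  stationary state is checked in the tests against an independent
  detailed-balance oracle: per-type balance at fixed `N` has the closed form
  `n_i = a_i N (E0 + n0_i)/(E0 + a_i N)` with `a_i = K_i ρ_i(0)`, and the
  self-consistency equation `Σ n_i(N) = N` is solved by bracketing.
- **Composome detection** marks maximal runs of ≥ 5 consecutive generations
  whose pairwise similarities all reach `H ≥ 0.9` (an all-pairs criterion; a
  running-centroid mode is available behind a flag). Episodes are clustered
  into compotypes by deterministic first-fit on centroid similarity.
- **Constant-population reactors** grow all assemblies concurrently; the
  first to reach `N_MAX` splits, both progeny are kept, and one uniformly
  random other assembly is removed. Frequencies are recorded against a
  reference compotype set built from a long single-lineage pre-run of the
  same matrix (self-consistent labelling). The environment-shift experiment
  replaces `ρ` mid-run by `(1−w)·ρ(0) + w·target`, with the target
  composition rescaled to the total of `ρ(0)` so units agree and the total
  external concentration is conserved; the published blend weight is
  `w = 0.1`. The shifted target is the compotype with the smallest positive
  mean frequency at the control run's pre-switch steady state.
- **Depletion screens** zero an entire `β` row and column (environmental
  removal of one compound; optionally also `ρ_i = 0`, equivalent for the
  catalytic network) and compare growth rates after/before over paired
  traces with a shared seed. Ratios inside [0.79, 1.25] are the neutral
  band; stalled or extinct depleted runs are recorded as ratio 0 and
  flagged.
- **K_eq sweeps** scale `k_f` downwards with `k_b` unchanged — a
  thermodynamic mutation-rate knob: lowering the joining free-energy drive
  raises the share of exit events. Persistence (fraction of generations
  inside composome episodes) declines and collapses as `K ρ` approaches 1.
- **Chiral GARD** doubles the repertoire into D/L enantiomer pairs with
  exact mirror symmetry `β(i,j) = β(σ(i),σ(j))`; within- and cross-handed
  blocks are sampled independently from the same lognormal. The environment
  is exactly racemic; enantioselection, when it occurs, is spontaneous
  symmetry breaking seeded by small-number statistics. The chiral runs use
  `N_G = 200` (100 scaffolds) with `N_MAX = 300`, the published parameter
  range for this experiment.
- **P-GARD** adds catalysed dimerisation and cleavage. Catalytic
  enhancements are computed on the fly by an additive sub-site rule
  (monomer catalyst *a* on dimerisation (i,j): `(β_ia + β_ja)/2`; dimer
  catalyst (a,b): `(β_ia + β_jb)/2`, templating-like), isolated in a single
  function so alternative rules can be swapped. Dimers are endogenous (no
  environmental exchange) and split as indivisible units. With zero dimer
  rates the channel layout and stream protocol make the extended kernel
  reproduce the basic kernel event for event. The dimer-takeover regime
  used in tests (`k_dim = 0.05`, `k_cleave = 0.1` at `N_G = 20`,
  `N_MAX = 80`) puts catalysed dimer formation in competition with monomer
  influx.

## Numerical choices

- One root seed spawns named per-component streams (init, growth, split,
  keep, victim) via `SeedSequence`; toggling one experimental arm therefore
  never perturbs another arm's stream, which is what makes weight-0 shifts
  and null depletions reproduce control runs bit for bit.
- Cutoff thresholds are expressed on `β` divided by its construction-time
  mean element; keeping the construction-time scale makes cutoff application
  idempotent. The cutoff is a matrix edit only (weak/strong catalytic
  closure); no reaction-network closure enumeration is performed.
- The leading-eigenvector analysis uses dense `numpy.linalg.eig`, rejects
  degenerate leading pairs (tie tolerance 1e-9 relative) and warns on
  all-zero rows after aggressive cutoffs.
- The logistic fit `f(t) = K/(1 + A e^(−rt))` uses bounded least squares
  (`K ≤ 1.5`, `r ≥ 0`) with slope-based initialisation and raises on
  non-convergence rather than returning silently.
- Growth phases carry a stall guard of 10^7 SSA events; float round-off in
  channel selection (u at the top of the cumulative sum) falls back to the
  last open channel.
- `n_compositions` uses exact big-integer binomials; `information_bits`
  falls back to a bit-length expansion beyond the float range.

## Problem sizes

Default experiment sizes are chosen so the full analysis suite runs in
minutes on one core: emergence statistics use 20 matrices × 500 generations;
the depletion screen 100 matrices × 30 compounds × 200 generations; reactor
experiments 60 assemblies × 2000 splits with 40-type repertoires; chiral
runs 10 × 500 generations; the K_eq sweep 5 matrices × 6 scales × 300
generations. The published experiments behind the screen and the reactors
used larger settings (1000 matrices; 1000 assemblies); the statistics
reported here are scaled-down reproductions and are read directionally.

## What the synthetic conditions do and do not show

All inputs are generated: `β` matrices are lognormal samples, not measured
rate enhancements, and the environment is a fixed equal-concentration bath.
Passing tests therefore demonstrate the *dynamical phenomena* — homeostatic
growth, composome emergence and inheritance, selection in reactors,
symmetry breaking — under the model's statistical assumptions, not that any
specific real lipid mixture behaves this way. Real-lipid parameterisations,
covalent metabolism beyond dimers, inner/outer-universe exchange and spatial
structure are out of scope.

## Known limitations

- Raw cosine similarity saturates at small `N_G` (100 molecules over 10
  types make any two compositions alike), so similarity-based heritability
  comparisons across repertoire sizes need a baseline correction (see the
  repertoire-boundary tests for both the raw and the baseline-corrected
  readings).
- Compotype clustering is first-fit and order-stable but not a global
  optimum; reference compotypes from a single pre-run lineage may miss
  states a reactor population can reach.
- The additive sub-site rule for P-GARD catalysis is the simplest reading of
  combinatorial sub-site catalysis; it is deliberately pluggable.
- Episode-level `N_MOL` counts types with mean count > 0.5 over the episode;
  other thresholds shift absolute values (comparisons are unaffected).
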