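"""Stochastic integration of the GARD rate law and growth-fission reproduction.

The elementary reactions are the entry and exit of single amphiphiles:

    A_i (outside)  <->  A_i (assembly)

with propensities

    forward_i  = k_f_i * rho_i * N * C_i
    backward_i = k_b_i * n_i * C_i
    C_i        = 1 + (1/N) * sum_j beta_ij * n_j

simulated exactly with the Gillespie direct method.  Reproduction is modelled
as growth from N_MIN to N_MAX followed by a random fission into two halves
(multivariate hypergeometric partition).  "Trace mode" follows one progeny
per generation, discarding the other; this is the single-lineage view in
which composomes (quasi-stationary compositions) are observed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from ._rng import streams
from .model_core import Assembly, GardError, GardParameters, random_assembly

__all__ = [
    "StalledGrowthError",
    "Trace",
    "TimeSeries",
    "propensities",
    "step_ssa",
    "grow_to_size",
    "split",
    "run_trace",
    "run_to_equilibrium",
    "mutate_composition",
    "keq_sweep",
    "ode_rhs",
]


class StalledGrowthError(GardError):
    """Growth did not reach N_MAX within the step budget (or went extinct)."""


# ---------------------------------------------------------------------------
# elementary operations

def propensities(assembly: Assembly, params: GardParameters) -> tuple[np.ndarray, np.ndarray]:
    """Forward (entry) and backward (exit) propensity vectors.

    The catalytic factor multiplies both directions identically, so mutual
    catalysis changes how fast the exchange runs, never where its equilibrium
    lies (K_i = k_f_i / k_b_i is untouched).
    """
    n = assembly.counts
    total = assembly.size
    if total == 0:
        raise GardError("propensities undefined for an empty assembly (N = 0)")
    c = 1.0 + (params.beta.values @ n) / total
    forward = params.k_f_vec * params.rho_vec * total * c
    backward = params.k_b_vec * n * c
    return forward, backward


def step_ssa(
    assembly: Assembly, params: GardParameters, rng: np.random.Generator
) -> tuple[Assembly, float]:
    """One exact SSA step: a single molecule enters or leaves.

    The event is chosen with probability proportional to its propensity and
    the elapsed time is exponential with rate equal to the total propensity.
    """
    forward, backward = propensities(assembly, params)
    total_rate = float(forward.sum() + backward.sum())
    if total_rate <= 0.0:
        raise StalledGrowthError("all propensities are zero (stalled system)")
    u = rng.random() * total_rate
    cum = np.cumsum(np.concatenate([forward, backward]))
    channel = int(np.searchsorted(cum, u, side="left"))
    channel = min(channel, 2 * params.n_types - 1)
    counts = assembly.counts.copy()
    if channel < params.n_types:
        counts[channel] += 1
    else:
        counts[channel - params.n_types] -= 1
    dt = -np.log(rng.random()) / total_rate
    return Assembly(counts), dt


def grow_to_size(
    assembly: Assembly, params: GardParameters, rng: np.random.Generator
) -> tuple[Assembly, float]:
    """Repeated SSA steps until N == n_max; returns the grown assembly and the
    elapsed simulated time (the inter-split interval used as the growth clock).
    """
    if assembly.size > params.n_max:
        raise GardError("assembly already larger than n_max")
    counts, elapsed, _steps, flag = _kernels.grow_kernel(
        assembly.counts,
        params.k_f_vec * params.rho_vec,
        params.k_b_vec,
        params.beta.values,
        params.n_max,
        params.max_steps_per_growth,
        rng,
    )
    if flag == _kernels.EXTINCT:
        raise StalledGrowthError("assembly went extinct during growth")
    if flag == _kernels.STALLED:
        raise StalledGrowthError(
            f"growth did not reach N_MAX={params.n_max} within "
            f"{params.max_steps_per_growth} steps"
        )
    return Assembly(counts), float(elapsed)


def split(assembly: Assembly, rng: np.random.Generator) -> tuple[Assembly, Assembly]:
    """Random fission into two halves of exactly N/2 molecules each.

    Molecules are partitioned without replacement, so per-type progeny counts
    follow the multivariate hypergeometric law and the parent's counts are
    conserved exactly.
    """
    total = assembly.size
    if total % 2 != 0:
        raise GardError("fission requires an even molecule count")
    first = rng.multivariate_hypergeometric(assembly.counts, total // 2)
    first = np.asarray(first, dtype=np.int64)
    return Assembly(first), Assembly(assembly.counts - first)


def mutate_composition(assembly: Assembly, type_index: int, delta: int) -> Assembly:
    """A compositional mutation: change the count of one molecule type by delta."""
    if not 0 <= type_index < assembly.n_types:
        raise GardError("type index out of range")
    counts = assembly.counts.copy()
    counts[type_index] += delta
    if counts[type_index] < 0:
        raise GardError("mutation would drive a count negative")
    return Assembly(counts)


# ---------------------------------------------------------------------------
# trace mode

@dataclass(frozen=True)
class Trace:
    """Per-generation compositions at fission along a single lineage."""

    compositions: np.ndarray          # (n_generations, n_types) int
    times: np.ndarray                 # simulated time of each fission
    params: GardParameters
    seed: int | None = None

    def __post_init__(self) -> None:
        comps = np.asarray(self.compositions, dtype=np.int64)
        times = np.asarray(self.times, dtype=np.float64)
        if comps.ndim != 2 or comps.shape[0] != times.shape[0]:
            raise GardError("trace shape mismatch")
        object.__setattr__(self, "compositions", comps)
        object.__setattr__(self, "times", times)

    def __len__(self) -> int:
        return self.compositions.shape[0]

    @property
    def n_generations(self) -> int:
        return len(self)

    def growth_rate(self) -> float:
        """Splits per unit simulated time over the whole trace."""
        if self.times[-1] <= 0:
            return 0.0
        return self.n_generations / float(self.times[-1])


def run_trace(
    params: GardParameters,
    n_generations: int,
    seed: int | None = None,
    initial: Assembly | None = None,
) -> Trace:
    """Alternate grow-to-N_MAX / fission / keep-one-progeny for
    ``n_generations``, recording the composition at each fission.

    The lineage starts from ``initial`` or, by default, from N_MIN molecules
    drawn uniformly with replacement from the repertoire (a randomly seeded
    assembly).  All randomness derives from ``seed`` through named
    sub-streams, so the same seed reproduces the trace exactly.
    """
    if n_generations < 1:
        raise GardError("n_generations must be >= 1")
    if params.n_max % 2 != 0:
        raise GardError("trace mode requires an even n_max")
    if seed is None:
        seed = params.seed
    rngs = streams(seed, "init", "growth", "split", "keep")
    assembly = initial if initial is not None else random_assembly(
        params.n_min, params.n_types, rngs["init"]
    )
    comps = np.zeros((n_generations, params.n_types), dtype=np.int64)
    times = np.zeros(n_generations)
    t = 0.0
    for gen in range(n_generations):
        assembly, dt = grow_to_size(assembly, params, rngs["growth"])
        t += dt
        comps[gen] = assembly.counts
        times[gen] = t
        progeny_a, progeny_b = split(assembly, rngs["split"])
        assembly = progeny_a if rngs["keep"].random() < 0.5 else progeny_b
    return Trace(comps, times, params, seed)


# ---------------------------------------------------------------------------
# finite supply, no fission

@dataclass(frozen=True)
class TimeSeries:
    """Sampled (time, composition) course of a no-fission run."""

    times: np.ndarray
    compositions: np.ndarray          # (n_samples, n_types)
    external: np.ndarray              # remaining external molecules per type
    params: GardParameters
    seed: int | None = None
    equilibrium_mode: bool = True

    def __len__(self) -> int:
        return self.times.shape[0]

    def sizes(self) -> np.ndarray:
        return self.compositions.sum(axis=1)

    def molar_fractions(self) -> np.ndarray:
        sizes = np.maximum(self.sizes(), 1)[:, None]
        return self.compositions / sizes


def run_to_equilibrium(
    params: GardParameters,
    seed: int | None = None,
    max_events: int = 400_000,
    sample_every: int = 500,
    initial: Assembly | None = None,
) -> TimeSeries:
    """Grow a single assembly without fission against a finite molecular
    supply until the external reservoir is (effectively) exhausted.

    The supply budget is shared out equally between types; each entry
    decrements the external count of its type and each exit restores it, so
    the effective concentration rho_i(t) tracks the remaining supply.  With
    equal equilibrium constants and equal initial concentrations, the late
    plateau has equal molar fractions for all types: the catalytic factor
    multiplies both directions and cancels at equilibrium.  The early
    transient, by contrast, is kinetically controlled and composome-like.
    """
    if params.supply_mode != "finite":
        raise GardError("run_to_equilibrium requires supply_mode='finite'")
    if params.fission_mode:
        raise GardError("run_to_equilibrium requires fission_mode=False")
    if seed is None:
        seed = params.seed
    rngs = streams(seed, "init", "growth")
    assembly = initial if initial is not None else random_assembly(
        params.n_min, params.n_types, rngs["init"]
    )
    per_type = params.supply_budget // params.n_types
    if per_type < 1:
        raise GardError("supply_budget must provide at least one molecule per type")
    external = np.full(params.n_types, per_type, dtype=np.int64)
    times, comps, exts, _k, flag = _kernels.equilibrium_kernel(
        assembly.counts,
        external,
        params.k_f_vec,
        params.k_b_vec,
        params.rho_vec,
        params.beta.values,
        max_events,
        sample_every,
        rngs["growth"],
    )
    if flag == _kernels.EXTINCT:
        raise StalledGrowthError("assembly went extinct before reaching equilibrium")
    return TimeSeries(times, comps, exts, params, seed)


# ---------------------------------------------------------------------------
# thermodynamic mutation-rate sweep

def keq_sweep(
    params: GardParameters,
    scales,
    n_generations: int,
    seed: int | None = None,
    n_matrices: int = 1,
    threshold: float = 0.9,
    min_length: int = 5,
):
    """Composome persistence as the exchange equilibrium constant is lowered.

    Lowering k_f with k_b unchanged reduces K_eq, i.e. weakens the free-energy
    drive for amphiphile joining; exits (compositional mutations) then make up
    a growing share of events.  For each scale factor the trace is re-run with
    k_f scaled and the fraction of generations lying inside composome episodes
    is reported.  Scale 1 with the same seed reproduces the unscaled trace.

    Returns a DataFrame with columns (keq_scale, matrix, persistence).
    """
    import pandas as pd

    from .compostats import detect_composomes
    from .model_core import sample_beta

    scales = list(scales)
    if not scales:
        raise GardError("empty scale grid")
    if any(s <= 0 for s in scales):
        raise GardError("scale factors must be positive")
    rows = []
    for m in range(n_matrices):
        if n_matrices == 1:
            p_base = params
        else:
            beta = sample_beta(params.n_types, params.beta.mu, params.beta.sigma,
                               seed=(seed or 0) + 7919 * m)
            p_base = params.with_(beta=beta)
        for scale in scales:
            p = p_base.with_(k_f=p_base.k_f_vec * scale)
            try:
                trace = run_trace(p, n_generations, seed=(seed or 0) + m)
                episodes = detect_composomes(trace, threshold=threshold, min_length=min_length)
                covered = sum(e.end - e.start + 1 for e in episodes)
                persistence = covered / n_generations
            except StalledGrowthError:
                persistence = 0.0
            rows.append({"keq_scale": float(scale), "matrix": m, "persistence": persistence})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# deterministic cross-check

def ode_rhs(t: float, n: np.ndarray, params: GardParameters) -> np.ndarray:
    """Mean-field GARD rate equation dn_i/dt = (k_f_i rho_i N - k_b_i n_i) C_i.

    Provided for deterministic cross-checks of the stochastic kernels (e.g.
    with scipy.integrate.solve_ivp); not used by the simulator itself.
    """
    total = n.sum()
    if total <= 0:
        return np.zeros_like(n)
    c = 1.0 + (params.beta.values @ n) / total
    return (params.k_f_vec * params.rho_vec * total - params.k_b_vec * n) * c
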