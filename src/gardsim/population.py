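"""Constant-population reactor simulations and evolution experiments.

A reactor holds a fixed number of assemblies.  Whichever assembly reaches
N_MAX first (in simulated time) splits; both progeny are kept and one other
assembly, chosen uniformly at random, is removed so the population stays
constant.  Compotype frequencies tracked against a reference compotype set
reveal selection phenomena: takeovers (one compotype displacing another at
steady state), responses to environmental chemistry shifts, and the fitness
consequences of depleting single compounds.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import derive_seed, streams
from .compostats import Compotype, cluster_compotypes, detect_composomes, similarity_H
from .dynamics import StalledGrowthError, Trace, grow_to_size, run_trace, split
from .model_core import Assembly, GardError, GardParameters, deplete_compound, random_assembly

__all__ = [
    "ReactorHistory",
    "ScreenResult",
    "LogisticFit",
    "reference_compotypes",
    "run_reactor",
    "detect_takeover",
    "fit_logistic",
    "shift_environment",
    "run_shift_experiment",
    "find_multi_compotype_params",
    "depletion_screen",
]


# ---------------------------------------------------------------------------
# reference compotypes

def reference_compotypes(
    params: GardParameters,
    seed: int | None,
    n_generations: int = 500,
    threshold: float = 0.9,
    min_length: int = 5,
    cluster_threshold: float = 0.9,
) -> list[Compotype]:
    """Build the compotype set of a beta matrix from a long single-lineage
    pre-run, used as the fixed labelling for reactor frequency tracking."""
    trace = run_trace(params, n_generations, seed=derive_seed(seed or 0, "reference"))
    episodes = detect_composomes(trace, threshold=threshold, min_length=min_length)
    if not episodes:
        return []
    return cluster_compotypes(episodes, threshold=cluster_threshold,
                              n_generations=n_generations)


def classify(composition: np.ndarray, compotypes: list[Compotype], threshold: float) -> int:
    """Index of the best-matching compotype, or -1 (drift) below threshold."""
    best, best_h = -1, threshold
    for k, ct in enumerate(compotypes):
        h = similarity_H(composition, ct.centroid)
        if h >= best_h:
            best, best_h = k, h
    return best


# ---------------------------------------------------------------------------
# the reactor

@dataclass(frozen=True)
class ReactorHistory:
    """Sampled compotype frequencies of a constant-population reactor run."""

    frequencies: pd.DataFrame        # index: split count; columns: C1..Ck, drift
    reference: tuple[Compotype, ...]
    pop_size: int
    n_splits: int
    params: GardParameters
    seed: int | None = None
    switch_at: int | None = None     # split count of an environment shift, if any

    def mean_frequency(self, column: str, start: int | None = None,
                       end: int | None = None) -> float:
        f = self.frequencies[column]
        idx = f.index
        mask = np.ones(len(idx), dtype=bool)
        if start is not None:
            mask &= idx >= start
        if end is not None:
            mask &= idx < end
        return float(f[mask].mean())


def run_reactor(
    params: GardParameters,
    pop_size: int,
    n_splits: int,
    seed: int | None = None,
    reference: list[Compotype] | None = None,
    record_every: int = 20,
    classify_threshold: float = 0.8,
    rho_schedule: dict[int, np.ndarray] | None = None,
    ref_generations: int = 500,
) -> ReactorHistory:
    """Constant-population reactor: grow all assemblies concurrently, split
    the first to reach N_MAX, keep both progeny, remove one random other
    assembly.  Time is counted in split events.

    ``rho_schedule`` maps split counts to replacement external concentration
    vectors (used for environment-shift experiments); growth already in
    flight is unaffected, newly created progeny grow under the new chemistry.
    """
    if pop_size < 2:
        raise GardError("pop_size must be >= 2")
    if n_splits < 1:
        raise GardError("n_splits must be >= 1")
    if reference is None:
        reference = reference_compotypes(params, seed, n_generations=ref_generations)
    rngs = streams(seed, "init", "growth", "split", "victim")
    columns = [f"C{k + 1}" for k in range(len(reference))] + ["drift"]

    current = params
    heap: list[tuple[float, int]] = []
    alive: dict[int, np.ndarray] = {}        # id -> grown composition at N_MAX
    counter = itertools.count()

    def launch(assembly: Assembly, start_time: float) -> None:
        grown, dt = grow_to_size(assembly, current, rngs["growth"])
        ident = next(counter)
        alive[ident] = grown.counts
        heapq.heappush(heap, (start_time + dt, ident))

    for _ in range(pop_size):
        launch(random_assembly(current.n_min, current.n_types, rngs["init"]), 0.0)

    records = []

    def record(split_count: int) -> None:
        tally = np.zeros(len(reference) + 1)
        for comp in alive.values():
            k = classify(comp, reference, classify_threshold)
            tally[k if k >= 0 else -1] += 1
        records.append(dict(zip(columns, tally / len(alive))) | {"split": split_count})

    record(0)
    switch_at = None
    for event in range(1, n_splits + 1):
        if rho_schedule and event in rho_schedule:
            current = current.with_(rho=np.asarray(rho_schedule[event], dtype=np.float64))
            switch_at = event
        while True:
            t_fission, ident = heapq.heappop(heap)
            if ident in alive:
                break
        parent = Assembly(alive.pop(ident))
        progeny_a, progeny_b = split(parent, rngs["split"])
        victims = sorted(alive.keys())
        victim = victims[int(rngs["victim"].integers(0, len(victims)))]
        del alive[victim]
        launch(progeny_a, t_fission)
        launch(progeny_b, t_fission)
        if len(alive) != pop_size:
            raise GardError("population size drifted (internal error)")
        if event % record_every == 0 or event == n_splits:
            record(event)

    freq = pd.DataFrame.from_records(records, index="split")
    return ReactorHistory(freq, tuple(reference), pop_size, n_splits, params, seed,
                          switch_at=switch_at)


# ---------------------------------------------------------------------------
# takeover detection and logistic fits

def detect_takeover(series, window: int = 5) -> list[tuple[int, int, int]]:
    """Find takeover events in compotype frequency series.

    ``series`` is a (time x compotypes) array or DataFrame.  An event
    (i, j, t) requires compotype i to be the strict maximum for ``window``
    consecutive samples before t, and j the strict maximum for ``window``
    samples from t on.  Ties are never dominance.
    """
    values = np.asarray(series.values if hasattr(series, "values") else series, dtype=float)
    if values.ndim != 2 or values.shape[1] < 2:
        raise GardError("need at least two series of equal length")
    n_t, n_k = values.shape
    if n_t < 2 * window:
        return []

    def strict_leader(t: int) -> int:
        row = values[t]
        k = int(np.argmax(row))
        if np.sum(row == row[k]) > 1:
            return -1
        return k

    leaders = np.array([strict_leader(t) for t in range(n_t)])
    events = []
    for t in range(window, n_t - window + 1):
        before = leaders[t - window:t]
        after = leaders[t:t + window]
        i, j = before[0], after[0]
        if i < 0 or j < 0 or i == j:
            continue
        if np.all(before == i) and np.all(after == j):
            if not events or events[-1][:2] != (i, j):
                events.append((int(i), int(j), int(t)))
    return events


@dataclass(frozen=True)
class LogisticFit:
    rate: float
    carrying_capacity: float
    initial_value: float
    residual_norm: float


def fit_logistic(series, t=None) -> LogisticFit:
    """Least-squares fit of the ecological logistic f(t) = K / (1 + A e^(-rt)).

    Raises on non-convergence rather than returning silently bad parameters.
    Returns (rate r, carrying capacity K, initial value f(0), residual norm).
    """
    from scipy.optimize import curve_fit

    f = np.asarray(series, dtype=float)
    if f.ndim != 1 or f.size < 5:
        raise GardError("need at least five points to fit a logistic")
    if np.any((f < 0) | (f > 1)):
        raise GardError("frequencies must lie in [0, 1]")
    t = np.arange(f.size, dtype=float) if t is None else np.asarray(t, dtype=float)

    def logistic(x, k, a, r):
        return k / (1.0 + a * np.exp(-r * x))

    k0 = max(float(f.max()), 1e-6)
    f0 = max(float(f[0]), 1e-6)
    a0 = max(k0 / f0 - 1.0, 1e-6)
    span = max(float(t[-1] - t[0]), 1.0)
    try:
        popt, _ = curve_fit(
            logistic, t, f,
            p0=[k0, a0, 1.0 / span],
            bounds=([1e-9, 1e-9, 0.0], [1.5, 1e12, np.inf]),
            maxfev=20_000,
        )
    except RuntimeError as exc:
        raise GardError(f"logistic fit did not converge: {exc}") from exc
    k, a, r = popt
    residual = float(np.linalg.norm(logistic(t, *popt) - f))
    return LogisticFit(rate=float(r), carrying_capacity=float(k),
                       initial_value=float(k / (1.0 + a)), residual_norm=residual)


# ---------------------------------------------------------------------------
# environment shift

def shift_environment(rho0: np.ndarray, target: np.ndarray, weight: float) -> np.ndarray:
    """Blend the external chemistry towards a target composition:

        rho'_i = (1 - w) rho_i(0) + w * target_i

    with the target rescaled so its total matches the total of rho0 — the
    blend biases molar proportions while conserving the total external
    concentration.  ``weight=0`` leaves the environment unchanged; the
    published experiment used w = 0.1.
    """
    rho0 = np.asarray(rho0, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if rho0.shape != target.shape:
        raise GardError("rho0 and target must have equal length")
    if not 0.0 <= weight <= 1.0:
        raise GardError("weight must lie in [0, 1]")
    total = target.sum()
    if total <= 0:
        raise GardError("target composition must be non-trivial")
    scaled = target * (rho0.sum() / total)
    return (1.0 - weight) * rho0 + weight * scaled


def run_shift_experiment(
    params: GardParameters,
    weight: float,
    switch_at: int,
    pop_size: int,
    n_splits: int,
    seed: int | None = None,
    target: int | np.ndarray | None = None,
    reference: list[Compotype] | None = None,
    record_every: int = 20,
    classify_threshold: float = 0.8,
    ref_generations: int = 500,
) -> ReactorHistory:
    """Two-phase reactor: at split ``switch_at`` the external concentrations
    are replaced by the blend towards the target compotype's composition.

    ``target`` may be a compotype index into the reference set (default: the
    minority compotype of the pre-run, i.e. the least-covered one) or an
    explicit composition.  With ``weight=0`` the run is bitwise identical to
    the unshifted control under the same seed.
    """
    if not 0 < switch_at <= n_splits:
        raise GardError("switch_at must fall inside the run")
    if reference is None:
        reference = reference_compotypes(params, seed, n_generations=ref_generations)
    if isinstance(target, np.ndarray):
        target_comp = target
    else:
        if not reference:
            raise GardError("no reference compotypes to target")
        if target is None:
            target = int(np.argmin([ct.frequency for ct in reference]))
        target_comp = reference[int(target)].centroid
    new_rho = shift_environment(params.rho_vec, target_comp, weight)
    return run_reactor(
        params, pop_size, n_splits, seed=seed, reference=reference,
        record_every=record_every, classify_threshold=classify_threshold,
        rho_schedule={switch_at: new_rho},
    )


def find_multi_compotype_params(
    template: GardParameters,
    seed: int,
    min_compotypes: int = 2,
    max_tries: int = 25,
    ref_generations: int = 400,
) -> tuple[GardParameters, list[Compotype]]:
    """Scan matrix seeds (deterministically derived from ``seed``) until a
    beta matrix whose reference set holds at least ``min_compotypes``
    compotypes is found.

    Multi-compotype matrices are the substrate of takeover and
    environment-shift experiments; a single-compotype landscape has nothing
    to select between.
    """
    from .model_core import sample_beta

    for k in range(max_tries):
        beta = sample_beta(template.n_types, template.beta.mu, template.beta.sigma,
                           seed=derive_seed(seed, f"shift-beta-{k}"))
        params = template.with_(beta=beta)
        reference = reference_compotypes(params, seed, n_generations=ref_generations)
        if len(reference) >= min_compotypes:
            return params, reference
    raise GardError(
        f"no matrix with >= {min_compotypes} compotypes in {max_tries} tries"
    )


# ---------------------------------------------------------------------------
# depletion screen

@dataclass(frozen=True)
class ScreenResult:
    """Per-(matrix, compound) outcome of the environmental depletion screen."""

    table: pd.DataFrame              # matrix, compound, ratio, best_similarity, stalled
    neutral_band: tuple[float, float] = (0.79, 1.25)

    def summary(self) -> dict:
        r = self.table["ratio"].to_numpy()
        lo, hi = self.neutral_band
        return {
            "n": int(r.size),
            "fraction_neutral": float(np.mean((r >= lo) & (r <= hi))),
            "fraction_diminished": float(np.mean(r < lo)),
            "fraction_enhanced": float(np.mean(r > hi)),
            "max_ratio": float(r.max()) if r.size else float("nan"),
            "min_ratio": float(r.min()) if r.size else float("nan"),
        }

    def histogram(self, bins=None) -> tuple[np.ndarray, np.ndarray]:
        if bins is None:
            lo, hi = self.neutral_band
            bins = [0.0, 0.25, 0.5, lo, hi, 2.0, 4.0, np.inf]
        return np.histogram(self.table["ratio"].to_numpy(), bins=bins)


def _trace_growth_and_episodes(params, n_generations, seed, threshold, min_length):
    trace = run_trace(params, n_generations, seed=seed)
    episodes = detect_composomes(trace, threshold=threshold, min_length=min_length)
    return trace.growth_rate(), episodes


def depletion_screen(
    params: GardParameters,
    n_matrices: int,
    n_generations: int = 200,
    seed: int | None = None,
    threshold: float = 0.9,
    min_length: int = 5,
) -> ScreenResult:
    """For each of ``n_matrices`` beta matrices, deplete each compound in turn
    and compare single-lineage growth rates after vs before.

    Growth rate is splits per unit simulated time.  For traces with detected
    composomes the pair of maximal compositional similarity between a
    composome before depletion and one after is reported.  Stalled or extinct
    depleted runs are recorded with ratio 0 and flagged.
    """
    from .model_core import sample_beta

    if n_matrices < 1:
        raise GardError("n_matrices must be >= 1")
    rows = []
    base_seed = seed or 0
    for m in range(n_matrices):
        beta = sample_beta(params.n_types, params.beta.mu, params.beta.sigma,
                           seed=derive_seed(base_seed, f"screen-beta-{m}"))
        p0 = params.with_(beta=beta)
        trace_seed = derive_seed(base_seed, f"screen-trace-{m}")
        try:
            rate0, eps0 = _trace_growth_and_episodes(p0, n_generations, trace_seed,
                                                     threshold, min_length)
        except StalledGrowthError:
            continue
        if rate0 <= 0:
            continue
        cents0 = [e.mean_composition for e in eps0]
        for compound in range(p0.n_types):
            p1 = p0.with_(beta=deplete_compound(beta, compound))
            stalled = False
            best_h = np.nan
            try:
                rate1, eps1 = _trace_growth_and_episodes(p1, n_generations, trace_seed,
                                                         threshold, min_length)
                ratio = rate1 / rate0
                if cents0 and eps1:
                    best_h = max(
                        similarity_H(c0, e1.mean_composition)
                        for c0 in cents0 for e1 in eps1
                    )
            except StalledGrowthError:
                ratio = 0.0
                stalled = True
            rows.append({
                "matrix": m,
                "compound": compound,
                "ratio": float(ratio),
                "best_similarity": float(best_h),
                "stalled": stalled,
            })
    return ScreenResult(pd.DataFrame(rows))
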