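"""Compositional similarity, composome/compotype detection, and information
metrics.

Similarity between compositions is the normalised dot product H (the cosine
of the angle between compositional vectors).  A composome is a run of
consecutive generations whose compositions stay mutually similar — the
quasi-stationary states in which an assembly grows homeostatically and
therefore reproduces.  Compotypes are clusters of similar composome episodes.

The information operations quantify how much can be encoded in a composition:
the number of multisets of size N over N_G types (compositional information)
versus the number of sequences of length N (sequence information).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model_core import ChiralParameters, BetaMatrix, GardError

__all__ = [
    "Episode",
    "Compotype",
    "similarity_H",
    "carpet",
    "detect_composomes",
    "cluster_compotypes",
    "repertoire_size",
    "expected_repertoire",
    "entropy",
    "n_compositions",
    "information_bits",
    "canonical_composome",
    "antipode_similarity_M",
    "enantiomeric_excess",
]


# ---------------------------------------------------------------------------
# similarity

def similarity_H(x: np.ndarray, y: np.ndarray) -> float:
    """Normalised dot product H = x.y / (|x||y|), in [0, 1] for count vectors.

    Symmetric and scale-invariant: H compares compositional *direction*, which
    is exactly what homeostatic growth preserves.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise GardError("compositions must have equal length")
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise GardError("similarity undefined for a zero vector")
    return float(np.dot(x, y) / (nx * ny))


def _as_matrix(trace) -> np.ndarray:
    comps = getattr(trace, "compositions", trace)
    comps = np.asarray(comps, dtype=np.float64)
    if comps.ndim != 2:
        raise GardError("expected a (generations x types) matrix of compositions")
    return comps


def carpet(trace) -> np.ndarray:
    """The time-correlation "carpet": pairwise H between all generations.

    Symmetric with unit diagonal; contiguous high-similarity blocks along the
    diagonal are composomes, off-diagonal blocks reveal recurrences of the
    same compositional state.
    """
    comps = _as_matrix(trace)
    if comps.shape[0] < 2:
        raise GardError("carpet needs at least two generations")
    norms = np.linalg.norm(comps, axis=1)
    if np.any(norms == 0):
        raise GardError("carpet undefined with empty compositions")
    unit = comps / norms[:, None]
    sim = np.clip(unit @ unit.T, 0.0, 1.0)
    np.fill_diagonal(sim, 1.0)
    return sim


# ---------------------------------------------------------------------------
# composome episodes

@dataclass(frozen=True)
class Episode:
    """A maximal run of generations in a composome state."""

    start: int                       # first generation (inclusive)
    end: int                         # last generation (inclusive)
    mean_composition: np.ndarray
    min_similarity: float

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise GardError("episode end before start")
        object.__setattr__(self, "mean_composition",
                           np.asarray(self.mean_composition, dtype=np.float64))

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def n_mol(self) -> int:
        """Restricted repertoire of the episode (types with mean count > 1/2)."""
        return int(np.sum(self.mean_composition > 0.5))


def detect_composomes(
    trace,
    threshold: float = 0.9,
    min_length: int = 5,
    mode: str = "allpairs",
) -> list[Episode]:
    """Find maximal non-overlapping runs of >= ``min_length`` consecutive
    generations that form a composome.

    In the default ``allpairs`` mode every pair of generations inside a run
    must satisfy H >= threshold; in ``centroid`` mode each generation must
    reach the threshold against the running mean of the run.  Generations
    outside every episode are drift.
    """
    if not 0.0 < threshold <= 1.0:
        raise GardError("threshold must be in (0, 1]")
    if min_length < 2:
        raise GardError("min_length must be >= 2")
    if mode not in ("allpairs", "centroid"):
        raise GardError("mode must be 'allpairs' or 'centroid'")
    comps = _as_matrix(trace)
    n_gen = comps.shape[0]
    norms = np.linalg.norm(comps, axis=1)
    if np.any(norms == 0):
        raise GardError("composome detection undefined with empty compositions")
    unit = comps / norms[:, None]
    episodes: list[Episode] = []
    start = 0
    while start < n_gen:
        end = start
        while end + 1 < n_gen:
            candidate = end + 1
            if mode == "allpairs":
                ok = bool(np.all(unit[start:candidate] @ unit[candidate] >= threshold))
            else:
                centroid = comps[start:candidate].mean(axis=0)
                ok = similarity_H(centroid, comps[candidate]) >= threshold
            if not ok:
                break
            end = candidate
        if end - start + 1 >= min_length:
            block = comps[start:end + 1]
            sim = (block / np.linalg.norm(block, axis=1)[:, None])
            pairwise = sim @ sim.T
            episodes.append(Episode(start, end, block.mean(axis=0), float(pairwise.min())))
            start = end + 1
        else:
            start += 1
    return episodes


# ---------------------------------------------------------------------------
# compotypes

@dataclass(frozen=True)
class Compotype:
    """A cluster of similar composome episodes."""

    centroid: np.ndarray             # L1-normalised composition
    episodes: tuple[Episode, ...]
    frequency: float                 # fraction of generations covered

    def __post_init__(self) -> None:
        c = np.asarray(self.centroid, dtype=np.float64)
        total = c.sum()
        if total <= 0:
            raise GardError("compotype centroid must be non-trivial")
        object.__setattr__(self, "centroid", c / total)
        if not 0.0 <= self.frequency <= 1.0:
            raise GardError("frequency must lie in [0, 1]")

    @property
    def n_mol(self) -> int:
        """Restricted repertoire N_MOL of the centroid (types above 0.5 %)."""
        return int(np.sum(self.centroid > 0.005))


def cluster_compotypes(
    episodes: list[Episode],
    threshold: float = 0.9,
    n_generations: int | None = None,
) -> list[Compotype]:
    """Greedy time-ordered (first-fit) clustering of episodes into compotypes.

    An episode joins the first existing compotype whose centroid similarity
    reaches the threshold, otherwise it founds a new one; centroids are
    updated as running normalised means.  Deterministic and order-stable.
    """
    if not episodes:
        raise GardError("no episodes to cluster")
    if n_generations is None:
        n_generations = max(e.end for e in episodes) + 1
    centroids: list[np.ndarray] = []
    members: list[list[Episode]] = []
    for ep in episodes:
        x = ep.mean_composition / ep.mean_composition.sum()
        for k, centroid in enumerate(centroids):
            if similarity_H(centroid, x) >= threshold:
                members[k].append(ep)
                updated = np.mean([m.mean_composition / m.mean_composition.sum()
                                   for m in members[k]], axis=0)
                centroids[k] = updated / updated.sum()
                break
        else:
            centroids.append(x)
            members.append([ep])
    out = []
    for centroid, eps in zip(centroids, members):
        covered = sum(e.length for e in eps)
        out.append(Compotype(centroid, tuple(eps), covered / n_generations))
    return out


# ---------------------------------------------------------------------------
# repertoire statistics

def repertoire_size(x: np.ndarray) -> int:
    """N_MOL: the number of molecule types actually present (count > 0)."""
    x = np.asarray(x)
    if np.any(x < 0):
        raise GardError("composition must be non-negative")
    return int(np.count_nonzero(x))


def expected_repertoire(n_molecules: int, n_types: int) -> tuple[float, float]:
    """Mean and standard deviation of N_MOL for a random assembly.

    For N molecules drawn uniformly with replacement from N_G types, the
    number of distinct types D has (occupancy statistics, exact):

        q = (1 - 1/N_G)^N               P(a given type absent)
        E[D] = N_G (1 - q)
        Var[D] = N_G q (1 - q) + N_G (N_G - 1) (r - q^2),  r = (1 - 2/N_G)^N

    e.g. N = N_G = 100 gives 63.4 +/- 3.1: even a random assembly uses far
    from the full environmental repertoire.
    """
    if n_molecules < 1 or n_types < 1:
        raise GardError("n_molecules and n_types must be >= 1")
    q = (1.0 - 1.0 / n_types) ** n_molecules
    mean = n_types * (1.0 - q)
    if n_types == 1:
        return mean, 0.0
    r = (1.0 - 2.0 / n_types) ** n_molecules
    var = n_types * q * (1.0 - q) + n_types * (n_types - 1) * (r - q * q)
    return float(mean), float(math.sqrt(max(var, 0.0)))


def entropy(x: np.ndarray, base: float | None = None) -> float:
    """Shannon entropy of the molar fractions, S = -sum p_i ln p_i (nats).

    Composomes, with their restricted and skewed repertoires, have lower
    entropy than random assemblies: composome emergence is a local
    entropy-reducing (unmixing) transition.  ``base=2`` reports bits.
    """
    x = np.asarray(x, dtype=np.float64)
    total = x.sum()
    if total <= 0:
        raise GardError("entropy undefined for an empty composition")
    p = x[x > 0] / total
    s = float(-np.sum(p * np.log(p)))
    if base is not None:
        s /= math.log(base)
    return s


# ---------------------------------------------------------------------------
# information content

def n_compositions(n_molecules: int, n_types: int) -> int:
    """Exact count of distinct compositions: the multiset coefficient
    C(N + N_G - 1, N) (arbitrary precision).
    """
    if n_molecules < 0 or n_types < 1:
        raise GardError("need n_molecules >= 0 and n_types >= 1")
    return math.comb(n_molecules + n_types - 1, n_molecules)


def _log2_bigint(value: int) -> float:
    try:
        return math.log2(value)
    except OverflowError:  # beyond float range: use the top bits
        bits = value.bit_length()
        top = value >> max(bits - 64, 0)
        return math.log2(top) + max(bits - 64, 0)


def information_bits(n_molecules: int, n_types: int, kind: str = "compositional") -> float:
    """Information capacity in bits of an assembly (compositional) or a
    polymer (sequential, equal monomer frequencies).

    Compositional information log2 C(N+N_G-1, N) is always below the
    sequential N log2 N_G, but the two become asymptotically equal as the
    repertoire grows (N_G >> N) — in a diverse-enough chemistry, compositions
    encode almost as much as sequences.
    """
    if kind == "compositional":
        return _log2_bigint(n_compositions(n_molecules, n_types))
    if kind == "sequential":
        if n_molecules < 0 or n_types < 1:
            raise GardError("need n_molecules >= 0 and n_types >= 1")
        return n_molecules * math.log2(n_types)
    raise GardError("kind must be 'compositional' or 'sequential'")


# ---------------------------------------------------------------------------
# eigen-analysis

def canonical_composome(beta: BetaMatrix | np.ndarray, tie_tol: float = 1e-9) -> np.ndarray:
    """The leading eigenvector of beta, L1-normalised and non-negative.

    Linearising the growth dynamics shows incessant (fission-free) growth is
    attracted to the eigenvector of the largest eigenvalue — the canonical
    composome of the matrix.  For strictly positive matrices Perron-Frobenius
    guarantees a unique real leading eigenvalue with a positive eigenvector.
    """
    values = beta.values if isinstance(beta, BetaMatrix) else np.asarray(beta, dtype=np.float64)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise GardError("beta must be square")
    zero_rows = np.flatnonzero(values.sum(axis=1) == 0)
    if zero_rows.size:
        import warnings

        warnings.warn(
            f"matrix has {zero_rows.size} all-zero row(s) (post-cutoff?); "
            "the leading eigenvector may be degenerate",
            RuntimeWarning,
            stacklevel=2,
        )
    eigvals, eigvecs = np.linalg.eig(values)
    moduli = np.abs(eigvals)
    lead = int(np.argmax(moduli))
    others = np.delete(moduli, lead)
    if others.size and moduli[lead] > 0 and (moduli[lead] - others.max()) <= tie_tol * moduli[lead]:
        raise GardError("leading eigenvalue is degenerate (tied moduli)")
    vec = np.real(eigvecs[:, lead])
    if vec.sum() < 0:
        vec = -vec
    vec = np.clip(vec, 0.0, None)
    total = vec.sum()
    if total <= 0:
        raise GardError("leading eigenvector is trivial")
    return vec / total


# ---------------------------------------------------------------------------
# enantioselection metrics

def antipode_similarity_M(x: np.ndarray, chiral: ChiralParameters) -> float:
    """M = H(x, sigma(x)): similarity of a composition to its exact mirror
    image.  Racemic compositions have M = 1; a fully homochiral composition
    over distinct scaffolds has M = 0.
    """
    x = np.asarray(x, dtype=np.float64)
    return similarity_H(x, chiral.antipode(x))


def enantiomeric_excess(x: np.ndarray, chiral: ChiralParameters) -> float:
    """ee = |sum_D - sum_L| / (sum_D + sum_L) over all scaffolds, in [0, 1]."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] != chiral.n_types:
        raise GardError("composition length does not match chiral repertoire")
    d = float(x[chiral.d_indices()].sum())
    l = float(x[chiral.l_indices()].sum())
    if d + l == 0:
        raise GardError("enantiomeric excess undefined for an empty assembly")
    return abs(d - l) / (d + l)
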