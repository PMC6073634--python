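"""Domain types for GARD simulations and construction/editing of the mutual
catalysis matrix.

The graded autocatalysis replication domain (GARD) model describes a
non-covalent assembly of amphiphiles (a micelle or small vesicle) exchanging
molecules with its environment.  The state of an assembly is the compositional
vector ``n`` (counts of each of the N_G molecule types); the chemistry is
encoded in a square matrix ``beta`` whose entry ``beta[i, j]`` is the graded
rate enhancement exerted by an in-assembly molecule of type ``j`` on the
entry/exit reactions of type ``i``.

Matrix elements are drawn from a lognormal distribution, the standard
statistical stand-in for the heavy-tailed spectrum of mutual molecular
recognition strengths (receptor-affinity-distribution statistics): weak
catalysis is common, strong catalysis rare.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._rng import stream

__all__ = [
    "GardError",
    "Assembly",
    "BetaMatrix",
    "GardParameters",
    "ChiralParameters",
    "sample_beta",
    "apply_cutoff",
    "deplete_compound",
    "build_chiral_beta",
    "random_assembly",
]

#: lognormal defaults (natural-log scale) for the beta matrix
DEFAULT_MU = -4.0
DEFAULT_SIGMA = 4.0


class GardError(ValueError):
    """Base class for model-level errors."""


# ---------------------------------------------------------------------------
# assemblies

@dataclass(frozen=True)
class Assembly:
    """An integer compositional vector; the simulated protocell state."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 1:
            raise GardError("assembly counts must be a 1-D vector")
        if np.any(counts < 0):
            raise GardError("assembly counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def size(self) -> int:
        """Total molecule count N."""
        return int(self.counts.sum())

    @property
    def n_types(self) -> int:
        return self.counts.shape[0]

    def molar_fractions(self) -> np.ndarray:
        n = self.size
        if n == 0:
            raise GardError("empty assembly has no molar fractions")
        return self.counts / n


def random_assembly(n_molecules: int, n_types: int, rng: np.random.Generator) -> Assembly:
    """Seed an assembly: ``n_molecules`` drawn uniformly with replacement."""
    if n_molecules < 1:
        raise GardError("need at least one molecule")
    draws = rng.integers(0, n_types, n_molecules)
    return Assembly(np.bincount(draws, minlength=n_types))


# ---------------------------------------------------------------------------
# the beta matrix

@dataclass(frozen=True)
class BetaMatrix:
    """Square matrix of graded mutual rate enhancements beta_ij > 0.

    ``norm_scale`` is the mean element value at construction time; cutoff
    thresholds are expressed on the scale ``beta / norm_scale``.  Keeping the
    construction-time scale (rather than renormalising after each edit) makes
    cutoff application idempotent.
    """

    values: np.ndarray
    mu: float | None = None
    sigma: float | None = None
    seed: int | None = None
    norm_scale: float | None = None
    cutoff_history: tuple[float, ...] = ()
    depleted: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise GardError("beta matrix must be square")
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise GardError("beta elements must be finite and non-negative")
        object.__setattr__(self, "values", values)
        if self.norm_scale is None:
            object.__setattr__(self, "norm_scale", float(values.mean()) or 1.0)

    @property
    def n_types(self) -> int:
        return self.values.shape[0]

    def normalized(self) -> np.ndarray:
        """Elements divided by the construction-time mean element."""
        return self.values / self.norm_scale

    def column_strengths(self) -> np.ndarray:
        """Total outgoing catalysis per compound (column sums)."""
        return self.values.sum(axis=0)


def sample_beta(
    n_types: int,
    mu: float = DEFAULT_MU,
    sigma: float = DEFAULT_SIGMA,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> BetaMatrix:
    """Draw an ``n_types`` x ``n_types`` beta matrix, elements i.i.d.
    lognormal(mu, sigma) on the natural-log scale.

    The same (n_types, mu, sigma, seed) always yields a bitwise-identical
    matrix.  ``sigma=0`` degenerates to the constant matrix exp(mu).
    """
    if n_types < 1:
        raise GardError("n_types must be >= 1")
    if sigma < 0:
        raise GardError("sigma must be >= 0")
    if rng is None:
        rng = stream(seed, "beta")
    values = np.exp(rng.normal(mu, sigma, size=(n_types, n_types)))
    return BetaMatrix(values, mu=mu, sigma=sigma, seed=seed)


def apply_cutoff(beta: BetaMatrix, threshold: float) -> BetaMatrix:
    """Zero all elements whose normalised value falls below ``threshold``.

    Thresholding turns the fully connected graded network into a sparse one:
    with a judicious cutoff most random assemblies lose catalytic closure
    while composome members, which concentrate on strongly linked compounds,
    tend to keep it.  ``threshold=0`` returns the matrix unchanged.
    """
    if threshold < 0:
        raise GardError("cutoff threshold must be >= 0")
    values = beta.values.copy()
    values[beta.normalized() < threshold] = 0.0
    return replace(
        beta,
        values=values,
        norm_scale=beta.norm_scale,
        cutoff_history=beta.cutoff_history + (float(threshold),),
    )


def deplete_compound(beta: BetaMatrix, index: int, rho: np.ndarray | None = None) -> BetaMatrix:
    """Remove a compound from the operative repertoire by zeroing its entire
    beta row and column.

    This mimics environmental depletion of the compound: nothing catalyses it
    and it catalyses nothing.  Basal (uncatalysed) entry remains unless
    ``rho`` is supplied, in which case the corresponding external
    concentration is zeroed in place as well (off by default; the two edits
    are formally equivalent for the catalytic network itself).
    """
    n = beta.n_types
    if not 0 <= index < n:
        raise GardError(f"compound index {index} out of range for {n} types")
    values = beta.values.copy()
    values[index, :] = 0.0
    values[:, index] = 0.0
    if rho is not None:
        rho[index] = 0.0
    return replace(
        beta,
        values=values,
        norm_scale=beta.norm_scale,
        depleted=tuple(sorted(set(beta.depleted) | {index})),
    )


# ---------------------------------------------------------------------------
# chirality

@dataclass(frozen=True)
class ChiralParameters:
    """Bookkeeping for a repertoire of enantiomer pairs.

    ``n_scaffolds`` distinct molecular scaffolds, each present as a D and an L
    enantiomer, give a total repertoire of ``2 * n_scaffolds``.  Index ``i``
    and ``antipode_map[i]`` are mirror images of each other.
    """

    n_scaffolds: int
    antipode_map: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n_scaffolds < 1:
            raise GardError("need at least one scaffold")
        s = self.n_scaffolds
        amap = self.antipode_map
        if amap is None:
            amap = np.concatenate([np.arange(s, 2 * s), np.arange(0, s)])
        amap = np.asarray(amap, dtype=np.int64)
        if amap.shape != (2 * s,) or not np.array_equal(amap[amap], np.arange(2 * s)):
            raise GardError("antipode map must be an involution on 2*n_scaffolds indices")
        object.__setattr__(self, "antipode_map", amap)

    @property
    def n_types(self) -> int:
        return 2 * self.n_scaffolds

    def antipode(self, x: np.ndarray) -> np.ndarray:
        """The mirror image of a composition: counts of each D/L pair swapped."""
        x = np.asarray(x)
        if x.shape[-1] != self.n_types:
            raise GardError("composition length does not match chiral repertoire")
        return x[..., self.antipode_map]

    def d_indices(self) -> np.ndarray:
        return np.arange(self.n_scaffolds)

    def l_indices(self) -> np.ndarray:
        return np.arange(self.n_scaffolds, 2 * self.n_scaffolds)


def build_chiral_beta(
    n_scaffolds: int,
    mu: float = DEFAULT_MU,
    sigma: float = DEFAULT_SIGMA,
    seed: int | None = None,
) -> tuple[BetaMatrix, ChiralParameters]:
    """Sample a mirror-symmetric beta matrix over D/L enantiomer pairs.

    Physics cannot distinguish the two mirror worlds, so the matrix must obey
    beta(i, j) == beta(sigma(i), sigma(j)) exactly, where sigma swaps each
    enantiomer pair.  Within-handedness (D on D / L on L) and cross-handedness
    (D on L / L on D) blocks are sampled independently from the same lognormal
    as :func:`sample_beta`; symmetry then fixes the mirrored blocks.
    """
    if n_scaffolds < 1:
        raise GardError("n_scaffolds must be >= 1")
    if sigma < 0:
        raise GardError("sigma must be >= 0")
    rng = stream(seed, "chiral-beta")
    same = np.exp(rng.normal(mu, sigma, size=(n_scaffolds, n_scaffolds)))  # D-on-D = L-on-L
    cross = np.exp(rng.normal(mu, sigma, size=(n_scaffolds, n_scaffolds)))  # D-on-L = L-on-D
    values = np.block([[same, cross], [cross, same]])
    beta = BetaMatrix(values, mu=mu, sigma=sigma, seed=seed)
    return beta, ChiralParameters(n_scaffolds)


# ---------------------------------------------------------------------------
# kinetic parameter sets

@dataclass(frozen=True)
class GardParameters:
    """Full kinetic specification of a GARD simulation.

    Rates follow the GARD rate law: with catalytic factor
    ``C_i = 1 + (1/N) * sum_j beta_ij n_j`` the entry propensity of type
    ``i`` is ``k_f_i * rho_i * N * C_i`` and its exit propensity is
    ``k_b_i * n_i * C_i``.  The same factor multiplies both directions, so
    catalysis accelerates equilibration without shifting the per-type
    equilibrium constant ``K_i = k_f_i / k_b_i``.

    Defaults place the chemistry in the entry-dominated regime
    (``K_i * rho_i = 2 > 1``): amphiphile joining is net downhill at every
    composition, exits occur at a rate that supplies compositional mutations.
    """

    beta: BetaMatrix
    n_max: int = 100
    n_min: int | None = None
    k_f: float | np.ndarray = 1.0
    k_b: float | np.ndarray = 1.0
    rho: float | np.ndarray = 2.0
    seed: int | None = None
    supply_mode: str = "infinite"           # "infinite" | "finite"
    supply_budget: int | None = None        # total external molecules, finite mode
    fission_mode: bool = True
    max_steps_per_growth: int = 10_000_000

    def __post_init__(self) -> None:
        if self.n_max < 2:
            raise GardError("n_max must be >= 2")
        if self.n_min is None:
            object.__setattr__(self, "n_min", self.n_max // 2)
        if not 1 <= self.n_min <= self.n_max:
            raise GardError("need 1 <= n_min <= n_max")
        if self.supply_mode not in ("infinite", "finite"):
            raise GardError("supply_mode must be 'infinite' or 'finite'")
        if self.supply_mode == "finite" and (self.supply_budget is None or self.supply_budget <= 0):
            raise GardError("finite supply requires a positive supply_budget")
        for name in ("k_f", "k_b", "rho"):
            vec = np.broadcast_to(np.asarray(getattr(self, name), dtype=np.float64), (self.n_types,))
            if np.any(vec < 0) or not np.all(np.isfinite(vec)):
                raise GardError(f"{name} must be finite and non-negative")
        if np.all(self.k_f_vec == 0) or np.all(self.rho_vec == 0):
            raise GardError("basal entry rates must not vanish everywhere")

    @property
    def n_types(self) -> int:
        return self.beta.n_types

    @property
    def k_f_vec(self) -> np.ndarray:
        return np.ascontiguousarray(np.broadcast_to(np.asarray(self.k_f, dtype=np.float64), (self.n_types,)))

    @property
    def k_b_vec(self) -> np.ndarray:
        return np.ascontiguousarray(np.broadcast_to(np.asarray(self.k_b, dtype=np.float64), (self.n_types,)))

    @property
    def rho_vec(self) -> np.ndarray:
        return np.ascontiguousarray(np.broadcast_to(np.asarray(self.rho, dtype=np.float64), (self.n_types,)))

    @property
    def equilibrium_constants(self) -> np.ndarray:
        """K_i = k_f_i / k_b_i (per-type, concentration units)."""
        with np.errstate(divide="ignore"):
            return self.k_f_vec / self.k_b_vec

    def with_(self, **changes) -> "GardParameters":
        return replace(self, **changes)

    def snapshot(self) -> dict:
        """A JSON-serialisable record of the parameter set (for provenance)."""

        def _scalar_or_list(v):
            arr = np.asarray(v)
            return float(arr) if arr.ndim == 0 else [float(x) for x in arr]

        return {
            "n_types": self.n_types,
            "n_max": self.n_max,
            "n_min": self.n_min,
            "k_f": _scalar_or_list(self.k_f),
            "k_b": _scalar_or_list(self.k_b),
            "rho": _scalar_or_list(self.rho),
            "seed": self.seed,
            "supply_mode": self.supply_mode,
            "supply_budget": self.supply_budget,
            "fission_mode": self.fission_mode,
            "beta": {
                "mu": self.beta.mu,
                "sigma": self.beta.sigma,
                "seed": self.beta.seed,
                "norm_scale": self.beta.norm_scale,
                "cutoff_history": list(self.beta.cutoff_history),
                "depleted": list(self.beta.depleted),
            },
        }
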