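"""Deterministic generation of test inputs.

Everything the test suite (or a user experimenting with the analysis tools)
needs can be generated locally from a seed: canned beta matrices, short
traces, traces with a planted composome block inside noise, and noisy
logistic frequency series.  Same seed, same files, no downloads.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import stream
from .config import RunConfig
from .dynamics import Trace, run_trace
from .io import write_beta_csv, write_table_csv, write_trace_csv
from .model_core import GardError, sample_beta

__all__ = [
    "make_fixture",
    "planted_composome_trace",
    "logistic_series",
]

KINDS = ("beta", "trace", "planted-composome", "logistic-series")


def planted_composome_trace(
    n_generations: int = 40,
    n_types: int = 100,
    n_max: int = 100,
    block_start: int = 15,
    block_length: int = 10,
    seed: int = 0,
) -> tuple[np.ndarray, tuple[int, int]]:
    """Compositions that are i.i.d. random except for a planted block of
    near-identical compositions; returns (compositions, (start, end)).

    Random size-N_MAX assemblies over a large repertoire are nearly mutually
    orthogonal, so the planted block is the only composome-like episode.
    """
    if block_start + block_length > n_generations:
        raise GardError("planted block does not fit in the trace")
    rng = stream(seed, "planted")
    comps = np.zeros((n_generations, n_types), dtype=np.int64)
    for g in range(n_generations):
        comps[g] = np.bincount(rng.integers(0, n_types, n_max), minlength=n_types)
    motif = np.zeros(n_types, np.int64)
    members = rng.choice(n_types, size=8, replace=False)
    motif[members] = np.array([30, 20, 15, 12, 10, 6, 4, 3])
    for g in range(block_start, block_start + block_length):
        wobble = np.bincount(rng.choice(members, size=4), minlength=n_types)
        comps[g] = motif + wobble
    return comps, (block_start, block_start + block_length - 1)


def logistic_series(
    n_points: int = 200,
    carrying_capacity: float = 0.6,
    rate: float = 0.05,
    initial_value: float = 0.01,
    noise: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """A logistic frequency curve f(t) = K / (1 + A e^(-rt)) with optional
    i.i.d. Gaussian noise, clipped to [0, 1]."""
    t = np.arange(n_points, dtype=float)
    a = carrying_capacity / initial_value - 1.0
    f = carrying_capacity / (1.0 + a * np.exp(-rate * t))
    if noise > 0:
        f = np.clip(f + stream(seed, "logistic").normal(0.0, noise, n_points), 0.0, 1.0)
    return pd.DataFrame({"t": t, "frequency": f})


def make_fixture(kind: str, outdir: str | Path, seed: int = 0,
                 config: RunConfig | None = None, **overrides) -> Path:
    """Write one deterministic fixture file of the given kind and return its
    path.  ``overrides`` tweak the generating parameters."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config is None:
        config = RunConfig(seed=seed)
    if kind == "beta":
        beta = sample_beta(overrides.get("n_types", config.n_types),
                           overrides.get("mu", config.mu),
                           overrides.get("sigma", config.sigma), seed=seed)
        return write_beta_csv(beta, outdir / f"beta_seed{seed}.csv")
    if kind == "trace":
        params = config.to_params()
        trace = run_trace(params, overrides.get("n_generations", 50), seed=seed)
        return write_trace_csv(trace, outdir / f"trace_seed{seed}.csv")
    if kind == "planted-composome":
        comps, (start, end) = planted_composome_trace(seed=seed, **{
            k: v for k, v in overrides.items()
            if k in ("n_generations", "n_types", "n_max", "block_start", "block_length")
        })
        params = config.to_params()
        trace = Trace(comps, np.arange(1.0, len(comps) + 1.0), params, seed)
        path = write_trace_csv(trace, outdir / f"planted_seed{seed}.csv")
        (outdir / f"planted_seed{seed}.block.txt").write_text(f"{start} {end}\n")
        return path
    if kind == "logistic-series":
        frame = logistic_series(seed=seed, **{
            k: v for k, v in overrides.items()
            if k in ("n_points", "carrying_capacity", "rate", "initial_value", "noise")
        })
        return write_table_csv(frame, outdir / f"logistic_seed{seed}.csv",
                               kind="logistic-series", meta={"seed": seed})
    raise GardError(f"unknown fixture kind {kind!r}; known: {KINDS}")
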