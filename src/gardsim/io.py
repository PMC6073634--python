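"""Reading and writing of beta matrices, traces and analysis tables.

All tables are plain delimited text with a ``#``-prefixed header block that
carries provenance (parameters, seed, matrix metadata) as one JSON line, so
every file can be traced back to — and regenerated from — its run
configuration.  Compound identifiers in files are 1-based; in memory all
indices are 0-based.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .compostats import Compotype, Episode
from .dynamics import Trace
from .model_core import BetaMatrix, GardParameters

__all__ = [
    "write_beta_csv",
    "read_beta_csv",
    "write_trace_csv",
    "read_trace_csv",
    "write_trace_json",
    "write_episodes_csv",
    "write_compotypes_csv",
    "write_table_csv",
]


def _header_lines(kind: str, meta: dict) -> str:
    return f"# gardsim {kind}\n# provenance: {json.dumps(meta, sort_keys=True)}\n"


def _read_provenance(path: Path) -> dict:
    with open(path) as fh:
        for line in fh:
            if line.startswith("# provenance:"):
                return json.loads(line.split(":", 1)[1])
            if not line.startswith("#"):
                break
    return {}


# ---------------------------------------------------------------------------
# beta matrices

def write_beta_csv(beta: BetaMatrix, path: str | Path) -> Path:
    """Write a beta matrix as CSV with a header row of 1-based compound ids."""
    path = Path(path)
    meta = {
        "mu": beta.mu, "sigma": beta.sigma, "seed": beta.seed,
        "norm_scale": beta.norm_scale,
        "cutoff_history": list(beta.cutoff_history),
        "depleted": [i + 1 for i in beta.depleted],
    }
    ids = [str(i + 1) for i in range(beta.n_types)]
    with open(path, "w") as fh:
        fh.write(_header_lines("beta-matrix", meta))
        fh.write("," + ",".join(ids) + "\n")
        for i, row in enumerate(beta.values):
            fh.write(ids[i] + "," + ",".join(f"{v:.10g}" for v in row) + "\n")
    return path


def read_beta_csv(path: str | Path) -> BetaMatrix:
    path = Path(path)
    meta = _read_provenance(path)
    frame = pd.read_csv(path, comment="#", index_col=0)
    values = frame.to_numpy(dtype=np.float64)
    return BetaMatrix(
        values,
        mu=meta.get("mu"),
        sigma=meta.get("sigma"),
        seed=meta.get("seed"),
        norm_scale=meta.get("norm_scale"),
        cutoff_history=tuple(meta.get("cutoff_history", ())),
        depleted=tuple(i - 1 for i in meta.get("depleted", ())),
    )


# ---------------------------------------------------------------------------
# traces

def _trace_meta(trace: Trace) -> dict:
    return {"seed": trace.seed, "params": trace.params.snapshot()}


def write_trace_csv(trace: Trace, path: str | Path) -> Path:
    """Tidy long format: one row per (generation, compound) with count > 0."""
    path = Path(path)
    gen, comp = np.nonzero(trace.compositions)
    frame = pd.DataFrame({
        "generation": gen,
        "time": trace.times[gen],
        "compound": comp + 1,
        "count": trace.compositions[gen, comp],
    })
    with open(path, "w") as fh:
        fh.write(_header_lines("trace", _trace_meta(trace)))
        frame.to_csv(fh, index=False)
    return path


def read_trace_csv(path: str | Path, n_types: int | None = None,
                   params: GardParameters | None = None) -> Trace:
    path = Path(path)
    meta = _read_provenance(path)
    frame = pd.read_csv(path, comment="#")
    n_gen = int(frame["generation"].max()) + 1
    if n_types is None:
        n_types = (params.n_types if params is not None
                   else meta.get("params", {}).get("n_types")
                   or int(frame["compound"].max()))
    comps = np.zeros((n_gen, n_types), dtype=np.int64)
    comps[frame["generation"], frame["compound"] - 1] = frame["count"]
    times = np.zeros(n_gen)
    times[frame["generation"]] = frame["time"]
    if params is None:
        from .model_core import sample_beta

        snap = meta.get("params", {})
        beta_meta = snap.get("beta", {})
        beta = sample_beta(n_types, beta_meta.get("mu", -4.0),
                           beta_meta.get("sigma", 4.0), seed=beta_meta.get("seed"))
        params = GardParameters(
            beta=beta,
            n_max=snap.get("n_max", int(comps.sum(axis=1).max())),
            n_min=snap.get("n_min"),
            k_f=snap.get("k_f", 1.0) if np.isscalar(snap.get("k_f", 1.0)) else np.asarray(snap["k_f"]),
            k_b=snap.get("k_b", 1.0) if np.isscalar(snap.get("k_b", 1.0)) else np.asarray(snap["k_b"]),
            rho=snap.get("rho", 2.0) if np.isscalar(snap.get("rho", 2.0)) else np.asarray(snap["rho"]),
            seed=snap.get("seed"),
        )
    return Trace(comps, times, params, seed=meta.get("seed"))


def write_trace_json(trace: Trace, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "provenance": _trace_meta(trace),
        "times": [float(t) for t in trace.times],
        "compositions": trace.compositions.tolist(),
    }
    path.write_text(json.dumps(payload))
    return path


# ---------------------------------------------------------------------------
# analysis tables

def write_episodes_csv(episodes: list[Episode], path: str | Path,
                       meta: dict | None = None) -> Path:
    path = Path(path)
    rows = [{
        "episode": k,
        "start": e.start,
        "end": e.end,
        "length": e.length,
        "n_mol": e.n_mol,
        "min_similarity": e.min_similarity,
    } for k, e in enumerate(episodes)]
    with open(path, "w") as fh:
        fh.write(_header_lines("episodes", meta or {}))
        pd.DataFrame(rows).to_csv(fh, index=False)
    return path


def write_compotypes_csv(compotypes: list[Compotype], path: str | Path,
                         meta: dict | None = None) -> Path:
    path = Path(path)
    rows = []
    for k, ct in enumerate(compotypes):
        for compound in np.flatnonzero(ct.centroid > 0):
            rows.append({
                "compotype": f"C{k + 1}",
                "frequency": ct.frequency,
                "n_episodes": len(ct.episodes),
                "n_mol": ct.n_mol,
                "compound": int(compound) + 1,
                "centroid_fraction": float(ct.centroid[compound]),
            })
    with open(path, "w") as fh:
        fh.write(_header_lines("compotypes", meta or {}))
        pd.DataFrame(rows).to_csv(fh, index=False)
    return path


def write_table_csv(frame: pd.DataFrame, path: str | Path, kind: str = "table",
                    meta: dict | None = None, index: bool = False) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_lines(kind, meta or {}))
        frame.to_csv(fh, index=index)
    return path
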