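"""Run configuration: validated experiment descriptions loadable from
TOML/YAML, convertible to kinetic parameter sets.

Every output file embeds the originating configuration (including the seed)
so that any result can be regenerated from its own provenance block.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, Field, field_validator

from .model_core import BetaMatrix, GardParameters, sample_beta

__all__ = ["RunConfig", "load_config"]


class RunConfig(BaseModel):
    """Complete description of one experiment run."""

    experiment: Literal[
        "simulate", "reactor", "screen", "shift", "equilibrium",
        "chiral", "pgard", "info", "fixture",
    ] = "simulate"

    # repertoire and assembly size
    n_types: int = Field(100, ge=1)
    n_max: int = Field(100, ge=2)
    n_min: Optional[int] = Field(None, ge=1)

    # kinetics
    k_f: float = Field(1.0, gt=0)
    k_b: float = Field(1.0, gt=0)
    rho: float = Field(2.0, gt=0)

    # beta matrix statistics
    mu: float = -4.0
    sigma: float = Field(4.0, ge=0)
    beta_seed: Optional[int] = None
    cutoff: float = Field(0.0, ge=0)

    # simulation extent
    n_generations: int = Field(500, ge=1)
    seed: int = 0

    # analysis thresholds
    similarity_threshold: float = Field(0.9, gt=0, le=1)
    min_episode_length: int = Field(5, ge=2)
    compotype_threshold: float = Field(0.9, gt=0, le=1)
    classify_threshold: float = Field(0.8, gt=0, le=1)

    # reactor / shift
    pop_size: int = Field(100, ge=2)
    n_splits: int = Field(2000, ge=1)
    record_every: int = Field(20, ge=1)
    shift_weight: float = Field(0.1, ge=0, le=1)
    switch_at: Optional[int] = None

    # depletion screen
    n_matrices: int = Field(100, ge=1)

    # finite supply (equilibrium experiment)
    supply_budget: int = Field(2000, ge=1)
    max_events: int = Field(400_000, ge=1)
    sample_every: int = Field(500, ge=1)

    # P-GARD
    dimer_k_f: float = Field(0.0, ge=0)
    dimer_k_b: float = Field(0.0, ge=0)

    # chiral
    n_scaffolds: int = Field(100, ge=1)

    # output
    out: Optional[str] = None

    @field_validator("n_max")
    @classmethod
    def _even_for_fission(cls, v: int) -> int:
        if v % 2 != 0:
            raise ValueError("n_max must be even (fission produces exact halves)")
        return v

    def beta_matrix(self) -> BetaMatrix:
        from .model_core import apply_cutoff

        beta = sample_beta(self.n_types, self.mu, self.sigma,
                           seed=self.beta_seed if self.beta_seed is not None else self.seed)
        if self.cutoff > 0:
            beta = apply_cutoff(beta, self.cutoff)
        return beta

    def to_params(self, beta: BetaMatrix | None = None,
                  supply_mode: str = "infinite",
                  fission_mode: bool = True) -> GardParameters:
        return GardParameters(
            beta=beta if beta is not None else self.beta_matrix(),
            n_max=self.n_max,
            n_min=self.n_min,
            k_f=self.k_f,
            k_b=self.k_b,
            rho=self.rho,
            seed=self.seed,
            supply_mode=supply_mode,
            supply_budget=self.supply_budget if supply_mode == "finite" else None,
            fission_mode=fission_mode,
        )

    def provenance(self) -> str:
        """Single-line JSON record embedded in output headers."""
        return json.dumps(self.model_dump(), sort_keys=True)


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from a TOML or YAML file (by extension)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".toml":
        import tomllib

        data = tomllib.loads(text)
    elif path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(text)
    elif path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        raise ValueError(f"unrecognised config format: {path.suffix}")
    return RunConfig.model_validate(data)
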