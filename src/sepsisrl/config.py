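"""Run configuration: one strict YAML file drives the whole experiment.

A ``RunConfig`` nests the per-stage parameter models and a single global
seed that fans out deterministically to per-stage seeds. A stage whose
``seed`` field is set explicitly in the file keeps it; otherwise the
stage seed is derived from (global seed, stage index), so changing only
the evaluation seed leaves simulation, preprocessing, and training
untouched.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .actions import RewardParams
from .agent import AgentConfig
from .cohort import SimParams
from .errors import ParseError
from .preprocess import PreprocessConfig

__all__ = ["EvalConfig", "RunConfig", "validate_config", "load_config", "stage_seed"]

_STAGE_INDEX = {"simulate": 0, "preprocess": 1, "agent": 2, "evaluation": 3}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    ss = np.random.SeedSequence([int(global_seed), _STAGE_INDEX[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


class EvalConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    min_count: int = Field(default=50, ge=1)
    test_fraction: float = Field(default=0.2, ge=0.0, lt=1.0)
    seed: int = 0


class RunConfig(BaseModel):
    """Full experiment configuration; every field has a default."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    out_dir: str = "runs/latest"
    sim: SimParams = Field(default_factory=lambda: SimParams(n_patients=500))
    preprocess: PreprocessConfig = Field(default_factory=PreprocessConfig)
    reward: RewardParams = Field(default_factory=RewardParams)
    agent: AgentConfig = Field(default_factory=AgentConfig)
    evaluation: EvalConfig = Field(default_factory=EvalConfig)

    def resolve_seeds(self) -> "RunConfig":
        """Fill unset stage seeds from the global seed; explicit ones win."""
        cfg = self.model_copy(deep=True)
        if "seed" not in cfg.sim.model_fields_set:
            cfg.sim.seed = stage_seed(cfg.seed, "simulate")
        if "seed" not in cfg.preprocess.model_fields_set:
            cfg.preprocess.seed = stage_seed(cfg.seed, "preprocess")
        if "seed" not in cfg.agent.model_fields_set:
            cfg.agent.seed = stage_seed(cfg.seed, "agent")
        if "seed" not in cfg.evaluation.model_fields_set:
            cfg.evaluation.seed = stage_seed(cfg.seed, "evaluation")
        return cfg


def _format_errors(exc: ValidationError) -> list[str]:
    out = []
    for err in exc.errors():
        path = ".".join(str(p) for p in err["loc"]) or "<root>"
        out.append(f"{path}: {err['msg']}")
    return out


def validate_config(path: str | Path) -> tuple[RunConfig | None, list[str]]:
    """Parse and validate a YAML run config.

    Returns (config, []) on success or (None, errors) with one entry per
    offending field path; an unparseable file yields a single parse error.
    """
    path = Path(path)
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        return None, [f"could not parse {path}: {exc}"]
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        return None, [f"{path}: top level must be a mapping"]
    try:
        return RunConfig(**raw), []
    except ValidationError as exc:
        return None, _format_errors(exc)


def load_config(path: str | Path | None) -> RunConfig:
    """Strict load; raises ParseError listing every problem."""
    if path is None:
        return RunConfig()
    cfg, errors = validate_config(path)
    if cfg is None:
        raise ParseError("invalid config:\n  " + "\n  ".join(errors))
    return cfg
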