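"""Run configuration: schema-validated YAML with defaults echoed back.

One config dialect for all three engines; unknown keys are rejected by name.
CLI flags override config-file keys (the CLI layer merges before validation).
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

__all__ = ["RunConfig", "CircuitOptimizeParams", "CellSimParams", "DirevoParams",
           "ConfigError", "load_config", "config_from_dict"]


class ConfigError(ValueError):
    """Invalid run configuration; the message names the offending key."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CircuitOptimizeParams(_Strict):
    topology: str = "iffl"  # named topology or a topology file path
    n_circuits: int = Field(default=8, ge=1)
    steps: int = Field(default=500, ge=1)
    lr: float = Field(default=0.05, ge=0.0)
    dt: float = Field(default=0.01, gt=0.0)
    u1: float = Field(default=1.0, gt=0.0)
    u2: float = Field(default=1.5, gt=0.0)
    t_step: float = Field(default=50.0, gt=0.0)
    t_end: float = Field(default=100.0, gt=0.0)
    s_min: float = Field(default=0.5, gt=0.0)
    w: float = Field(default=1.0, gt=0.0)


class CellSimParams(_Strict):
    model: str = "bundled"  # 'bundled' or a model file path
    t_end: float = Field(default=1.0, gt=0.0)
    tau: float = Field(default=1e-4, gt=0.0)
    n_traj: int = Field(default=48, ge=1)
    record_stride: int = Field(default=1, ge=1)


class DirevoParams(_Strict):
    N: int = Field(default=10, ge=1)
    K: int = Field(default=2, ge=0)
    A: int = Field(default=2, ge=2)
    pop: int = Field(default=100, ge=1)
    genes: int = Field(default=1, ge=1)
    mu: float = Field(default=0.5, ge=0.0, le=1.0)
    policy: str = "truncation:0.1"  # name[:param]
    generations: int = Field(default=50, ge=1)
    steps_per_iteration: int = Field(default=1, ge=1)
    replicates: int = Field(default=1, ge=1)
    adjacent: bool = False
    fixed_landscape: bool = False


_PARAM_MODELS = {
    "circuit-optimize": CircuitOptimizeParams,
    "cell-sim": CellSimParams,
    "direvo": DirevoParams,
}


class RunConfig(_Strict):
    engine: Literal["circuit-optimize", "cell-sim", "direvo"]
    seed: int = Field(default=0, ge=0)
    out_dir: str = "results"
    params: CircuitOptimizeParams | CellSimParams | DirevoParams | None = None

    def model_post_init(self, __context):
        model = _PARAM_MODELS[self.engine]
        if self.params is None:
            object.__setattr__(self, "params", model())
        elif not isinstance(self.params, model):
            raise ValueError(f"params block does not match engine {self.engine!r}")

    def echo(self) -> dict:
        """Fully defaulted config as a plain dict (round-trips via load)."""
        return {"engine": self.engine, "seed": self.seed, "out_dir": self.out_dir,
                "params": self.params.model_dump()}


def config_from_dict(raw: dict) -> RunConfig:
    engine = raw.get("engine")
    if engine not in _PARAM_MODELS:
        raise ConfigError(f"engine must be one of {sorted(_PARAM_MODELS)}, got {engine!r}")
    data = dict(raw)
    params = data.pop("params", None)
    try:
        if params is not None:
            data["params"] = _PARAM_MODELS[engine].model_validate(params)
        return RunConfig.model_validate(data)
    except ValidationError as err:
        first = err.errors()[0]
        loc = ".".join(str(p) for p in first["loc"]) or "<root>"
        raise ConfigError(f"invalid config key {loc!r}: {first['msg']}") from err


def load_config(path: str | Path) -> RunConfig:
    """Load, validate and default-fill a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    return config_from_dict(raw)
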