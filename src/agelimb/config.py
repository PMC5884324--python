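"""Run configuration, validation, and reproducibility manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, field_validator

from .errors import ConfigError


class RigConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    kind: str = "three_point"
    segment: str = "thigh"
    impactor_mass_kg: float = 6.25
    impactor_speed_ms: float | None = None   # m/s; rig default if omitted
    angular_rate: float = 1.0                # deg/ms
    preload_n: float = 400.0

    @field_validator("kind")
    @classmethod
    def _kind(cls, v: str) -> str:
        allowed = ("three_point", "four_point_knee", "limb_bending", "limb_shear")
        if v not in allowed:
            raise ValueError(f"rig kind must be one of {allowed}")
        return v


class RunConfig(BaseModel):
    """Validated top-level configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    ages: list[float] = [30.0, 70.0]
    rig: RigConfig = RigConfig()
    geometry_overrides: dict[str, dict] = {}
    site_multipliers: dict[str, dict] = {}
    seed: int = 0
    output_dir: str = "."

    @field_validator("ages")
    @classmethod
    def _ages(cls, v: list[float]) -> list[float]:
        for a in v:
            if not (20.0 <= a <= 90.0):
                raise ValueError(f"age {a} outside [20, 90]")
        return v


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    try:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return RunConfig(**raw)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc
    except yaml.YAMLError as exc:
        raise ConfigError(f"invalid YAML: {exc}") from exc


def config_hash(config: RunConfig) -> str:
    """SHA-256 of the canonical JSON form of a configuration."""
    canon = json.dumps(config.model_dump(), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()


def manifest(config: RunConfig) -> dict:
    """Reproducibility manifest: everything needed to re-run bit-identically."""
    from . import __version__

    return {
        "package": "agelimb",
        "version": __version__,
        "config": config.model_dump(),
        "config_sha256": config_hash(config),
        "seed": config.seed,
    }
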