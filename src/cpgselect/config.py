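"""Config-file plumbing for the end-to-end pipeline.

The YAML layout mirrors :class:`PipelineConfig`; nested sections (``synth``,
``ga``, ``gbr``, ``sfs``) map onto the corresponding parameter dataclasses.
All nested seeds are re-derived from the single master ``seed`` at run time,
so one number controls every source of randomness.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .data import DataError
from .fitness import GBRParams
from .ga import GAConfig
from .sfs import SFSConfig
from .synth import SynthConfig

__all__ = ["PipelineConfig", "ConfigError", "load_config", "config_hash"]


class ConfigError(ValueError):
    """Raised when a pipeline configuration is invalid."""


@dataclass
class PipelineConfig:
    """Everything needed for a full preprocess -> group -> GA -> SFS run."""

    # input: either a synthetic cohort or one-or-more matrix files
    synth: SynthConfig | None = None
    input_paths: list[str] = field(default_factory=list)
    input_format: str = "matrix"  # "matrix" | "geo"
    age_column: str = "age"
    geo_age_field: str = "age"

    # preprocessing
    split_ratio: float = 2.0 / 3.0
    z_threshold: float = 3.0
    #: "split-first" fits imputation/normalization on train only (no
    #: leakage); "preprocess-first" cleans the pooled data before splitting
    preprocess_mode: str = "split-first"

    # stage 1
    scheme: str = "three"  # "three" | "five" | "identity" | "auto"
    target_groups: int = 3  # used when scheme == "auto"
    n_components: int = 60

    # stage 2
    filter_k: int = 8000
    ga: GAConfig = field(default_factory=GAConfig)
    gbr: GBRParams = field(default_factory=GBRParams)
    sfs: SFSConfig = field(default_factory=SFSConfig)
    target_size: int = 100
    folds: int = 3
    parallelism_degree: int = 1

    seed: int = 0
    outdir: str | None = None

    def validate(self) -> None:
        if self.synth is None and not self.input_paths:
            raise ConfigError("either a synth section or input_paths is required")
        if self.synth is not None and self.input_paths:
            raise ConfigError("synth and input_paths are mutually exclusive")
        if self.input_format not in ("matrix", "geo"):
            raise ConfigError(f"unknown input_format {self.input_format!r}")
        if not 0 < self.split_ratio < 1:
            raise ConfigError("split_ratio must lie in (0, 1)")
        if self.preprocess_mode not in ("split-first", "preprocess-first"):
            raise ConfigError(f"unknown preprocess_mode {self.preprocess_mode!r}")
        if self.scheme not in ("three", "five", "identity", "auto"):
            raise ConfigError(f"unknown scheme {self.scheme!r}")
        if self.filter_k < 1:
            raise ConfigError("filter_k must be >= 1")
        if self.parallelism_degree < 1:
            raise ConfigError("parallelism_degree must be >= 1")
        try:
            if self.synth is not None:
                self.synth.validate()
            self.ga.validate()
            self.sfs.validate()
        except DataError as exc:
            raise ConfigError(str(exc)) from exc

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


_SECTIONS = {"synth": SynthConfig, "ga": GAConfig, "gbr": GBRParams, "sfs": SFSConfig}


def _build(cls, mapping: dict[str, Any], where: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")
    coerced = {
        k: tuple(v) if isinstance(v, list) else v
        for k, v in mapping.items()
    }
    try:
        return cls(**coerced)
    except (TypeError, DataError) as exc:
        raise ConfigError(f"bad {where} section: {exc}") from exc


def load_config(path: str | Path) -> PipelineConfig:
    """Parse a YAML pipeline config file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"no such config file: {path}")
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    kwargs: dict[str, Any] = {}
    for key, value in raw.items():
        if key in _SECTIONS:
            if not isinstance(value, dict):
                raise ConfigError(f"{path}: section {key!r} must be a mapping")
            kwargs[key] = _build(_SECTIONS[key], value, key)
        else:
            kwargs[key] = value
    config = _build(PipelineConfig, kwargs, "pipeline config")
    config.validate()
    return config


def config_hash(config: PipelineConfig) -> str:
    """Stable hash of the full configuration (stamped into artifacts)."""
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
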