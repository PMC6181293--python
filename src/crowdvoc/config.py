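"""Run configuration: a flat YAML file mapped onto dataclasses."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .evaluate import ModelConfig
from .features import FeatureConfig
from .preprocess import PreprocessConfig, RoomParams

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Everything an end-to-end run needs, in one place."""

    metadata_path: str
    compound_path: str
    out_dir: str = "results"
    room: RoomParams = field(default_factory=RoomParams)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    min_test_screenings: int = 8
    always_together: tuple[str, ...] = ()
    min_viewers: int = 0
    permutation_k: int = 50
    pvalue_variant: str = "add_one"
    exclude_ids: tuple[str, ...] = ()
    holm_correction: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.permutation_k < 1:
            raise ConfigError("permutation_k must be >= 1")
        if self.min_viewers < 0:
            raise ConfigError("min_viewers must be >= 0")

    def digest(self) -> str:
        """Stable hash of the configuration, stamped on every output."""
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


_SECTIONS = {
    "room": RoomParams,
    "preprocess": PreprocessConfig,
    "features": FeatureConfig,
    "model": ModelConfig,
}


def load_config(path) -> RunConfig:
    """Read a RunConfig from YAML; unknown keys are configuration errors."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must hold a mapping")
    kwargs: dict = {}
    for key, value in raw.items():
        if key in _SECTIONS:
            if not isinstance(value, dict):
                raise ConfigError(f"section {key!r} must be a mapping")
            try:
                kwargs[key] = _SECTIONS[key](**value)
            except TypeError as exc:
                raise ConfigError(f"section {key!r}: {exc}") from exc
        elif key in ("always_together", "exclude_ids"):
            kwargs[key] = tuple(value or ())
        else:
            kwargs[key] = value
    try:
        cfg = RunConfig(**kwargs)
    except TypeError as exc:
        raise ConfigError(f"bad configuration field: {exc}") from exc
    for p in (cfg.metadata_path, cfg.compound_path):
        if not Path(p).exists():
            raise ConfigError(f"input file not found: {p}")
    return cfg
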