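"""YAML run configuration: one merged, validated view of every knob.

A config file is a flat-ish YAML mapping with up to five sections —
``generator``, ``discriminator``, ``training``, ``metrics``, ``phantoms``
— plus top-level ``seed`` and ``verbosity``.  Unknown keys anywhere are
rejected by name; every field has a documented default, so the empty file
is a valid config.  The effective config is echoed to the log at load
time so a run's parameters are always on record.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .losses import LossWeights
from .metrics import WindowSpec
from .nn.models import DiscriminatorConfig, GeneratorConfig
from .phantoms import PhantomSpec
from .training import AblationFlags, TrainConfig

__all__ = ["RunConfig", "load_config"]

log = logging.getLogger("bpfuse")


@dataclass(frozen=True)
class MetricsConfig:
    abf_window: WindowSpec = field(default_factory=lambda: WindowSpec(8, 8))
    cv_window: WindowSpec = field(default_factory=lambda: WindowSpec(16, 16))
    cv_sigma: float = 1.5


@dataclass(frozen=True)
class RunConfig:
    """Merged view of all component configs, as loaded from one YAML file."""

    seed: int = 0
    verbosity: str = "info"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    discriminator: DiscriminatorConfig = field(default_factory=DiscriminatorConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    phantoms: PhantomSpec = field(default_factory=PhantomSpec)

    def resolved_training(self) -> TrainConfig:
        """Training config with the run-level seed and model configs folded in."""
        return replace(self.training, seed=self.seed,
                       generator=self.generator,
                       discriminator=self.discriminator)


def _build(cls, data: dict, path: str):
    """Construct dataclass ``cls`` from a mapping, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: expected a mapping, got {type(data).__name__}")
    known = {f.name: f for f in fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in known:
            raise ConfigurationError(f"unknown config key {path}.{key}")
        kwargs[key] = _coerce(cls, key, value, f"{path}.{key}")
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"{path}: {exc}") from exc


_NESTED = {
    (TrainConfig, "loss_weights"): LossWeights,
    (TrainConfig, "ablation"): AblationFlags,
    (TrainConfig, "generator"): GeneratorConfig,
    (TrainConfig, "discriminator"): DiscriminatorConfig,
    (MetricsConfig, "abf_window"): WindowSpec,
    (MetricsConfig, "cv_window"): WindowSpec,
}

_TUPLES = {
    (TrainConfig, "betas"), (TrainConfig, "split"),
    (DiscriminatorConfig, "channel_schedule"), (PhantomSpec, "size"),
}


def _coerce(cls, key, value, path):
    nested = _NESTED.get((cls, key))
    if nested is not None:
        return _build(nested, value, path)
    if (cls, key) in _TUPLES:
        if not isinstance(value, (list, tuple)):
            raise ConfigurationError(f"{path}: expected a list")
        return tuple(value)
    return value


_SECTIONS = {
    "generator": GeneratorConfig,
    "discriminator": DiscriminatorConfig,
    "training": TrainConfig,
    "metrics": MetricsConfig,
    "phantoms": PhantomSpec,
}


def load_config(path) -> RunConfig:
    """Load and validate a YAML config file; empty file -> all defaults."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    kwargs = {}
    for key, value in raw.items():
        if key in ("seed", "verbosity"):
            kwargs[key] = value
        elif key in _SECTIONS:
            kwargs[key] = _build(_SECTIONS[key], value, key)
        else:
            raise ConfigurationError(f"unknown config key {key}")
    cfg = RunConfig(**kwargs)
    log.info("effective config: %s", dataclasses.asdict(cfg))
    return cfg
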