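"""Run configuration: one structured file driving the whole workflow."""

from __future__ import annotations

from dataclasses import MISSING, dataclass, field, fields
from pathlib import Path

import yaml

from .exceptions import ConfigurationError

__all__ = ["RunConfig", "load_config", "default_config_path"]


@dataclass(frozen=True)
class GeneratorSection:
    n: int = 10_000
    fault_rate: float = 0.023
    seasonal_temp_amplitude: float = 1.2


@dataclass(frozen=True)
class PreprocessSection:
    split_mode: str = "chronological"
    core_threshold: float = 0.40


@dataclass(frozen=True)
class SVMSection:
    C: float = 10.0
    gamma: float = 0.05
    epsilon: float = 0.1


@dataclass(frozen=True)
class RFSection:
    n_trees: int = 100
    max_depth: int = 18
    mtry: int = 2


@dataclass(frozen=True)
class ANNSection:
    hidden_sizes: tuple[int, ...] = (128, 64)
    learning_rate: float = 0.001
    batch_size: int = 64
    l2_lambda: float = 0.0001
    max_epochs: int = 500
    early_stop_patience: int = 20


@dataclass(frozen=True)
class ModelsSection:
    svm: SVMSection = field(default_factory=SVMSection)
    rf: RFSection = field(default_factory=RFSection)
    ann: ANNSection = field(default_factory=ANNSection)


@dataclass(frozen=True)
class EntropySection:
    n_perm: int = 10
    estimator: str = "plug_in"
    state_window: str = "24h"


@dataclass(frozen=True)
class OperationSection:
    weeks: int = 12
    shock_rate_per_hour: float = 0.125
    shock_sd: float = 3.8
    unpredictable_sd: float = 10.5
    seasonal_amplitude: float = 2.0
    gain: float = 1.0


@dataclass(frozen=True)
class TeaSection:
    capex: float = 500_000.0
    operating_saving: float = 13.5
    capacity: float = 100.0
    discount_rate: float = 0.08
    lifetime: int = 10
    baseline_energy_intensity: float = 100.0


_SECTION_TYPES = {
    "generator": GeneratorSection,
    "preprocess": PreprocessSection,
    "models": ModelsSection,
    "entropy": EntropySection,
    "operation": OperationSection,
    "tea": TeaSection,
}


@dataclass(frozen=True)
class RunConfig:
    """Parsed run configuration; unknown keys are rejected."""

    generator: GeneratorSection = field(default_factory=GeneratorSection)
    preprocess: PreprocessSection = field(default_factory=PreprocessSection)
    models: ModelsSection = field(default_factory=ModelsSection)
    entropy: EntropySection = field(default_factory=EntropySection)
    operation: OperationSection = field(default_factory=OperationSection)
    tea: TeaSection = field(default_factory=TeaSection)
    seed: int = 42

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        kwargs = {}
        seed = data.pop("seed", 42)
        for name, typ in _SECTION_TYPES.items():
            section = data.pop(name, {})
            kwargs[name] = _build_section(typ, section, name)
        if data:
            raise ConfigurationError(f"unknown configuration keys: {sorted(data)}")
        return cls(seed=int(seed), **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _build_section(typ, data, name):
    if isinstance(data, typ):
        return data
    data = dict(data or {})
    allowed = {f.name: f for f in fields(typ)}
    kwargs = {}
    for key, value in data.items():
        if key not in allowed:
            raise ConfigurationError(f"unknown key {key!r} in section {name!r}")
        f = allowed[key]
        if isinstance(value, dict):
            default = f.default_factory() if f.default_factory is not MISSING else f.default
            kwargs[key] = _build_section(type(default), value, f"{name}.{key}")
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return typ(**kwargs)


def default_config_path() -> Path:
    return Path(__file__).parent / "data" / "default_config.yaml"


def load_config(path=None) -> RunConfig:
    """Load a run configuration (the packaged default when no path given)."""
    if path is None:
        return RunConfig.from_yaml(default_config_path())
    return RunConfig.from_yaml(path)
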