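"""Experiment configuration: one YAML-serializable object for the pipeline.

Defaults reproduce the reference protocol: N=50 window samples at 100 Hz,
0.05–35 Hz band-pass, three 30-unit LSTM layers, 300 epochs at batch 256,
amplitude gates 100–150 / 60–100 mmHg, 50-sample refractory separation,
5-second aggregation windows, and a 22/6/10-of-38-style participant split.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .model import ModelConfig, TrainConfig
from .preprocess import FilterSpec
from .synthetic import CohortConfig

__all__ = ["SimulatorConfig", "ExtractionConfig", "ExperimentConfig"]


@dataclass(frozen=True)
class SimulatorConfig:
    n_participants: int = 38
    duration: float = 480.0
    fs: float = 100.0
    master_seed: int = 7
    cohort: CohortConfig = field(default_factory=CohortConfig)


@dataclass(frozen=True)
class ExtractionConfig:
    sys_gate: tuple[float, float] = (100.0, 150.0)
    dia_gate: tuple[float, float] = (60.0, 100.0)
    refractory: int = 50          # samples
    window_s: float = 5.0


@dataclass(frozen=True)
class ExperimentConfig:
    simulator: SimulatorConfig = field(default_factory=SimulatorConfig)
    filter: FilterSpec = field(default_factory=FilterSpec)
    N: int = 50
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    split_fractions: tuple[float, float, float] = (22 / 38, 6 / 38, 10 / 38)
    split_seed: int = 7

    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)

    def to_dict(self) -> dict:
        def clean(x):
            if isinstance(x, dict):
                return {k: clean(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [clean(v) for v in x]
            return x
        return clean(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        sim = d.get("simulator", {})
        if isinstance(sim, dict):
            sim = dict(sim)
            cohort = sim.get("cohort", {})
            if isinstance(cohort, dict):
                cohort = {k: tuple(v) if isinstance(v, list) else v
                          for k, v in cohort.items()}
                sim["cohort"] = CohortConfig(**cohort)
            d["simulator"] = SimulatorConfig(**sim)
        if isinstance(d.get("filter"), dict):
            d["filter"] = FilterSpec(**d["filter"])
        if isinstance(d.get("model"), dict):
            d["model"] = ModelConfig(**d["model"])
        if isinstance(d.get("train"), dict):
            d["train"] = TrainConfig(**d["train"])
        ext = d.get("extraction", {})
        if isinstance(ext, dict):
            ext = {k: tuple(v) if isinstance(v, list) else v
                   for k, v in ext.items()}
            d["extraction"] = ExtractionConfig(**ext)
        if isinstance(d.get("split_fractions"), list):
            d["split_fractions"] = tuple(d["split_fractions"])
        return cls(**d)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "ExperimentConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(yaml.safe_load(text))
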