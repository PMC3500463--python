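"""Experiment configuration: one YAML-serializable object per run.

``ExperimentConfig.full_scale()`` encodes the canonical study constants
(1048 Hz acquisition, 256 Hz analysis rate, 0.5/30/50 Hz filters,
-2..65 ms excision with 250 ms context, +/-75 uV and 50 uV/step rejection,
-100..0 ms baseline, the 10-channel peri-occipital pool, 80-230 and
200-350 ms test windows at q = 0.05, TMS windows 96-119 / 156-179 /
236-259 ms, and the 25-block x 96-trial schedule); ``desk()`` and
``tiny()`` are proportionally reduced profiles for interactive use and
test fixtures.
"""

from __future__ import annotations

import dataclasses
from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class ScheduleConfig:
    n_blocks: int = 25
    trials_per_block: int = 96


@dataclass
class SimulationConfig:
    n_subjects: int = 11
    n_poor: int = 0
    sfreq: float = 1048.0
    iti_s: float = 2.0
    noise_scale: float = 1.0
    erp_noise_sd_uv: float = 0.2


@dataclass
class PreprocessConfig:
    highpass_hz: float = 0.5
    lowpass_hz: float = 30.0
    notch_hz: float = 50.0
    downsample_to_hz: float = 256.0
    excision_window_ms: tuple[float, float] = (-2.0, 65.0)
    excision_context_ms: float = 250.0
    tmin_s: float = -0.2
    tmax_s: float = 0.5
    baseline_ms: tuple[float, float] = (-100.0, 0.0)
    amp_uv: float = 75.0
    step_uv: float = 50.0
    apply_laplacian: bool = True


@dataclass
class StatsConfig:
    q: float = 0.05
    early_window_ms: tuple[float, float] = (80.0, 230.0)
    late_window_ms: tuple[float, float] = (200.0, 350.0)
    cumulative_window_ms: tuple[float, float] = (227.0, 313.0)
    rt_bounds_ms: tuple[float, float] = (100.0, 1500.0)
    min_accuracy: float = 0.67


@dataclass
class ExperimentConfig:
    """Full pipeline configuration; serializes losslessly to/from YAML."""

    seed: int = 0
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    @classmethod
    def full_scale(cls, seed: int = 0) -> "ExperimentConfig":
        """The full-scale study conditions (11 subjects x 200 trials/type)."""
        return cls(seed=seed)

    @classmethod
    def desk(cls, seed: int = 0) -> "ExperimentConfig":
        """A desk-scale profile: 5 subjects x 4 trials/type, full pipeline."""
        return cls(
            seed=seed,
            schedule=ScheduleConfig(n_blocks=2, trials_per_block=24),
            simulation=SimulationConfig(n_subjects=5),
        )

    @classmethod
    def tiny(cls, seed: int = 0) -> "ExperimentConfig":
        """The miniature fixture: 3 subjects x 2 trials/type."""
        return cls(
            seed=seed,
            schedule=ScheduleConfig(n_blocks=1, trials_per_block=24),
            simulation=SimulationConfig(n_subjects=3),
        )

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            with open(path, "w") as f:
                f.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "ExperimentConfig":
        if hasattr(source, "read"):
            raw = yaml.safe_load(source.read())
        else:
            try:
                with open(source) as f:
                    raw = yaml.safe_load(f.read())
            except (OSError, ValueError):
                raw = yaml.safe_load(source)
        def build(klass, d):
            fields = {f.name: f for f in dataclasses.fields(klass)}
            kwargs = {}
            for k, v in d.items():
                if k not in fields:
                    raise ValueError(f"unknown config key {k!r} for {klass.__name__}")
                if isinstance(v, list):
                    v = tuple(v)
                kwargs[k] = v
            return klass(**kwargs)

        return cls(
            seed=int(raw.get("seed", 0)),
            schedule=build(ScheduleConfig, raw.get("schedule", {})),
            simulation=build(SimulationConfig, raw.get("simulation", {})),
            preprocess=build(PreprocessConfig, raw.get("preprocess", {})),
            stats=build(StatsConfig, raw.get("stats", {})),
        )
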