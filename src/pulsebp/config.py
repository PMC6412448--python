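"""Pipeline configuration: nested sections, YAML round-trip, validation.

Every stage of the pipeline reads its settings from one
:class:`PipelineConfig`.  A single global seed drives all stages;
per-stage seeds are derived from it deterministically so one number
reproduces the entire run.  Unknown keys in a config file are rejected
rather than ignored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from pulsebp.emd import (
    DEFAULT_BEAT_BAND_HZ,
    DEFAULT_MAX_IMFS,
    DEFAULT_SD_THRESHOLD,
)
from pulsebp.simulate import SimulationConfig

__all__ = [
    "EMDSettings", "FeatureSettings", "ModelSettings", "EvalSettings",
    "PipelineConfig", "load_config", "save_config", "stage_seed",
]


@dataclass
class EMDSettings:
    sd_threshold: float = DEFAULT_SD_THRESHOLD
    max_imfs: int = DEFAULT_MAX_IMFS
    beat_band_hz: tuple[float, float] = DEFAULT_BEAT_BAND_HZ

    def __post_init__(self) -> None:
        if not 0 < self.sd_threshold < 1:
            raise ValueError("sd_threshold must be in (0, 1)")
        if self.max_imfs < 1:
            raise ValueError("max_imfs must be >= 1")
        lo, hi = self.beat_band_hz
        if not 0 < lo < hi:
            raise ValueError("beat_band_hz must satisfy 0 < low < high")


@dataclass
class FeatureSettings:
    ai_convention: str = "systolic_over_dicrotic"
    hr_bounds_bpm: tuple[float, float] = (40.0, 180.0)
    min_beats: int = 3

    def __post_init__(self) -> None:
        if self.ai_convention not in ("systolic_over_dicrotic",
                                      "dicrotic_over_systolic"):
            raise ValueError(f"unknown ai_convention {self.ai_convention!r}")
        if self.min_beats < 1:
            raise ValueError("min_beats must be >= 1")


@dataclass
class ModelSettings:
    algorithms: tuple[str, ...] = ("RFR", "GBR", "ABR")
    split_ratio: float = 0.8
    split_mode: str = "record"
    n_estimators: int = 100
    rfr_max_depth: int | None = None
    base_depth: int = 3
    learning_rate: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.split_ratio < 1:
            raise ValueError("split_ratio must be in (0, 1)")
        if self.split_mode not in ("record", "subject"):
            raise ValueError("split_mode must be 'record' or 'subject'")
        bad = set(self.algorithms) - {"RFR", "GBR", "ABR"}
        if bad:
            raise ValueError(f"unknown algorithms {sorted(bad)}")


@dataclass
class EvalSettings:
    thresholds_mmHg: tuple[float, ...] = (5.0, 10.0, 15.0)
    make_plots: bool = True

    def __post_init__(self) -> None:
        thr = np.asarray(self.thresholds_mmHg, dtype=float)
        if np.any(thr <= 0) or np.any(np.diff(thr) <= 0):
            raise ValueError("thresholds must be positive and increasing")


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    emd: EMDSettings = field(default_factory=EMDSettings)
    features: FeatureSettings = field(default_factory=FeatureSettings)
    model: ModelSettings = field(default_factory=ModelSettings)
    evaluation: EvalSettings = field(default_factory=EvalSettings)
    seed: int = 0
    outdir: str = "results"

    def with_seed(self, seed: int) -> "PipelineConfig":
        """Copy of the config re-rooted at a new global seed."""
        cfg = dataclasses.replace(self, seed=seed)
        cfg.simulation = dataclasses.replace(
            self.simulation, seed=stage_seed(seed, "simulate"))
        return cfg


#: stable stage names used for seed derivation
_STAGES = ("simulate", "split", "rfr", "gbr", "abr")


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed (< 2**31) from the single global seed."""
    ss = np.random.SeedSequence([int(global_seed), _STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _tupleize(value, like):
    """YAML gives lists; dataclass defaults use tuples."""
    if isinstance(like, tuple) and isinstance(value, list):
        return tuple(value)
    return value


def _build(cls, data: dict, context: str):
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ValueError(f"unknown key(s) in {context}: {sorted(unknown)}")
    defaults = cls()
    kwargs = {
        k: _tupleize(v, getattr(defaults, k)) for k, v in data.items()
    }
    return cls(**kwargs)


_SECTIONS = {
    "simulation": SimulationConfig,
    "emd": EMDSettings,
    "features": FeatureSettings,
    "model": ModelSettings,
    "evaluation": EvalSettings,
}


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML config file; missing sections take defaults."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    unknown = set(data) - set(_SECTIONS) - {"seed", "outdir"}
    if unknown:
        raise ValueError(f"{path}: unknown section(s) {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        kwargs[name] = _build(cls, data.get(name, {}) or {}, name)
    cfg = PipelineConfig(
        seed=int(data.get("seed", 0)),
        outdir=str(data.get("outdir", "results")),
        **kwargs,
    )
    return cfg.with_seed(cfg.seed)


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_listify(v) for v in obj]
    return obj


def save_config(config: PipelineConfig, path: str | Path) -> None:
    blob = _listify(dataclasses.asdict(config))
    Path(path).write_text(yaml.safe_dump(blob, sort_keys=False))
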