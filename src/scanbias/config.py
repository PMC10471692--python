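"""YAML configuration: geometry, simulator, detector and analysis blocks."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional

import yaml

from .detect import DetectorParams
from .geometry import ScreenGeometry
from .simulate import SimulatorConfig

__all__ = ["AnalysisConfig", "ScoringConfig", "PipelineConfig", "load_config"]


@dataclass(frozen=True)
class AnalysisConfig:
    bootstrap_B: int = 2000
    ci_level: float = 0.95
    horizon_frac: float = 0.5
    min_amplitude_deg: float = 1.0
    central_radius_deg: float = 1.93
    n_bins: int = 36
    eye: str = "right"


@dataclass(frozen=True)
class ScoringConfig:
    window_ms: int = 0


@dataclass(frozen=True)
class PipelineConfig:
    geometry: ScreenGeometry = field(default_factory=ScreenGeometry)
    simulator: SimulatorConfig = field(default_factory=SimulatorConfig)
    detector: DetectorParams = field(default_factory=DetectorParams)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)


def _build(cls, block: Optional[dict], **extra):
    block = dict(block or {})
    block.update(extra)
    names = {f.name for f in fields(cls)}
    unknown = set(block) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} option(s): {sorted(unknown)}")
    return cls(**block)


def load_config(path: Optional[str | Path]) -> PipelineConfig:
    """Load a pipeline configuration; a missing path yields all defaults."""
    raw: dict = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    geometry = _build(ScreenGeometry, raw.get("geometry"))
    sim_block = dict(raw.get("simulator") or {})
    if "amp_schedule" in sim_block:
        sim_block["amp_schedule"] = tuple(sim_block["amp_schedule"])
    simulator = _build(SimulatorConfig, sim_block, geometry=geometry)
    return PipelineConfig(
        geometry=geometry,
        simulator=simulator,
        detector=_build(DetectorParams, raw.get("detector")),
        analysis=_build(AnalysisConfig, raw.get("analysis")),
        scoring=_build(ScoringConfig, raw.get("scoring")),
    )
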