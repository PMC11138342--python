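"""YAML configuration loading for simulator and pipeline parameters.

A config file is a flat (optionally sectioned) key/value document.  Keys
mirror the dataclass field names; unknown keys are an error so typos do
not silently fall back to defaults.

Example::

    simulate:
      duration_s: 600
      concentration_per_ml: {green: 1000, orange: 1000}
    detect:
      bg_window_s: 5
      noise_window_s: 60
      k: 5
    match:
      speed_min_mm_s: 5
      speed_max_mm_s: 150
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .detect import DetectionParams
from .matching import MatchParams
from .pipeline import PipelineParams
from .simulate import SimConfig

__all__ = ["load_config", "load_sim_config", "load_pipeline_params"]


def _build(cls, data: dict, where: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown key(s) in {where}: {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path) -> dict:
    """Parse a YAML config into its raw section dictionaries."""
    with Path(path).open() as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return data


def load_sim_config(path: str | Path) -> SimConfig:
    data = load_config(path)
    section = data.get("simulate", data)
    return _build(SimConfig, dict(section), "simulate")


def load_pipeline_params(path: str | Path) -> PipelineParams:
    data = load_config(path)
    det = _build(DetectionParams, dict(data.get("detect", {})), "detect")
    match = _build(MatchParams, dict(data.get("match", {})), "match")
    rest = dict(data.get("classify", {}))
    fields = {f.name for f in dataclasses.fields(PipelineParams)}
    unknown = set(rest) - fields
    if unknown:
        raise ValueError(f"unknown key(s) in classify: {sorted(unknown)}")
    return PipelineParams(detection=det, match=match, **rest)
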