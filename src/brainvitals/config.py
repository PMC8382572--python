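"""YAML serialization for simulator and pipeline configuration objects."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .pipeline import PipelineConfig
from .simulate import CohortConfig, GroupSpec, MeasureSpec, NoiseConfig


def _tupled(d: dict, keys: tuple[str, ...]) -> dict:
    return {k: (tuple(v) if k in keys and isinstance(v, list) else v) for k, v in d.items()}


def save_config(config: CohortConfig | NoiseConfig | PipelineConfig, path: str | Path) -> None:
    payload = {"type": type(config).__name__, "params": asdict(config)}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_cohort_config(path: str | Path) -> CohortConfig:
    payload = yaml.safe_load(Path(path).read_text())
    if payload.get("type") != "CohortConfig":
        raise ValueError(f"{path} does not hold a CohortConfig")
    params = payload["params"]
    groups = []
    for g in params.pop("groups"):
        g["measures"] = {m: MeasureSpec(**spec) for m, spec in g.get("measures", {}).items()}
        groups.append(GroupSpec(**g))
    noise = NoiseConfig(**params.pop("noise")) if "noise" in params else NoiseConfig()
    return CohortConfig(groups=groups, noise=noise, **params)


def load_noise_config(path: str | Path) -> NoiseConfig:
    payload = yaml.safe_load(Path(path).read_text())
    if payload.get("type") != "NoiseConfig":
        raise ValueError(f"{path} does not hold a NoiseConfig")
    return NoiseConfig(**payload["params"])


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    payload = yaml.safe_load(Path(path).read_text())
    if payload.get("type") != "PipelineConfig":
        raise ValueError(f"{path} does not hold a PipelineConfig")
    params = payload["params"]
    for key in ("band_hz", "epoch_window_ms", "baseline_ms"):
        if key in params:
            params[key] = tuple(params[key])
    if "windows_ms" in params:
        params["windows_ms"] = {k: tuple(v) for k, v in params["windows_ms"].items()}
    return PipelineConfig(**params)
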