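"""Pipeline configuration with published defaults."""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the phase-estimation / gating / reconstruction pipeline.

    Defaults follow the values used throughout the reference experiments:
    HP penalty 6400, respiration low-pass 230 BPM, heart band 310-840 BPM,
    cutoff c = 0.2, gate multiple k = 2.0, kernel constants k_phi = 0.4 and
    k_L = 2.0.
    """

    fps: float = 233.0
    lambda_: float = 6400.0
    resp_lowpass_bpm: float = 230.0
    heart_band_bpm: tuple[float, float] = (310.0, 840.0)
    c: float = 0.2
    k: float = 2.0
    k_phi: float = 0.4
    k_L: float = 2.0
    one_sided: bool = True
    lowess_fraction: float = 0.3
    lowess_iterations: int = 3
    seed: int = 0

    def replace(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["heart_band_bpm"] = list(self.heart_band_bpm)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "heart_band_bpm" in d:
            d["heart_band_bpm"] = tuple(d["heart_band_bpm"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)
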