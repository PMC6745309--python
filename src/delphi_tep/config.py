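"""Run configuration: every tunable of the pipeline in one place.

Unknown keys are rejected so typos cannot silently fall back to defaults;
the effective configuration is echoed into every output directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    artifact_window_ms: tuple = (-2.0, 10.0)
    band_hz: tuple = (1.0, 80.0)
    notch_hz: float = 50.0
    resample_hz: float = 1000.0
    epoch_window_ms: tuple = (-500.0, 500.0)
    baseline_ms: tuple = (-300.0, -50.0)
    reject: dict = field(default_factory=lambda: {"amp_uv": 150.0, "flat_uv": 0.1})
    q_window_ms: tuple = (15.0, 300.0)
    freq_classes: dict = field(
        default_factory=lambda: {
            "baseline_max": 0.5,
            "inhibitory_lo": 1.0,
            "inhibitory_hi": 5.0,
            "excitatory_min": 20.0,
        }
    )
    stp_protocol: str = "inhibitory"
    io_feature: str = "q"
    min_trial_retention: float = 0.5
    classifier: dict = field(default_factory=lambda: {"min_regions": 4})
    seed: int = 0
    verbosity: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in d:
                continue
            v = d[f.name]
            kwargs[f.name] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        for k, v in out.items():
            if isinstance(v, tuple):
                out[k] = list(v)
        return out

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    def hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
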