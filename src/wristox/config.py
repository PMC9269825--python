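"""Run configuration: one serializable object that pins every knob.

A run's YAML echo plus the code version reproduces its outputs
bit-identically, because all randomness flows from the single seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Union

import yaml

from .synth import ErrorModel, PerfusionSettings
from .types import CalibrationCurve, QCThresholds


@dataclass
class ProtocolConfig:
    plateau_targets: List[float] = field(default_factory=lambda: [97.0, 92.0, 87.0, 82.0])
    plateau_duration: float = 150.0
    pre_wait: float = 30.0
    n_extractions: int = 8
    min_spacing: float = 20.0


@dataclass
class RunConfig:
    seed: int = 0
    n_subjects: int = 12
    fs: float = 50.0
    epoch_length: float = 10.0
    epoch_step: float = 5.0
    hr_bpm: float = 75.0
    wrist_sao2_bias: float = -1.5  # site difference encoded in wrist signals
    reference_error_sd_spo2: float = 1.0
    reference_error_sd_hr: float = 1.0
    pair_tolerance: float = 5.0
    curve: CalibrationCurve = field(default_factory=CalibrationCurve)
    thresholds: QCThresholds = field(default_factory=QCThresholds)
    perfusion: PerfusionSettings = field(default_factory=PerfusionSettings)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    error_model: ErrorModel = field(default_factory=ErrorModel)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        def sub(key, typ):
            if key in data and isinstance(data[key], dict):
                d = data[key]
                if typ in (QCThresholds,):
                    for k in ("dc_range", "ac_pp_range", "hr_valid", "spo2_valid"):
                        if k in d and isinstance(d[k], list):
                            d[k] = tuple(d[k])
                data[key] = typ(**d)
        sub("curve", CalibrationCurve)
        sub("thresholds", QCThresholds)
        sub("perfusion", PerfusionSettings)
        sub("protocol", ProtocolConfig)
        sub("error_model", ErrorModel)
        return cls(**data)

    @classmethod
    def from_yaml(cls, text_or_path: Union[str, Path]) -> "RunConfig":
        text = str(text_or_path)
        if "\n" not in text and Path(text).exists():
            text = Path(text).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError("config YAML must contain a mapping")
        return cls.from_dict(data)
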