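"""Domain types shared across the wristox pipeline.

Units convention: PPG channels are raw ADC counts (18-bit), accelerometer
axes are arbitrary sensor units, time is seconds from recording start,
SpO2 is percent, heart rate is beats per minute.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

ADC_BITS = 18
ADC_MAX = 2**ADC_BITS - 1  # 262143 counts


@dataclass(frozen=True)
class CalibrationCurve:
    """Quadratic mapping from the ratio-of-ratios gamma to SpO2 (%).

    SpO2 = a*gamma**2 + b*gamma + c.  The defaults are the device-family
    constants; per-subject overrides are allowed.  With a < 0 the
    physiologically meaningful branch is gamma > -b/(2a), where SpO2
    decreases as gamma grows.
    """

    a: float = -44.6
    b: float = 5.9
    c: float = 108.1

    def __post_init__(self) -> None:
        if self.a == 0:
            raise ValueError("calibration curve requires a != 0")

    def spo2(self, gamma: float) -> float:
        return self.a * gamma**2 + self.b * gamma + self.c

    @property
    def vertex(self) -> float:
        """Gamma at the parabola's turning point (branch boundary)."""
        return -self.b / (2.0 * self.a)

    @property
    def spo2_max(self) -> float:
        """Largest SpO2 the curve can produce (value at the vertex)."""
        return self.spo2(self.vertex)


@dataclass(frozen=True)
class QCThresholds:
    """Signal-quality and validity thresholds.

    The jolt threshold and the HR/SpO2 acceptance ranges are device
    constants; the remaining bounds are empirical and configurable.
    Comparisons are strict: boundary values fail toward exclusion.
    """

    jolt_threshold: float = 18.0
    dc_range: Tuple[float, float] = (5_000.0, 250_000.0)
    ac_pp_range: Tuple[float, float] = (20.0, 50_000.0)
    ir_red_corr_min: float = 0.8
    accel_ppg_corr_max: float = 0.5
    ac_amp_max: float = 50_000.0
    hr_valid: Tuple[float, float] = (40.0, 180.0)
    spo2_valid: Tuple[float, float] = (80.0, 100.0)

    def __post_init__(self) -> None:
        for name in ("dc_range", "ac_pp_range", "hr_valid", "spo2_valid"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be ordered (min < max)")


@dataclass(frozen=True)
class SubjectInfo:
    subject_id: str = "S01"
    age_years: float = 37.0
    sex: str = "M"  # "M" | "F"
    skin: str = "white"  # "white" | "black"
    bmi: float = 26.2


@dataclass
class RawRecording:
    """Synchronized two-channel PPG plus tri-axial accelerometer stream."""

    red: np.ndarray  # integer counts, shape (n,)
    ir: np.ndarray  # integer counts, shape (n,)
    accel: np.ndarray  # arbitrary units, shape (n, 3)
    fs: float = 50.0
    site: str = "wrist"  # "finger" | "wrist"
    subject: SubjectInfo = field(default_factory=SubjectInfo)

    def __post_init__(self) -> None:
        self.red = np.asarray(self.red)
        self.ir = np.asarray(self.ir)
        self.accel = np.asarray(self.accel, dtype=float)
        n = len(self.red)
        if len(self.ir) != n or self.accel.shape != (n, 3):
            raise ValueError("red, ir and accel must have equal length")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        for name, ch in (("red", self.red), ("ir", self.ir)):
            if len(ch) and (ch.min() < 0 or ch.max() > ADC_MAX):
                raise ValueError(f"{name} counts outside 18-bit range")
        if self.site not in ("finger", "wrist"):
            raise ValueError("site must be 'finger' or 'wrist'")

    @property
    def n_samples(self) -> int:
        return len(self.red)

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class Epoch:
    """Half-open 0-based sample interval [start, stop)."""

    start: int
    stop: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.stop:
            raise ValueError("epoch requires 0 <= start < stop")

    def __len__(self) -> int:
        return self.stop - self.start


@dataclass(frozen=True)
class ACDCComponents:
    """DC (epoch mean of raw counts) and AC (RMS of band-passed counts)
    components of the red and infrared channels for one epoch."""

    red_dc: float
    red_ac: float
    ir_dc: float
    ir_ac: float


@dataclass(frozen=True)
class SubjectOffset:
    """Intra-subject calibration offset: finger-site minus wrist-site
    mean SpO2, added to every subsequent wrist reading."""

    spo2_finger: float
    spo2_wrist: float

    @property
    def offset(self) -> float:
        return self.spo2_finger - self.spo2_wrist


ZERO_OFFSET = SubjectOffset(0.0, 0.0)


@dataclass
class Measurement:
    """One epoch's SpO2/HR estimate with quality and validity flags."""

    time: float
    spo2_raw: float
    spo2_compensated: float
    hr: float
    qc_passed: bool
    motion_free: bool
    valid: bool
    fail_reason: Optional[str] = None

    def __post_init__(self) -> None:
        # valid implies every gate passed; enforce rather than trust callers
        if self.valid:
            ok = (
                self.qc_passed
                and self.motion_free
                and math.isfinite(self.hr)
                and math.isfinite(self.spo2_compensated)
            )
            if not ok:
                raise ValueError("valid measurement with failed gates")
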