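"""Synthetic PPG/accelerometer recordings and paired-reading tables.

The generator emulates what the processing pipeline and the validation
statistics assume: a pulsatile AC component (fundamental plus one
harmonic) riding on a DC baseline in both optical channels, with the
AC/DC modulation ratios chosen so that the ratio-of-ratios gamma encodes
a prescribed SaO2 trajectory through the calibration curve; a
near-constant gravity vector on the accelerometer, broken by motion
bursts that may also corrupt the PPG; and device/reference reading pairs
with Gaussian disagreement of known bias and spread.

All randomness flows from explicit integer seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .types import ADC_MAX, CalibrationCurve, RawRecording, SubjectInfo

# RMS of sin(phi) + h*sin(2*phi) relative to unit fundamental amplitude
_DEF_HARMONIC = 0.25

HRSpec = Union[float, Sequence[Tuple[float, float]], Callable[[np.ndarray], np.ndarray]]


@dataclass(frozen=True)
class PhysioProfile:
    """SaO2/HR ground-truth trajectory for one simulated session.

    The SaO2 trace ramps linearly over ``pre_plateau_wait`` seconds into
    each plateau and holds it for ``plateau_duration`` seconds.  The HR
    trajectory may be a constant, a piecewise-constant list of
    ``(start_time, bpm)`` breakpoints, or a callable of a time array.
    """

    plateau_targets: Sequence[float] = (97.0, 92.0, 87.0, 82.0)
    plateau_duration: float = 150.0
    pre_plateau_wait: float = 30.0
    hr_trajectory: HRSpec = 75.0
    transition_time: float = 30.0  # alias kept distinct: ramp length = pre_plateau_wait

    def __post_init__(self) -> None:
        if not self.plateau_targets:
            raise ValueError("at least one plateau target required")
        for s in self.plateau_targets:
            if not 80.0 <= s <= 100.0:
                raise ValueError("plateau targets must lie in [80, 100] %")
        for hr in np.atleast_1d(self.hr_at(np.linspace(0, self.total_duration, 50))):
            if not 0.0 < hr < 300.0:
                raise ValueError("heart rate must lie in (0, 300) bpm")

    @property
    def total_duration(self) -> float:
        return len(self.plateau_targets) * (
            self.pre_plateau_wait + self.plateau_duration
        )

    def plateau_hold_start(self, i: int) -> float:
        """Start time of plateau i's hold phase (after its entry ramp)."""
        return i * (self.pre_plateau_wait + self.plateau_duration) + self.pre_plateau_wait

    def sao2_at(self, t: np.ndarray) -> np.ndarray:
        """Ground-truth SaO2 (%) at times ``t`` (piecewise linear)."""
        t = np.asarray(t, dtype=float)
        ramp = min(self.transition_time, self.pre_plateau_wait)
        knots_t = [0.0]
        knots_s = [self.plateau_targets[0]]
        for i, target in enumerate(self.plateau_targets):
            start = i * (self.pre_plateau_wait + self.plateau_duration)
            knots_t += [start + ramp, start + self.pre_plateau_wait + self.plateau_duration]
            knots_s += [target, target]
        return np.interp(t, knots_t, knots_s)

    def hr_at(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        hr = self.hr_trajectory
        if callable(hr):
            return np.asarray(hr(t), dtype=float)
        if np.isscalar(hr):
            return np.full_like(t, float(hr))
        pts = sorted(hr)  # piecewise-constant breakpoints
        times = np.array([p[0] for p in pts])
        vals = np.array([p[1] for p in pts])
        idx = np.clip(np.searchsorted(times, t, side="right") - 1, 0, len(vals) - 1)
        return vals[idx]


@dataclass(frozen=True)
class MotionEvent:
    """One burst of wrist movement; optionally couples into the PPG."""

    start: float
    duration: float
    amplitude: float = 100.0
    corrupts_ppg: bool = True

    def __post_init__(self) -> None:
        if self.start < 0 or self.duration <= 0 or self.amplitude <= 0:
            raise ValueError("motion event requires start >= 0, duration > 0, amplitude > 0")


@dataclass(frozen=True)
class ErrorModel:
    """Gaussian device-minus-reference disagreement for paired readings."""

    spo2_bias: float = 0.0
    spo2_sd: float = 0.0
    hr_bias: float = 0.0
    hr_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spo2_sd < 0 or self.hr_sd < 0:
            raise ValueError("standard deviations must be >= 0")


@dataclass(frozen=True)
class PerfusionSettings:
    """Optical operating point of the simulated sensor site.

    ``ir_modulation`` is the target IR AC-RMS / DC ratio; the red-channel
    modulation follows from the SaO2-encoded gamma.  Defaults sit inside
    the default QC acceptance windows.
    """

    red_dc: float = 100_000.0
    ir_dc: float = 120_000.0
    ir_modulation: float = 0.02
    harmonic_ratio: float = _DEF_HARMONIC
    noise_sd: float = 3.0
    accel_gravity: float = 64.0
    accel_jitter_sd: float = 1.0

    @property
    def waveform_rms_factor(self) -> float:
        return math.sqrt((1.0 + self.harmonic_ratio**2) / 2.0)


def invert_spo2_to_gamma(
    spo2_target: float, curve: CalibrationCurve = CalibrationCurve()
) -> float:
    """Gamma that the calibration curve maps to ``spo2_target``.

    Picks the root on the physiologically monotone branch (SpO2 strictly
    decreasing in gamma), i.e. gamma > -b/(2a) for a < 0.  Raises when the
    target saturation is unreachable for the curve.
    """
    a, b, c = curve.a, curve.b, curve.c
    disc = b * b - 4.0 * a * (c - spo2_target)
    if disc < 0:
        raise ValueError(
            f"SpO2 {spo2_target}% unreachable: no real gamma on this curve"
        )
    # Of the two roots (-b +/- sqrt(disc))/(2a), the one on the decreasing
    # branch (gamma > vertex for a < 0, gamma < vertex for a > 0) is in both
    # cases (-b - sqrt(disc))/(2a).
    return (-b - math.sqrt(disc)) / (2.0 * a)


def generate_recording(
    profile: PhysioProfile,
    motion: Sequence[MotionEvent] = (),
    curve: CalibrationCurve = CalibrationCurve(),
    perfusion: PerfusionSettings = PerfusionSettings(),
    seed: int = 0,
    fs: float = 50.0,
    duration: Optional[float] = None,
    sao2_offset: float = 0.0,
    site: str = "wrist",
    subject: SubjectInfo = SubjectInfo(),
) -> RawRecording:
    """Simulate one two-channel PPG + accelerometer recording.

    Each optical channel is DC * (1 + m(t) * w(phi(t))) + white noise,
    quantized to 18-bit counts, where w is a fundamental-plus-harmonic
    pulse waveform at the instantaneous heart rate and the modulation
    depths m are chosen per sample so the epoch AC/DC ratios encode
    SaO2(t) + ``sao2_offset`` through the calibration curve.  The
    accelerometer is a constant gravity vector plus small jitter, with
    bursts added during motion events; events with ``corrupts_ppg`` also
    add a PPG excursion proportional to the accelerometer magnitude.
    """
    rng = np.random.default_rng(seed)
    if duration is None:
        duration = profile.total_duration
    n = int(round(duration * fs))
    if n < 2:
        raise ValueError("recording must span at least 2 samples")
    t = np.arange(n) / fs
    p = perfusion

    hr = profile.hr_at(t)
    phase = 2.0 * np.pi * np.cumsum(hr / 60.0) / fs
    wave = np.sin(phase) + p.harmonic_ratio * np.sin(2.0 * phase)

    sao2 = np.clip(profile.sao2_at(t) + sao2_offset, None, curve.spo2_max)
    disc = curve.b**2 - 4.0 * curve.a * (curve.c - sao2)
    gamma = (-curve.b - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * curve.a)
    k = p.waveform_rms_factor
    r_ir = p.ir_modulation  # target IR AC-RMS / DC
    r_red = np.exp(np.log(r_ir) / gamma)  # gamma = ln(r_ir)/ln(r_red)
    m_ir = r_ir / k
    m_red = r_red / k

    red = p.red_dc * (1.0 + m_red * wave) + rng.normal(0.0, p.noise_sd, n)
    ir = p.ir_dc * (1.0 + m_ir * wave) + rng.normal(0.0, p.noise_sd, n)

    accel = np.zeros((n, 3))
    accel[:, 2] = p.accel_gravity
    accel += rng.normal(0.0, p.accel_jitter_sd, (n, 3))
    for ev in motion:
        i0 = int(round(ev.start * fs))
        i1 = min(n, int(round((ev.start + ev.duration) * fs)))
        if i0 >= n or i1 <= i0:
            continue
        burst = rng.normal(0.0, ev.amplitude, (i1 - i0, 3))
        accel[i0:i1] += burst
        if ev.corrupts_ppg:
            mag = np.linalg.norm(accel[i0:i1], axis=1)
            excursion = (mag - mag.mean()) / max(ev.amplitude, 1.0)
            red[i0:i1] += 0.3 * p.red_dc * excursion
            ir[i0:i1] += 0.3 * p.ir_dc * excursion

    for name, ch in (("red", red), ("ir", ir)):
        if ch.min() < 0 or ch.max() > ADC_MAX:
            raise ValueError(
                f"perfusion settings clip the 18-bit range on the {name} channel"
            )
    return RawRecording(
        red=np.rint(red).astype(np.int64),
        ir=np.rint(ir).astype(np.int64),
        accel=accel,
        fs=fs,
        site=site,
        subject=subject,
    )


# ---------------------------------------------------------------------------
# Subject roster and paired readings
# ---------------------------------------------------------------------------

def default_roster(n_subjects: int = 12, seed: int = 0) -> pd.DataFrame:
    """Deterministic subject roster mirroring the study sample make-up:
    12 adults, 10 male / 2 female, 8 white / 4 black skin, ages 20-51,
    BMI around 26."""
    if n_subjects <= 0:
        raise ValueError("need at least one subject")
    rng = np.random.default_rng(seed)
    sid = [f"S{i + 1:02d}" for i in range(n_subjects)]
    sex = ["F" if (i % 6) == 5 else "M" for i in range(n_subjects)]
    skin = ["black" if (i % 3) == 2 else "white" for i in range(n_subjects)]
    age = np.clip(np.round(rng.normal(37, 9, n_subjects)), 20, 51)
    bmi = np.round(np.clip(rng.normal(26.2, 3.3, n_subjects), 18.5, 38.0), 1)
    return pd.DataFrame(
        {"subject_id": sid, "age_years": age, "sex": sex, "skin": skin, "bmi": bmi}
    )


TruthDistribution = Union[None, Tuple[float, float], Callable[[np.random.Generator, int], np.ndarray]]


def generate_paired_dataset(
    n_pairs: int,
    truth_distribution: TruthDistribution = None,
    error_model: ErrorModel = ErrorModel(),
    roster: Optional[pd.DataFrame] = None,
    hr_range: Tuple[float, float] = (64.0, 122.0),
    pair_spacing: float = 20.0,
) -> pd.DataFrame:
    """Simulate simultaneous device/reference reading pairs.

    Reference SpO2 is drawn from ``truth_distribution`` (default uniform
    on [80, 100]; a (lo, hi) tuple selects another uniform; a callable
    ``f(rng, n)`` draws arbitrarily), reference HR uniform over
    ``hr_range``.  Device readings are reference + Normal(bias, sd^2) per
    the error model.  Pairs are attributed round-robin to the roster
    subjects with per-subject acquisition order; the whole table is
    reproducible from ``error_model.seed``.
    """
    if n_pairs <= 0:
        raise ValueError("n_pairs must be positive")
    rng = np.random.default_rng(error_model.seed)
    if truth_distribution is None:
        ref_spo2 = rng.uniform(80.0, 100.0, n_pairs)
    elif callable(truth_distribution):
        ref_spo2 = np.asarray(truth_distribution(rng, n_pairs), dtype=float)
    else:
        lo, hi = truth_distribution
        ref_spo2 = rng.uniform(lo, hi, n_pairs)
    ref_hr = rng.uniform(hr_range[0], hr_range[1], n_pairs)
    dev_spo2 = ref_spo2 + rng.normal(error_model.spo2_bias, error_model.spo2_sd, n_pairs)
    dev_hr = ref_hr + rng.normal(error_model.hr_bias, error_model.hr_sd, n_pairs)
    if roster is None:
        roster = default_roster(seed=error_model.seed)
    idx = np.arange(n_pairs) % len(roster)
    rows = roster.iloc[idx].reset_index(drop=True)
    order = np.arange(n_pairs) // len(roster)  # per-subject acquisition index
    return pd.DataFrame(
        {
            "subject_id": rows["subject_id"],
            "t_s": order * pair_spacing,
            "spo2_dev": dev_spo2,
            "spo2_ref": ref_spo2,
            "hr_dev": dev_hr,
            "hr_ref": ref_hr,
            "age_years": rows["age_years"],
            "sex": rows["sex"],
            "skin": rows["skin"],
            "bmi": rows["bmi"],
            "acquisition_order": order,
        }
    )
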