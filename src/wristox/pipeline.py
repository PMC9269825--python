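"""Signal-processing pipeline for reflective wrist pulse oximetry.

The chain is: accelerometer jolt -> stillness windows -> zero-phase FIR
band-pass (0.5-3 Hz) -> per-epoch AC/DC decomposition -> signal quality
control -> motion-artifact check -> ratio-of-ratios gamma -> SpO2 via the
calibration quadratic -> intra-subject offset compensation -> spectral HR.

All operations are batch (offline); nothing here is streaming.
"""

from __future__ import annotations

import math
from fractions import Fraction
from functools import lru_cache
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .types import (
    ACDCComponents,
    CalibrationCurve,
    Epoch,
    Measurement,
    QCThresholds,
    RawRecording,
    SubjectOffset,
    ZERO_OFFSET,
)

FIR_ORDER = 50  # taps = order + 1
_INTERNAL_FS = 10.0  # rate at which the band-pass operates (band is 0.5-3 Hz)
PASSBAND = (0.5, 3.0)  # Hz


# ---------------------------------------------------------------------------
# Motion: jolt and stillness
# ---------------------------------------------------------------------------

def compute_jolt(accel: np.ndarray) -> np.ndarray:
    """Time-difference of the acceleration-vector magnitude.

    j[t] = |a[t]| - |a[t-1]| with |a| = sqrt(x^2 + y^2 + z^2).  The output
    has one sample fewer than the input; j[i] describes the transition
    between samples i and i+1.
    """
    accel = np.asarray(accel, dtype=float)
    if accel.ndim != 2 or accel.shape[1] != 3:
        raise ValueError("accel must have shape (n, 3)")
    if accel.shape[0] < 2:
        raise ValueError("jolt requires at least 2 accelerometer samples")
    mag = np.linalg.norm(accel, axis=1)
    return np.diff(mag)


def detect_still_windows(
    jolt: np.ndarray,
    thresholds: QCThresholds = QCThresholds(),
    min_window: float = 10.0,
    fs: float = 50.0,
) -> List[Epoch]:
    """Maximal sample intervals with no movement above the jolt threshold.

    A window [s, e) is still when |j[t]| < jolt_threshold (strictly) for
    every transition t inside it.  Windows shorter than ``min_window``
    seconds are discarded.  The comparison is strict, so a jolt exactly at
    the threshold counts as movement.
    """
    jolt = np.asarray(jolt, dtype=float)
    still = np.abs(jolt) < thresholds.jolt_threshold
    min_len = int(round(min_window * fs))
    windows: List[Epoch] = []
    i = 0
    n = len(still)
    while i < n:
        if still[i]:
            j = i
            while j < n and still[j]:
                j += 1
            # jolt run [i, j) covers samples [i, j]; half-open -> [i, j+1)
            if (j + 1 - i) >= min_len:
                windows.append(Epoch(i, j + 1))
            i = j
        else:
            i += 1
    return windows


# ---------------------------------------------------------------------------
# Band-pass filtering
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _bandpass_taps(fs_internal: float) -> np.ndarray:
    # Equiripple design; pass band weighted for flatness because the AC
    # amplitude feeds the gamma ratio directly.  Stop-band floors only need
    # ~10 dB per pass (the filter is applied forward and backward).
    return sps.remez(
        FIR_ORDER + 1,
        [0, 0.1, 0.6, 2.85, 3.7, fs_internal / 2],
        [0, 1, 0],
        weight=[8, 1, 4],
        fs=fs_internal,
    )


@lru_cache(maxsize=8)
def _resample_fractions(fs: float) -> Tuple[int, int]:
    frac = Fraction(_INTERNAL_FS / fs).limit_denominator(1000)
    return frac.numerator, frac.denominator


def bandpass_filter(x: Sequence[float], fs: float = 50.0) -> np.ndarray:
    """Zero-phase 0.5-3 Hz band-pass of a PPG channel.

    A 50th-order FIR is applied anti-causally (forward-backward) at a
    10 Hz internal rate matched to the pulse band, with polyphase
    resampling on either side; this realizes the narrow 0.5 Hz lower edge
    within the 50-tap budget.  Output has the same length as the input.
    Requires more than 3 x 50 input samples.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D signal")
    if len(x) <= 3 * FIR_ORDER:
        raise ValueError(
            f"signal too short for filtering: need > {3 * FIR_ORDER} samples"
        )
    if fs <= 2 * PASSBAND[1]:
        raise ValueError("sampling rate too low for the 0.5-3 Hz band")
    up, down = _resample_fractions(fs)
    taps = _bandpass_taps(_INTERNAL_FS)
    # remove the mean before resampling to keep edge transients small
    mu = x.mean()
    xi = sps.resample_poly(x - mu, up, down)
    padlen = min(3 * len(taps), len(xi) - 1)
    yi = sps.filtfilt(taps, [1.0], xi, padlen=padlen)
    y = sps.resample_poly(yi, down, up)
    if len(y) < len(x):  # pragma: no cover - exact-ratio rates rarely hit this
        y = np.pad(y, (0, len(x) - len(y)))
    return y[: len(x)]


# ---------------------------------------------------------------------------
# AC/DC decomposition and quality control
# ---------------------------------------------------------------------------

MIN_EPOCH_SECONDS = 5.0


def extract_acdc(
    red_epoch: Sequence[float],
    ir_epoch: Sequence[float],
    fs: float = 50.0,
    red_filtered: Optional[np.ndarray] = None,
    ir_filtered: Optional[np.ndarray] = None,
) -> ACDCComponents:
    """DC (mean of the raw epoch) and AC (RMS of the band-passed epoch)
    for both channels.

    ``red_filtered``/``ir_filtered`` may carry pre-computed band-passed
    slices (e.g. when a whole still window was filtered at once); otherwise
    the epoch is filtered here.  Epochs must span at least 5 s so the RMS
    covers several cardiac cycles.
    """
    red = np.asarray(red_epoch, dtype=float)
    ir = np.asarray(ir_epoch, dtype=float)
    if len(red) != len(ir):
        raise ValueError("epoch channels must have equal length")
    if len(red) < MIN_EPOCH_SECONDS * fs:
        raise ValueError(f"epoch shorter than {MIN_EPOCH_SECONDS} s")
    if red_filtered is None:
        red_filtered = bandpass_filter(red, fs)
    if ir_filtered is None:
        ir_filtered = bandpass_filter(ir, fs)
    rms = lambda v: float(np.sqrt(np.mean(np.square(v))))
    return ACDCComponents(
        red_dc=float(red.mean()),
        red_ac=rms(red_filtered),
        ir_dc=float(ir.mean()),
        ir_ac=rms(ir_filtered),
    )


def check_signal_quality(
    components: ACDCComponents,
    red_ac_epoch: Sequence[float],
    ir_ac_epoch: Sequence[float],
    thresholds: QCThresholds = QCThresholds(),
) -> Tuple[bool, Optional[str]]:
    """Three-stage quality control, evaluated in order with short-circuit.

    1. DC means of both channels inside ``dc_range``;
    2. peak-to-peak of both band-passed AC epochs inside ``ac_pp_range``;
    3. correlation between the IR and RED AC epochs strictly above
       ``ir_red_corr_min``.

    Returns ``(passed, first_failing_reason)``.
    """
    t = thresholds
    if not (t.dc_range[0] < components.red_dc < t.dc_range[1]
            and t.dc_range[0] < components.ir_dc < t.dc_range[1]):
        return False, "dc_out_of_range"
    red_ac = np.asarray(red_ac_epoch, dtype=float)
    ir_ac = np.asarray(ir_ac_epoch, dtype=float)
    for ch in (red_ac, ir_ac):
        pp = float(ch.max() - ch.min()) if len(ch) else 0.0
        if not t.ac_pp_range[0] < pp < t.ac_pp_range[1]:
            return False, "ac_pp_out_of_range"
    if red_ac.std() == 0 or ir_ac.std() == 0:
        return False, "low_channel_correlation"
    corr = float(np.corrcoef(red_ac, ir_ac)[0, 1])
    if not corr > t.ir_red_corr_min:
        return False, "low_channel_correlation"
    return True, None


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    # zero-variance input => correlation undefined; treated as 0 (no
    # evidence of coupling), which passes the motion sub-check
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def detect_motion_corrupted(
    red_ac_epoch: Sequence[float],
    ir_ac_epoch: Sequence[float],
    accel_epoch: np.ndarray,
    thresholds: QCThresholds = QCThresholds(),
) -> Tuple[bool, Optional[str]]:
    """Motion-artifact check on one epoch.

    The epoch is corrupted when the band-passed AC excursion exceeds
    ``ac_amp_max``, or when either PPG channel correlates with the
    accelerometer magnitude at |r| >= ``accel_ppg_corr_max``.  Returns
    ``(motion_free, reason)``.
    """
    t = thresholds
    red_ac = np.asarray(red_ac_epoch, dtype=float)
    ir_ac = np.asarray(ir_ac_epoch, dtype=float)
    accel_epoch = np.asarray(accel_epoch, dtype=float)
    if not (len(red_ac) == len(ir_ac) == accel_epoch.shape[0]):
        raise ValueError("epoch slices must have equal length")
    for ch in (red_ac, ir_ac):
        if len(ch) and float(np.abs(ch).max()) > t.ac_amp_max:
            return False, "ac_amplitude_exceeded"
    mag = np.linalg.norm(accel_epoch, axis=1)
    for ch in (red_ac, ir_ac):
        if abs(_safe_corr(mag, ch)) >= t.accel_ppg_corr_max:
            return False, "accel_ppg_correlation"
    return True, None


# ---------------------------------------------------------------------------
# Gamma, SpO2, offset compensation
# ---------------------------------------------------------------------------

def compute_gamma(components: ACDCComponents) -> float:
    """Ratio of ratios: ln(IR_AC/IR_DC) / ln(RED_AC/RED_DC)."""
    c = components
    if min(c.red_dc, c.red_ac, c.ir_dc, c.ir_ac) <= 0:
        raise ValueError("gamma requires strictly positive AC/DC components")
    red_ratio = c.red_ac / c.red_dc
    if red_ratio == 1.0:
        raise ValueError("gamma undefined: RED_AC equals RED_DC")
    return math.log(c.ir_ac / c.ir_dc) / math.log(red_ratio)


def compute_spo2(gamma: float, curve: CalibrationCurve = CalibrationCurve()) -> float:
    """SpO2 (%) from gamma via the calibration quadratic, unclamped.

    Out-of-range values are preserved; the 80-100 % acceptance rule is
    applied downstream when measurements are flagged valid/invalid.
    """
    if not math.isfinite(gamma):
        raise ValueError("gamma must be finite")
    return curve.spo2(gamma)


def compensate(spo2_raw: float, offset: SubjectOffset) -> float:
    """Apply the intra-subject calibration: SpO2 + (finger - wrist)."""
    return spo2_raw + offset.offset


# ---------------------------------------------------------------------------
# Heart rate
# ---------------------------------------------------------------------------

_HR_PEAK_POWER_RATIO = 10.0  # dominant peak vs median in-band power


def estimate_heart_rate(filtered_epoch: Sequence[float], fs: float = 50.0) -> float:
    """HR (bpm) from the dominant spectral peak of a band-passed epoch.

    The magnitude spectrum (Hann window) is searched over 0.5-3 Hz; the
    peak is refined by parabolic interpolation on log power.  If no peak
    stands at least 10x above the median in-band power the epoch carries
    no usable periodicity and an error is raised.
    """
    x = np.asarray(filtered_epoch, dtype=float)
    if len(x) < MIN_EPOCH_SECONDS * fs:
        raise ValueError(f"epoch shorter than {MIN_EPOCH_SECONDS} s")
    win = np.hanning(len(x))
    nfft = 8 * len(x)  # zero-pad for a fine frequency grid
    spec = np.abs(np.fft.rfft((x - x.mean()) * win, n=nfft)) ** 2
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    band = (freqs >= PASSBAND[0]) & (freqs <= PASSBAND[1])
    p = spec[band]
    f = freqs[band]
    if len(p) < 3 or p.max() <= 0:
        raise ValueError("no spectral content in the heart-rate band")
    k = int(np.argmax(p))
    if p[k] < _HR_PEAK_POWER_RATIO * np.median(p):
        raise ValueError("no dominant periodicity above the noise floor")
    if 0 < k < len(p) - 1:
        # parabolic refinement on log power
        la, lb, lc = np.log(p[k - 1 : k + 2] + 1e-300)
        denom = la - 2 * lb + lc
        delta = 0.5 * (la - lc) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    df = f[1] - f[0]
    return 60.0 * float(f[k] + delta * df)


# ---------------------------------------------------------------------------
# Calibration and end-to-end processing
# ---------------------------------------------------------------------------

CALIBRATION_SECONDS = 90.0
EDGE_TRIM = FIR_ORDER // 2  # samples dropped at still-window boundaries


def _epochs_in_window(window: Epoch, epoch_len: int, step: int) -> List[Epoch]:
    start = window.start + EDGE_TRIM
    stop = window.stop - EDGE_TRIM
    out = []
    s = start
    while s + epoch_len <= stop:
        out.append(Epoch(s, s + epoch_len))
        s += step
    return out


def process_recording(
    recording: RawRecording,
    curve: CalibrationCurve = CalibrationCurve(),
    offset: SubjectOffset = ZERO_OFFSET,
    thresholds: QCThresholds = QCThresholds(),
    epoch_length: float = 10.0,
    epoch_step: float = 5.0,
) -> List[Measurement]:
    """Run the full chain over a recording and emit one measurement per
    epoch slid across the still windows.

    A measurement is ``valid`` only when QC passed, the epoch is motion
    free, HR lies in the 40-180 bpm acceptance range and the compensated
    SpO2 lies in 80-100 %.  Nothing is clamped; failures are flagged.
    """
    fs = recording.fs
    epoch_len = int(round(epoch_length * fs))
    step = int(round(epoch_step * fs))
    if recording.n_samples < epoch_len:
        raise ValueError("recording shorter than one epoch")
    jolt = compute_jolt(recording.accel)
    windows = detect_still_windows(jolt, thresholds, epoch_length, fs)
    red = recording.red.astype(float)
    ir = recording.ir.astype(float)
    out: List[Measurement] = []
    for w in windows:
        if len(w) <= 3 * FIR_ORDER:
            continue
        red_f = bandpass_filter(red[w.start : w.stop], fs)
        ir_f = bandpass_filter(ir[w.start : w.stop], fs)
        for ep in _epochs_in_window(w, epoch_len, step):
            lo, hi = ep.start - w.start, ep.stop - w.start
            red_raw, ir_raw = red[ep.start : ep.stop], ir[ep.start : ep.stop]
            red_ac, ir_ac = red_f[lo:hi], ir_f[lo:hi]
            comp = extract_acdc(red_raw, ir_raw, fs, red_ac, ir_ac)
            qc_ok, reason = check_signal_quality(comp, red_ac, ir_ac, thresholds)
            motion_ok, m_reason = detect_motion_corrupted(
                red_ac, ir_ac, recording.accel[ep.start : ep.stop], thresholds
            )
            spo2_raw = math.nan
            if qc_ok:
                try:
                    spo2_raw = compute_spo2(compute_gamma(comp), curve)
                except ValueError:
                    qc_ok, reason = False, "gamma_undefined"
            spo2_comp = compensate(spo2_raw, offset)
            try:
                hr = estimate_heart_rate(ir_ac, fs)
            except ValueError:
                hr = math.nan
            hr_ok = thresholds.hr_valid[0] <= hr <= thresholds.hr_valid[1]
            spo2_ok = (
                thresholds.spo2_valid[0] <= spo2_comp <= thresholds.spo2_valid[1]
            )
            valid = qc_ok and motion_ok and hr_ok and spo2_ok
            if not qc_ok:
                fail = reason
            elif not motion_ok:
                fail = m_reason
            elif not hr_ok:
                fail = "hr_out_of_range"
            elif not spo2_ok:
                fail = "spo2_out_of_range"
            else:
                fail = None
            out.append(
                Measurement(
                    time=(ep.start + ep.stop) / 2.0 / fs,
                    spo2_raw=spo2_raw,
                    spo2_compensated=spo2_comp,
                    hr=hr,
                    qc_passed=qc_ok,
                    motion_free=motion_ok,
                    valid=valid,
                    fail_reason=fail,
                )
            )
    return out


def calibrate_subject(
    finger_recording: RawRecording,
    wrist_recording: RawRecording,
    curve: CalibrationCurve = CalibrationCurve(),
    thresholds: QCThresholds = QCThresholds(),
    epoch_length: float = 10.0,
    epoch_step: float = 5.0,
) -> SubjectOffset:
    """Intra-subject offset from 90 s finger and wrist baselines.

    Both recordings must span at least 90 s and carry the matching site
    labels.  The offset is the difference of the mean raw SpO2 over valid
    epochs in each recording's first 90 s.
    """
    if finger_recording.site != "finger" or wrist_recording.site != "wrist":
        raise ValueError("recordings must be labelled site='finger' and site='wrist'")
    means = {}
    for rec in (finger_recording, wrist_recording):
        if rec.duration < CALIBRATION_SECONDS:
            raise ValueError(
                f"{rec.site} recording shorter than {CALIBRATION_SECONDS:.0f} s"
            )
        n = int(CALIBRATION_SECONDS * rec.fs)
        head = RawRecording(
            red=rec.red[:n],
            ir=rec.ir[:n],
            accel=rec.accel[:n],
            fs=rec.fs,
            site=rec.site,
            subject=rec.subject,
        )
        ms = process_recording(
            head, curve, ZERO_OFFSET, thresholds, epoch_length, epoch_step
        )
        vals = [m.spo2_raw for m in ms if m.valid]
        if not vals:
            raise ValueError(
                f"no valid calibration epoch in the first 90 s of the {rec.site} recording"
            )
        means[rec.site] = float(np.mean(vals))
    return SubjectOffset(spo2_finger=means["finger"], spo2_wrist=means["wrist"])
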