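"""Controlled-desaturation protocol and data-conditioning chain.

Covers the measurement-extraction schedule over the four saturation
plateaus, pairing of device measurements with reference readings,
single-pass outlier removal on the paired error, the
Kolmogorov-Smirnov normality check, and the cyclic per-subject range
equalization that balances the three reference-SpO2 bins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .types import Measurement


@dataclass(frozen=True)
class PlateauSpec:
    """One desaturation plateau of the test protocol."""

    label: str
    target: float  # %
    spo2_range: Tuple[float, float]
    gas_label: str = ""  # carried as metadata only
    duration: float = 150.0  # hold time, seconds (2.5 min)
    n_extractions: int = 8
    min_spacing: float = 20.0  # seconds between extractions

    def __post_init__(self) -> None:
        if self.n_extractions < 1 or self.duration <= 0 or self.min_spacing < 0:
            raise ValueError("invalid plateau specification")
        if (self.n_extractions - 1) * self.min_spacing > self.duration:
            raise ValueError(
                f"plateau {self.label}: {self.n_extractions} extractions at "
                f">= {self.min_spacing} s spacing do not fit in {self.duration} s"
            )


def default_protocol() -> List[PlateauSpec]:
    """The four-plateau protocol: targets 97/92/87/82 %, 2.5 min holds,
    8 extractions each at >= 20 s spacing (32 per subject)."""
    return [
        PlateauSpec("I", 97.0, (95.0, 100.0), "ambient air"),
        PlateauSpec("II", 92.0, (90.0, 94.0), "O2 15% + N 85%"),
        PlateauSpec("III", 87.0, (85.0, 89.0), "O2 13% + N 87%"),
        PlateauSpec("IV", 82.0, (80.0, 84.0), "O2 11% + N 89%"),
    ]


def schedule_measurements(
    plateaus: Sequence[PlateauSpec], pre_wait: float = 30.0
) -> np.ndarray:
    """Extraction timestamps for a session, seconds from session start.

    Each plateau is entered after a ``pre_wait`` stabilization ramp; its
    n extractions are spread evenly across the hold, so consecutive
    extractions sit duration/(n-1) >= min_spacing apart.
    """
    times: List[float] = []
    t = 0.0
    for p in plateaus:
        t += pre_wait
        if p.n_extractions == 1:
            times.append(t + p.duration / 2.0)
        else:
            step = p.duration / (p.n_extractions - 1)
            if step < p.min_spacing:
                raise ValueError(f"plateau {p.label}: spacing infeasible")
            times.extend(t + i * step for i in range(p.n_extractions))
        t += p.duration
    return np.asarray(times)


def extract_pairs(
    device_measurements: Sequence[Measurement],
    reference: pd.DataFrame,
    schedule: np.ndarray,
    tolerance: float = 5.0,
    subject: Optional[dict] = None,
) -> pd.DataFrame:
    """Pair scheduled extraction times with device and reference readings.

    For each scheduled time the nearest *valid* device measurement within
    ``tolerance`` seconds is taken, together with the reference reading
    interpolated at the scheduled time.  Scheduled times without a valid
    device measurement yield no pair.  ``reference`` needs columns
    ``t_s``, ``spo2``, ``hr``; ``subject`` supplies covariate columns.
    """
    valid = [m for m in device_measurements if m.valid]
    rows = []
    order = 0
    ref_t = reference["t_s"].to_numpy(dtype=float)
    for tau in np.asarray(schedule, dtype=float):
        if not valid:
            break
        dts = np.array([abs(m.time - tau) for m in valid])
        k = int(np.argmin(dts))
        if dts[k] > tolerance:
            continue
        m = valid[k]
        row = {
            "subject_id": (subject or {}).get("subject_id", "S01"),
            "t_s": tau,
            "spo2_dev": m.spo2_compensated,
            "spo2_ref": float(np.interp(tau, ref_t, reference["spo2"].to_numpy(dtype=float))),
            "hr_dev": m.hr,
            "hr_ref": float(np.interp(tau, ref_t, reference["hr"].to_numpy(dtype=float))),
            "acquisition_order": order,
        }
        for key in ("age_years", "sex", "skin", "bmi"):
            if subject and key in subject:
                row[key] = subject[key]
        rows.append(row)
        order += 1
    cols = ["subject_id", "t_s", "spo2_dev", "spo2_ref", "hr_dev", "hr_ref",
            "acquisition_order"]
    return pd.DataFrame(rows) if rows else pd.DataFrame(columns=cols)


# ---------------------------------------------------------------------------
# Conditioning: outliers, normality, range equalization
# ---------------------------------------------------------------------------

def remove_outliers(pairs: pd.DataFrame, k: float = 2.0) -> pd.DataFrame:
    """Single-pass outlier removal on the SpO2 error.

    The error e = spo2_dev - spo2_ref is computed over all pairs; pairs
    with |e - mean(e)| > k * SD(e) (sample SD, n-1 denominator) are
    dropped.  Applied exactly once — re-running on the output may remove
    more pairs, which is deliberately not done.
    """
    if len(pairs) < 3:
        raise ValueError("outlier removal requires at least 3 pairs")
    e = (pairs["spo2_dev"] - pairs["spo2_ref"]).to_numpy(dtype=float)
    mu = e.mean()
    sd = e.std(ddof=1)
    if math.isinf(k):
        return pairs.copy()
    keep = np.abs(e - mu) <= k * sd
    return pairs.loc[keep].copy()


def ks_normality_check(errors: Sequence[float]) -> Tuple[float, float]:
    """One-sample KS test of the standardized errors against N(0, 1).

    Returns (statistic, asymptotic p-value).  Raises on fewer than five
    values or zero variance.
    """
    e = np.asarray(errors, dtype=float)
    if len(e) < 5:
        raise ValueError("normality check requires at least 5 values")
    sd = e.std(ddof=1)
    if sd == 0:
        raise ValueError("normality check undefined for zero-variance errors")
    z = (e - e.mean()) / sd
    res = stats.kstest(z, "norm", method="asymp")
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class RangeBins:
    """Closed integer-percent bins partitioning the 80-100 % reference
    range; reference values are rounded to the nearest integer percent
    (oximeter display convention) before binning."""

    edges: Tuple[Tuple[int, int], ...] = ((80, 86), (87, 93), (94, 100))

    def assign(self, spo2_ref: np.ndarray) -> np.ndarray:
        """Bin index per pair; -1 for values outside every bin."""
        rounded = np.floor(np.asarray(spo2_ref, dtype=float) + 0.5)
        out = np.full(len(rounded), -1, dtype=int)
        for i, (lo, hi) in enumerate(self.edges):
            out[(rounded >= lo) & (rounded <= hi)] = i
        return out


def equalize_ranges(
    pairs: pd.DataFrame, bins: RangeBins = RangeBins()
) -> pd.DataFrame:
    """Balance the reference-SpO2 bins by cyclic per-subject removal.

    For every bin holding more pairs than the smallest (non-empty) bin,
    subjects are visited cyclically in ascending id order and each
    visited subject's last-acquired pair in that bin is removed (subjects
    with none left are skipped) until the bin count reaches the smallest
    bin's count.  The smallest bin is untouched; retained pairs keep
    their original order.  Deterministic.
    """
    if pairs.empty:
        return pairs.copy()
    df = pairs
    bin_idx = pd.Series(bins.assign(df["spo2_ref"].to_numpy()), index=df.index)
    counts = {
        b: int((bin_idx == b).sum())
        for b in range(len(bins.edges))
        if bool((bin_idx == b).any())
    }
    if not counts:
        return pairs.copy()
    target = min(counts.values())
    subjects = sorted(df["subject_id"].unique())
    removed: set = set()
    for b, count in counts.items():
        while count > target:
            progressed = False
            for s in subjects:
                if count <= target:
                    break
                cand = df.index[
                    (bin_idx == b)
                    & (df["subject_id"] == s)
                    & ~df.index.isin(list(removed))
                ]
                if len(cand) == 0:
                    continue
                sub = df.loc[cand]
                # last acquired; ties broken toward later file order
                last = sub.sort_values(
                    ["acquisition_order"], kind="stable"
                ).index[-1]
                removed.add(last)
                count -= 1
                progressed = True
            if not progressed:  # pragma: no cover - bin exhausted defensively
                break
    kept = df.loc[~df.index.isin(list(removed))]
    return kept.copy()


def conditioning_log(
    before: pd.DataFrame, after: pd.DataFrame, stage: str
) -> dict:
    """Structured record of one conditioning step (for run logs)."""
    removed = before.index.difference(after.index)
    return {
        "stage": stage,
        "n_in": int(len(before)),
        "n_out": int(len(after)),
        "removed": [int(i) for i in removed],
    }
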