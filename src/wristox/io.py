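"""CSV/JSON/YAML plumbing for recordings, measurements and paired readings.

Dialect: comma-separated UTF-8, "." decimal, timestamps as seconds from
start, full float precision (repr) so files round-trip bit-exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import List, Optional, Union

import numpy as np
import pandas as pd

from .types import Measurement, RawRecording, SubjectInfo

PathLike = Union[str, Path]

RECORDING_COLUMNS = ["t_s", "red", "ir", "ax", "ay", "az"]
PAIRS_COLUMNS = [
    "subject_id", "t_s", "spo2_dev", "spo2_ref", "hr_dev", "hr_ref",
    "age_years", "sex", "skin", "bmi",
]
MEASUREMENT_COLUMNS = [
    "t_s", "spo2_raw", "spo2_comp", "hr", "qc_passed", "motion_free",
    "valid", "fail_reason",
]


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def write_recording_csv(recording: RawRecording, path: PathLike) -> Path:
    """Write a recording as CSV plus a sidecar JSON with site and subject
    metadata (same stem, .json suffix)."""
    path = Path(path)
    n = recording.n_samples
    df = pd.DataFrame(
        {
            "t_s": np.arange(n) / recording.fs,
            "red": recording.red,
            "ir": recording.ir,
            "ax": recording.accel[:, 0],
            "ay": recording.accel[:, 1],
            "az": recording.accel[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format=None)
    meta = {
        "fs": recording.fs,
        "site": recording.site,
        **dataclasses.asdict(recording.subject),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_recording_csv(path: PathLike) -> RawRecording:
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(RECORDING_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    else:
        meta = {}
    fs = float(meta.get("fs", 50.0))
    subject = SubjectInfo(
        subject_id=meta.get("subject_id", path.stem),
        age_years=float(meta.get("age_years", 37.0)),
        sex=meta.get("sex", "M"),
        skin=meta.get("skin", "white"),
        bmi=float(meta.get("bmi", 26.2)),
    )
    return RawRecording(
        red=df["red"].to_numpy(np.int64),
        ir=df["ir"].to_numpy(np.int64),
        accel=df[["ax", "ay", "az"]].to_numpy(float),
        fs=fs,
        site=meta.get("site", "wrist"),
        subject=subject,
    )


def write_measurements_csv(measurements: List[Measurement], path: PathLike) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "t_s": [m.time for m in measurements],
            "spo2_raw": [m.spo2_raw for m in measurements],
            "spo2_comp": [m.spo2_compensated for m in measurements],
            "hr": [m.hr for m in measurements],
            "qc_passed": [m.qc_passed for m in measurements],
            "motion_free": [m.motion_free for m in measurements],
            "valid": [m.valid for m in measurements],
            "fail_reason": [m.fail_reason or "" for m in measurements],
        }
    )
    df.to_csv(path, index=False)
    return path


def read_measurements_csv(path: PathLike) -> List[Measurement]:
    df = pd.read_csv(Path(path), keep_default_na=False, na_values=["nan", ""])
    out: List[Measurement] = []
    for row in df.itertuples(index=False):
        reason = getattr(row, "fail_reason", "")
        reason = None if (isinstance(reason, float) or reason == "") else str(reason)
        out.append(
            Measurement(
                time=float(row.t_s),
                spo2_raw=float(row.spo2_raw),
                spo2_compensated=float(row.spo2_comp),
                hr=float(row.hr),
                qc_passed=bool(row.qc_passed),
                motion_free=bool(row.motion_free),
                valid=bool(row.valid),
                fail_reason=reason,
            )
        )
    return out


def write_pairs_csv(pairs: pd.DataFrame, path: PathLike) -> Path:
    path = Path(path)
    cols = [c for c in PAIRS_COLUMNS if c in pairs.columns]
    extra = [c for c in ("acquisition_order",) if c in pairs.columns]
    pairs[cols + extra].to_csv(path, index=False)
    return path


def read_pairs_csv(path: PathLike) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed CSV: {exc}") from exc
    required = {"subject_id", "spo2_dev", "spo2_ref"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for col in ("spo2_dev", "spo2_ref", "hr_dev", "hr_ref"):
        if col in df.columns:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            if len(bad):
                # +2: header line plus 1-based numbering
                raise ValueError(
                    f"{path}: non-numeric value in column '{col}' at line {bad[0] + 2}"
                )
    if "acquisition_order" not in df.columns:
        # derive per-subject acquisition order from time order
        if "t_s" in df.columns:
            df["acquisition_order"] = (
                df.groupby("subject_id")["t_s"].rank(method="first").astype(int) - 1
            )
        else:
            df["acquisition_order"] = df.groupby("subject_id").cumcount()
    return df
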