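"""Shared fixtures: small synthetic recordings and pair tables.

Everything is generated programmatically from fixed seeds; no data files.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from wristox.synth import (
    ErrorModel,
    PhysioProfile,
    generate_paired_dataset,
    generate_recording,
)


def steady_profile(sao2: float, hr: float, duration: float = 60.0) -> PhysioProfile:
    """Constant-saturation profile for short test recordings."""
    return PhysioProfile(
        plateau_targets=[sao2],
        plateau_duration=duration,
        pre_plateau_wait=0.0,
        hr_trajectory=hr,
        transition_time=0.0,
    )


@pytest.fixture(scope="session")
def clean_recording():
    """60 s still recording at SaO2 97 %, HR 75 bpm."""
    return generate_recording(steady_profile(97.0, 75.0), seed=11, duration=60.0)


@pytest.fixture(scope="session")
def clean_epoch(clean_recording):
    """A 10 s epoch (samples 500-1000) of the clean recording."""
    r = clean_recording
    sl = slice(500, 1000)
    return r.red[sl].astype(float), r.ir[sl].astype(float), r.accel[sl]


@pytest.fixture()
def zero_error_pairs():
    """Paired table where device readings equal the reference exactly."""
    return generate_paired_dataset(60, error_model=ErrorModel(seed=3))


def binned_pair_table(bin_counts, n_subjects: int = 12) -> pd.DataFrame:
    """Pair table with exact reference-bin occupancies, subjects assigned
    round-robin with increasing per-subject acquisition order."""
    centers = {0: 83.0, 1: 90.0, 2: 97.0}
    rows = []
    k = 0
    per_subject_order = {}
    for b, cnt in enumerate(bin_counts):
        for _ in range(cnt):
            sid = f"S{(k % n_subjects) + 1:02d}"
            order = per_subject_order.get(sid, 0)
            per_subject_order[sid] = order + 1
            rows.append(
                {
                    "subject_id": sid,
                    "t_s": 20.0 * order,
                    "spo2_dev": centers[b],
                    "spo2_ref": centers[b],
                    "hr_dev": 75.0,
                    "hr_ref": 75.0,
                    "acquisition_order": order,
                }
            )
            k += 1
    return pd.DataFrame(rows)
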