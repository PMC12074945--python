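"""Inference: from a subject profile to a decoded FITT prescription.

A trained network, fed an encoded subject with the desired improvement
(default 10 % of baseline), emits the four prescription codes, which are
decoded back to physical units: frequency rounded to the nearest
positive integer, intensity reported as a midpoint with a configurable
+/- band (default 5 %HRR), time in minutes and volume in weeks at two
decimals.

Decoded values are screened for plausibility (intensity 40-90 %HRR,
time 10-90 min, volume 4-52 wk — deliberately wider than guideline
ranges to warn without blocking); violations are flagged, never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .encoding import (
    Prescription,
    SubjectProfile,
    encode_subject,
    round_half_up,
)
from .network import NetworkState, forward

__all__ = [
    "PrescriptionRequest",
    "PrescriptionResult",
    "prescribe",
    "batch_prescribe",
    "SCREENING_BOUNDS",
]

SCREENING_BOUNDS = {
    "intensity": (40.0, 90.0),   # %HRR
    "time": (10.0, 90.0),        # min/session
    "volume": (4.0, 52.0),       # weeks
}


@dataclass(frozen=True)
class PrescriptionRequest:
    profile: SubjectProfile
    target_improvement: float = 0.10

    def __post_init__(self) -> None:
        if self.target_improvement <= 0:
            raise ValueError("target_improvement must be positive")


@dataclass(frozen=True)
class PrescriptionResult:
    prescription: Prescription
    flags: tuple[str, ...]
    model_id: str | None = None


def _screen(y: np.ndarray, rx_values: dict[str, float]) -> list[str]:
    flags = []
    if y[2] < 0 or y[3] < 0:
        flags.append("negative raw time/volume output")
    for name, (lo, hi) in SCREENING_BOUNDS.items():
        v = rx_values[name]
        if not lo <= v <= hi:
            flags.append(f"{name} {v:g} outside plausible range [{lo:g}, {hi:g}]")
    return flags


def prescribe(
    model: NetworkState,
    req: PrescriptionRequest,
    band_pct: float = 5.0,
    model_id: str | None = None,
) -> PrescriptionResult:
    """Encode the profile, forward-pass, decode, and screen.

    Pure function of (model, request): identical requests yield
    identical prescriptions.
    """
    x = encode_subject(
        SubjectProfile(
            age=req.profile.age,
            sex=req.profile.sex,
            bmi=req.profile.bmi,
            vo2_pre=req.profile.vo2_pre,
            improvement=req.target_improvement,
        )
    )
    y = forward(model, x)
    if not np.all(np.isfinite(y)):
        raise ValueError("model produced non-finite output (untrained or diverged?)")
    freq = max(1, int(round_half_up(y[0])))
    pct = (float(y[1]) + 0.5) * 100.0
    time = round_half_up(float(y[2]), 2)
    vol = round_half_up(float(y[3]), 2)
    flags = _screen(y, {"intensity": pct, "time": time, "volume": vol})
    # construct without the dataclass validators so implausible model
    # output is reported with flags instead of crashing
    rx = Prescription.__new__(Prescription)
    object.__setattr__(rx, "frequency", freq)
    object.__setattr__(rx, "intensity", pct)
    object.__setattr__(rx, "time", time)
    object.__setattr__(rx, "volume", vol)
    object.__setattr__(rx, "intensity_range", (pct - band_pct, pct + band_pct))
    return PrescriptionResult(prescription=rx, flags=tuple(flags), model_id=model_id)


def batch_prescribe(
    model: NetworkState,
    roster: Sequence[SubjectProfile],
    target_improvement: float = 0.10,
    band_pct: float = 5.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Prescribe for every subject and summarize per element.

    Returns (per-subject table, summary table).  The summary gives mean,
    SD (n-1) and min-max per prescription element, the format used to
    report group prescriptions.  Per-row failures are recorded in the
    flags column, not fatal.
    """
    if not roster:
        raise ValueError("roster is empty")
    rows = []
    for i, profile in enumerate(roster):
        try:
            res = prescribe(
                model, PrescriptionRequest(profile, target_improvement), band_pct
            )
            rx = res.prescription
            rows.append(
                {
                    "subject": i + 1, "age": profile.age, "sex": profile.sex,
                    "bmi": profile.bmi, "vo2_pre": profile.vo2_pre,
                    "frequency": rx.frequency, "intensity_pct_hrr": rx.intensity,
                    "intensity_low": rx.intensity_range[0],
                    "intensity_high": rx.intensity_range[1],
                    "time_min": rx.time, "volume_wk": rx.volume,
                    "flags": "; ".join(res.flags),
                }
            )
        except Exception as exc:  # per-row failure -> reported, not fatal
            rows.append({"subject": i + 1, "flags": f"ERROR: {exc}"})
    table = pd.DataFrame(rows)
    elements = ["frequency", "intensity_pct_hrr", "time_min", "volume_wk"]
    summary_rows = []
    for el in elements:
        v = table[el].dropna().to_numpy(float)
        summary_rows.append(
            {
                "element": el,
                "mean": float(v.mean()),
                "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
                "min": float(v.min()),
                "max": float(v.max()),
            }
        )
    return table, pd.DataFrame(summary_rows)
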