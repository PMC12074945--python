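"""Numeric coding of subject profiles and FITT prescriptions.

The network consumes a 5-vector (age, sex, BMI, baseline VO2max,
target improvement) and emits a 4-vector (frequency, intensity code,
time, volume).  Exercise intensity in %HRR is coded as a decimal offset
about the 50 %HRR reference: ``code = pct/100 - 0.5``, so 60 %HRR maps
to 0.1 and 50 %HRR to 0.  When a study reports an intensity *range*, the
midpoint is coded.  Age, BMI and baseline VO2max carry one decimal
place; improvement (a fraction of baseline, e.g. 0.10 for 10 %), time
(minutes) and volume (weeks) carry two.  Sex is a binary indicator
(0 = female, 1 = male).

Frequency (sessions/week) has no published transform and is carried as
its raw numeric value; decoded model output is rounded to the nearest
positive integer.  All rounding is round-half-up (half away from zero),
applied once at encoding time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SubjectProfile",
    "Prescription",
    "EncodedSample",
    "round_half_up",
    "encode_intensity",
    "decode_intensity",
    "encode_intensity_range",
    "encode_subject",
    "decode_subject",
    "encode_prescription",
    "decode_prescription",
]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (the convention used throughout)."""
    scale = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


@dataclass(frozen=True)
class SubjectProfile:
    """Basic information for one subject.

    age : years (1 decimal); sex : 0 = female, 1 = male;
    bmi : kg/m^2 (1 decimal); vo2_pre : baseline VO2max in
    mL.kg^-1.min^-1 (1 decimal); improvement : target VO2max gain as a
    fraction of baseline (2 decimals, 0.10 = 10 %).
    """

    age: float
    sex: int
    bmi: float
    vo2_pre: float
    improvement: float

    def __post_init__(self) -> None:
        if not (self.age > 0 and self.bmi > 0 and self.vo2_pre > 0):
            raise ValueError("age, bmi and vo2_pre must be positive")
        if self.sex not in (0, 1):
            raise ValueError(f"sex must be 0 (female) or 1 (male), got {self.sex!r}")
        if self.improvement <= 0:
            raise ValueError("improvement must be positive")


@dataclass(frozen=True)
class Prescription:
    """One FITT prescription: frequency (d/wk), intensity (%HRR midpoint),
    time (min/session), volume (weeks)."""

    frequency: float
    intensity: float
    time: float
    volume: float
    intensity_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.frequency < 1:
            raise ValueError("frequency must be >= 1 session/week")
        if not (0 < self.intensity < 100):
            raise ValueError("intensity must be in (0, 100) %HRR")
        if self.time <= 0 or self.volume <= 0:
            raise ValueError("time and volume must be positive")
        if self.intensity_range is not None:
            lo, hi = self.intensity_range
            if not (lo <= self.intensity <= hi):
                raise ValueError("intensity_range must bracket the midpoint")


@dataclass(frozen=True)
class EncodedSample:
    """Paired network input (5-vector) and target (4-vector)."""

    x: np.ndarray
    y: np.ndarray
    study_id: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if self.x.shape != (5,) or self.y.shape != (4,):
            raise ValueError("x must be a 5-vector and y a 4-vector")


def encode_intensity(pct_hrr: float) -> float:
    """Map %HRR to the network's intensity code: pct/100 - 0.5."""
    if not 0 < pct_hrr < 100:
        raise ValueError(f"intensity must be in (0, 100) %HRR, got {pct_hrr}")
    return pct_hrr / 100.0 - 0.5


def decode_intensity(code: float) -> float:
    """Inverse of :func:`encode_intensity`: (code + 0.5) * 100."""
    if not -0.5 < code < 0.5:
        raise ValueError(f"intensity code must be in (-0.5, 0.5), got {code}")
    return (code + 0.5) * 100.0


def encode_intensity_range(low: float, high: float) -> float:
    """Code the midpoint of a reported %HRR range."""
    if low > high:
        raise ValueError(f"range low {low} exceeds high {high}")
    return encode_intensity((low + high) / 2.0)


def encode_subject(profile: SubjectProfile) -> np.ndarray:
    """Profile -> [age, sex, bmi, vo2_pre, improvement] with canonical rounding."""
    return np.array(
        [
            round_half_up(profile.age, 1),
            float(profile.sex),
            round_half_up(profile.bmi, 1),
            round_half_up(profile.vo2_pre, 1),
            round_half_up(profile.improvement, 2),
        ]
    )


def decode_subject(x: Sequence[float]) -> SubjectProfile:
    x = np.asarray(x, dtype=float)
    if x.shape != (5,):
        raise ValueError("subject vector must have 5 components")
    return SubjectProfile(
        age=float(x[0]),
        sex=int(round(x[1])),
        bmi=float(x[2]),
        vo2_pre=float(x[3]),
        improvement=float(x[4]),
    )


def encode_prescription(rx: Prescription) -> np.ndarray:
    """Prescription -> [frequency, intensity code, time, volume].

    Frequency is carried raw; intensity is the coded midpoint (from the
    stated range when present); time and volume keep two decimals.
    """
    if rx.intensity_range is not None:
        code = encode_intensity_range(*rx.intensity_range)
    else:
        code = encode_intensity(rx.intensity)
    return np.array(
        [
            float(rx.frequency),
            code,
            round_half_up(rx.time, 2),
            round_half_up(rx.volume, 2),
        ]
    )


def decode_prescription(y: Sequence[float], band_pct: float = 5.0) -> Prescription:
    """4-vector -> Prescription.  Frequency is rounded to the nearest
    positive integer; the intensity range defaults to midpoint +/- 5 %HRR
    (``band_pct`` widens it to e.g. +/-10)."""
    y = np.asarray(y, dtype=float)
    if y.shape != (4,):
        raise ValueError("prescription vector must have 4 components")
    if np.any(~np.isfinite(y)):
        raise ValueError("prescription vector must be finite")
    freq = max(1, int(round_half_up(y[0])))
    pct = decode_intensity(float(y[1]))
    lo = max(pct - band_pct, 0.0 + 1e-9)
    hi = min(pct + band_pct, 100.0 - 1e-9)
    return Prescription(
        frequency=freq,
        intensity=pct,
        time=round_half_up(float(y[2]), 2),
        volume=round_half_up(float(y[3]), 2),
        intensity_range=(lo, hi),
    )
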