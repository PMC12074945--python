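"""Validation statistics for prescription models.

Covers the standard regression metrics (MAE, RMSE, R^2, MSE, Pearson R),
relative prescription error ratios with a tolerance band, improvement
hit rates (fraction of subjects whose observed gain falls within
mean +/- k*SD of the group), Bland-Altman agreement (bias and 95 %
limits of agreement), and expected-versus-observed linear regression.

Conventions: sample standard deviations use the n-1 denominator; band
bounds are inclusive; error ratios are signed as (predicted - target) /
target so a negative mean means under-prescription; Bland-Altman
differences default to (expected - observed); whole-percent rates use
round-half-up.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .encoding import Prescription, round_half_up

__all__ = [
    "MetricSet",
    "ErrorRatioReport",
    "HitRateBand",
    "AgreementReport",
    "RegressionReport",
    "metric_set",
    "error_ratios",
    "hit_rate",
    "percent_rate",
    "dropout_rate",
    "bland_altman",
    "expected_vs_observed_regression",
]


@dataclass(frozen=True)
class MetricSet:
    rmse: float
    mae: float
    r2: float
    mse: float
    pearson_r: float
    r2_defined: bool = True


def metric_set(pred: Sequence[float], target: Sequence[float]) -> MetricSet:
    """Pooled MAE/RMSE/MSE/R^2/Pearson R over paired predictions.

    A zero-variance target leaves R^2 (and R) undefined; they come back
    as NaN with ``r2_defined`` False rather than raising.
    """
    p = np.asarray(pred, dtype=float).ravel()
    t = np.asarray(target, dtype=float).ravel()
    if p.shape != t.shape or p.size < 2:
        raise ValueError("pred and target must be equal-length with n >= 2")
    r = p - t
    mse = float(np.mean(r ** 2))
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    defined = ss_tot > 0 and np.std(p) > 0
    if ss_tot > 0:
        r2 = 1.0 - float(np.sum(r ** 2)) / ss_tot
    else:
        r2 = np.nan
    if defined:
        pearson = float(np.corrcoef(p, t)[0, 1])
    else:
        pearson = np.nan
    return MetricSet(
        rmse=float(np.sqrt(mse)),
        mae=float(np.mean(np.abs(r))),
        r2=r2,
        mse=mse,
        pearson_r=pearson,
        r2_defined=bool(ss_tot > 0),
    )


@dataclass(frozen=True)
class ErrorRatioReport:
    """Signed relative deviations (%) per prescription element."""

    ratios: dict[str, np.ndarray]
    mean: dict[str, float]
    sd: dict[str, float]
    within_band: dict[str, float]
    tolerance: float
    n_excluded: int = 0


_RATIO_ELEMENTS = ("intensity", "time", "volume")


def error_ratios(
    pred: Sequence[Prescription],
    target: Sequence[Prescription],
    tolerance: float = 20.0,
) -> ErrorRatioReport:
    """Relative deviations 100*(pred - target)/target for intensity,
    time and volume, with the fraction inside +/- ``tolerance`` %.

    Pairs whose target element is zero are excluded with a warning.
    """
    if len(pred) != len(target) or not pred:
        raise ValueError("pred and target must be nonempty and equal length")
    ratios: dict[str, list[float]] = {k: [] for k in _RATIO_ELEMENTS}
    n_excluded = 0
    for p, t in zip(pred, target):
        for name in _RATIO_ELEMENTS:
            tv = getattr(t, name)
            pv = getattr(p, name)
            if tv == 0:
                n_excluded += 1
                warnings.warn(f"zero target {name}; pair excluded", stacklevel=2)
                continue
            ratios[name].append(100.0 * (pv - tv) / tv)
    arr = {k: np.asarray(v, dtype=float) for k, v in ratios.items()}
    mean = {k: float(v.mean()) if v.size else np.nan for k, v in arr.items()}
    sd = {
        k: float(v.std(ddof=1)) if v.size > 1 else np.nan for k, v in arr.items()
    }
    within = {
        k: float(np.mean(np.abs(v) <= tolerance)) if v.size else np.nan
        for k, v in arr.items()
    }
    return ErrorRatioReport(
        ratios=arr, mean=mean, sd=sd, within_band=within,
        tolerance=tolerance, n_excluded=n_excluded,
    )


def percent_rate(hits: int, n: int) -> int:
    """Whole-percent rate, round-half-up (e.g. 43/61 -> 70)."""
    if not 0 <= hits <= n or n < 1:
        raise ValueError("need 0 <= hits <= n with n >= 1")
    return int(round_half_up(100.0 * hits / n))


def dropout_rate(enrolled: int, completed: int) -> float:
    """Study dropout as a one-decimal percent (e.g. 64 enrolled, 61
    completed -> 4.7)."""
    if completed > enrolled or enrolled < 1:
        raise ValueError("need 0 <= completed <= enrolled")
    return round_half_up(100.0 * (enrolled - completed) / enrolled, 1)


@dataclass(frozen=True)
class HitRateBand:
    M: float
    sd: float
    k: float
    range: tuple[float, float]
    hits: int
    n: int
    rate: int


def hit_rate(improvements: Sequence[float], k: float = 1.0) -> HitRateBand:
    """Fraction of observed improvements (%) inside M +/- k*sd.

    M and sd are the sample mean and n-1 standard deviation of the
    improvements themselves; bounds are inclusive; the rate is a whole
    percent (round-half-up).  Typical k: 1 and 1.96.
    """
    v = np.asarray(improvements, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 improvements")
    M = float(v.mean())
    sd = float(v.std(ddof=1))
    lo, hi = M - k * sd, M + k * sd
    hits = int(np.sum((v >= lo) & (v <= hi)))
    return HitRateBand(
        M=M, sd=sd, k=k, range=(lo, hi), hits=hits, n=v.size,
        rate=percent_rate(hits, v.size),
    )


@dataclass(frozen=True)
class AgreementReport:
    bias: float
    loa_low: float
    loa_high: float
    coverage: float
    sd_diff: float
    n: int


def bland_altman(
    expected: Sequence[float],
    observed: Sequence[float],
    orientation: str = "expected-observed",
) -> AgreementReport:
    """Bland-Altman agreement: bias and 95 % limits of agreement.

    Differences are ``expected - observed`` by default (flip with
    ``orientation="observed-expected"``); LoA = bias +/- 1.96 * sd of the
    differences; coverage is the percent of differences inside the LoA.
    """
    e = np.asarray(expected, dtype=float)
    o = np.asarray(observed, dtype=float)
    if e.shape != o.shape or e.size < 2:
        raise ValueError("expected and observed must be paired with n >= 2")
    if orientation == "expected-observed":
        d = e - o
    elif orientation == "observed-expected":
        d = o - e
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = bias - 1.96 * sd, bias + 1.96 * sd
    coverage = float(100.0 * np.mean((d >= lo) & (d <= hi)))
    return AgreementReport(
        bias=bias, loa_low=lo, loa_high=hi, coverage=coverage, sd_diff=sd, n=d.size
    )


@dataclass(frozen=True)
class RegressionReport:
    slope: float
    intercept: float
    r2: float
    slope_ci: tuple[float, float]
    p_value: float
    n: int


def expected_vs_observed_regression(
    expected: Sequence[float], observed: Sequence[float]
) -> RegressionReport:
    """OLS of observed on expected with 95 % slope CI and the p-value of
    the non-zero-slope test."""
    e = np.asarray(expected, dtype=float)
    o = np.asarray(observed, dtype=float)
    if e.shape != o.shape or e.size < 3:
        raise ValueError("need paired data with n >= 3")
    if np.var(e) == 0:
        raise ValueError("expected values are degenerate (zero variance)")
    model = sm.OLS(o, sm.add_constant(e)).fit()
    ci = model.conf_int(alpha=0.05)
    return RegressionReport(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r2=float(model.rsquared),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        p_value=float(model.pvalues[1]),
        n=e.size,
    )
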