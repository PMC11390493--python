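"""Weak-stationarity preprocessing of trending CPET signals.

A ramp test drives every channel upward, so the raw series are trend
nonstationary.  The pipeline slices each channel at the ventilatory
threshold, first-differences each side, standardizes to zero mean and unit
(population) variance, and verifies weak stationarity with the augmented
Dickey-Fuller test, correcting the per-record family of p-values with the
Holm-Sidak step-down procedure.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from statsmodels.tsa.stattools import adfuller

from .io_cpet import METRICS, CpetRecord

__all__ = [
    "Signal",
    "StationarityReport",
    "SegmentResult",
    "DegenerateSignalError",
    "difference",
    "standardize",
    "adf_test",
    "holm_sidak_adjust",
    "make_stationary_segments",
    "ADF_MIN_LENGTH",
    "SIDES",
]

#: Segment labels: before/after VT1, or the whole un-split signal.
SIDES = ("before", "after")

#: Minimum length for the ADF regression to be meaningful.
ADF_MIN_LENGTH = 20


class DegenerateSignalError(ValueError):
    """Zero-variance (or otherwise unusable) signal."""


@dataclasses.dataclass(frozen=True)
class Signal:
    """An ordered real-valued series with its metric and segment labels."""

    values: np.ndarray
    metric: str | None = None
    segment: str | None = None  # "before" | "after" | "whole"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("a Signal needs a 1-d series of length >= 2")
        if not np.all(np.isfinite(values)):
            raise ValueError("Signal values must be finite")

    def __len__(self) -> int:
        return self.values.size


def _as_signal(x: Signal | Sequence[float] | np.ndarray) -> Signal:
    return x if isinstance(x, Signal) else Signal(np.asarray(x, dtype=float))


@dataclasses.dataclass(frozen=True)
class StationarityReport:
    """ADF unit-root test outcome, optionally with a family-wise adjustment."""

    adf_statistic: float
    p_value: float
    alpha: float
    is_stationary_raw: bool
    p_adjusted: float | None = None
    is_stationary_adjusted: bool | None = None


def difference(x: Signal | np.ndarray) -> Signal:
    """First difference x̃_t = x_t − x_{t−1}, length N−1, labels carried over."""
    sig = _as_signal(x)
    if len(sig) < 3:
        raise ValueError("differencing needs at least 3 observations")
    return Signal(np.diff(sig.values), metric=sig.metric, segment=sig.segment)


def standardize(x: Signal | np.ndarray) -> Signal:
    """Center and scale to zero mean, unit population variance (divide by N)."""
    sig = _as_signal(x)
    v = sig.values
    sd = float(np.std(v))  # ddof=0
    if sd == 0.0 or not np.isfinite(sd):
        raise DegenerateSignalError(
            f"zero-variance signal (metric={sig.metric}, segment={sig.segment})"
        )
    return Signal((v - v.mean()) / sd, metric=sig.metric, segment=sig.segment)


def adf_test(x: Signal | np.ndarray, alpha: float = 0.05) -> StationarityReport:
    """Augmented Dickey-Fuller unit-root test; rejection implies stationarity.

    Regression with constant, no trend (the differenced segments are mean
    zero by construction); lag order chosen by AIC up to ⌊(N−1)^(1/3)⌋.
    """
    sig = _as_signal(x)
    n = len(sig)
    if n < ADF_MIN_LENGTH:
        raise ValueError(f"ADF test needs at least {ADF_MIN_LENGTH} observations, got {n}")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    maxlag = int(np.floor((n - 1) ** (1.0 / 3.0)))
    stat, pvalue, *_ = adfuller(sig.values, maxlag=maxlag, regression="c", autolag="AIC")
    return StationarityReport(
        adf_statistic=float(stat),
        p_value=float(pvalue),
        alpha=alpha,
        is_stationary_raw=bool(pvalue < alpha),
    )


def holm_sidak_adjust(
    p_values: Sequence[float], alpha: float = 0.05
) -> list[tuple[float, bool]]:
    """Holm-Sidak step-down adjustment.

    Sort ascending; the i-th ordered p gets 1 − (1 − p_(i))^(n−i+1), enforced
    monotone nondecreasing down the sequence and clipped at 1; reject when
    the adjusted p is below ``alpha``.  Results return in the input order.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="mergesort")
    n = p.size
    ranks = np.arange(n)
    stepwise = 1.0 - (1.0 - p[order]) ** (n - ranks)
    adjusted_sorted = np.minimum(np.maximum.accumulate(stepwise), 1.0)
    adjusted = np.empty(n)
    adjusted[order] = adjusted_sorted
    return [(float(pa), bool(pa < alpha)) for pa in adjusted]


@dataclasses.dataclass(frozen=True)
class SegmentResult:
    """One (metric, side) slice after differencing and standardization."""

    signal: Signal | None
    report: StationarityReport | None
    degenerate: bool = False


def make_stationary_segments(
    record: CpetRecord,
    vt1_index: int,
    alpha: float = 0.05,
    metrics: Sequence[str] = METRICS,
) -> dict[tuple[str, str], SegmentResult]:
    """Slice every metric at VT1, difference, standardize, and ADF-test.

    ``vt1_index`` is the 1-based count k of pre-threshold breaths: the
    before-segment is breaths 1..k, the after-segment k+1..N.  Each side must
    keep at least ``ADF_MIN_LENGTH + 1`` breaths so the differenced series
    supports the ADF regression.  All raw p-values of one record form a
    single Holm-Sidak family; zero-variance segments are flagged and
    excluded from the family.
    """
    n = record.n_breaths
    min_side = ADF_MIN_LENGTH + 1
    if not (min_side <= vt1_index <= n - min_side):
        raise ValueError(
            f"vt1_index={vt1_index} leaves fewer than {min_side} breaths on one side "
            f"of a {n}-breath record"
        )
    prepared: dict[tuple[str, str], SegmentResult] = {}
    family_keys: list[tuple[str, str]] = []
    family_p: list[float] = []
    for metric in metrics:
        values = record.channel(metric)
        for side, chunk in (("before", values[:vt1_index]), ("after", values[vt1_index:])):
            raw = Signal(chunk, metric=metric, segment=side)
            try:
                prep = standardize(difference(raw))
            except DegenerateSignalError:
                prepared[(metric, side)] = SegmentResult(None, None, degenerate=True)
                continue
            report = adf_test(prep, alpha=alpha)
            prepared[(metric, side)] = SegmentResult(prep, report)
            family_keys.append((metric, side))
            family_p.append(report.p_value)
    for key, (p_adj, reject) in zip(family_keys, holm_sidak_adjust(family_p, alpha)):
        res = prepared[key]
        assert res.report is not None
        prepared[key] = SegmentResult(
            res.signal,
            dataclasses.replace(res.report, p_adjusted=p_adj, is_stationary_adjusted=reject),
        )
    return prepared
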