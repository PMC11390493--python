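"""Automated first-ventilatory-threshold (VT1) detection.

VT1 is estimated as the breath index that best partitions a detection series
into two segments under a two-segment log-variance objective, applied to two
standard detection series — the V-slope response (V̇CO2 over the breath
index) and excess CO2 (V̇CO2²/V̇O2 − V̇CO2) — and averaging the two indices.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np

from .io_cpet import CpetRecord

__all__ = [
    "Vt1Estimate",
    "ChangePoint",
    "exco2_series",
    "logvar_changepoint",
    "detect_vt1",
    "VARIANCE_FLOOR",
]

#: Floor inside the log to avoid −inf on near-constant segments.
VARIANCE_FLOOR = 1e-12


@dataclasses.dataclass(frozen=True)
class ChangePoint:
    k: int  # 1-based: first segment is x[1..k]
    objective: float


@dataclasses.dataclass(frozen=True)
class Vt1Estimate:
    """Per-method change points and their (half-up rounded) average."""

    k_vslope: int
    k_exco2: int
    k_mean: int
    time_at_k: float  # seconds, at breath k_mean
    objective_vslope: float
    objective_exco2: float
    options: dict = dataclasses.field(default_factory=dict)


def exco2_series(vo2: np.ndarray, vco2: np.ndarray) -> np.ndarray:
    """Excess-CO2 detection series: V̇CO2²/V̇O2 − V̇CO2 (= V̇CO2·(RER − 1))."""
    vo2 = np.asarray(vo2, dtype=float)
    vco2 = np.asarray(vco2, dtype=float)
    if vo2.shape != vco2.shape:
        raise ValueError("vo2 and vco2 must have equal length")
    if np.any(vo2 <= 0):
        raise ValueError("vo2 must be positive everywhere")
    return vco2 * vco2 / vo2 - vco2


def _segment_variances(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Population variances of every prefix x[:k] and suffix x[k:] in O(N)."""
    n = x.size
    s1 = np.cumsum(x)
    s2 = np.cumsum(x * x)
    k = np.arange(1, n + 1, dtype=float)
    pre = s2 / k - (s1 / k) ** 2
    rev1 = s1[-1] - np.concatenate([[0.0], s1[:-1]])
    rev2 = s2[-1] - np.concatenate([[0.0], s2[:-1]])
    length = n - np.arange(n, dtype=float)
    post = rev2 / length - (rev1 / length) ** 2
    return np.maximum(pre, 0.0), np.maximum(post, 0.0)


def logvar_changepoint(
    x: np.ndarray,
    min_size: int = 10,
    *,
    coefficients: str = "as-printed",
) -> ChangePoint:
    """Exact minimizer of the two-segment log-variance partition objective.

    For a split after breath k (segments x[1..k] and x[k+1..N], empirical
    population variances V0, V1) the default objective is

        (k − 1)·log V0 + (N − k + 1)·log V1,

    scanned exhaustively over min_size ≤ k ≤ N − min_size via cumulative
    sums; ties break toward the smallest k.  ``coefficients="length"``
    weights by the segment lengths (k, N − k) instead, which makes the
    estimator exactly covariant under time reversal.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    if n < 2 * min_size:
        raise ValueError(f"need at least {2 * min_size} observations, got {n}")
    if np.ptp(x) == 0.0:
        raise DegenerateVarianceError("all-constant signal: variance undefined in log")
    if coefficients not in ("as-printed", "length"):
        raise ValueError("coefficients must be 'as-printed' or 'length'")
    pre, post = _segment_variances(x)
    ks = np.arange(min_size, n - min_size + 1)
    v0 = pre[ks - 1]  # variance of x[:k]
    v1 = post[ks]  # variance of x[k:]
    if np.any(v0 < VARIANCE_FLOOR) or np.any(v1 < VARIANCE_FLOOR):
        warnings.warn(
            "near-constant candidate segment hit the variance floor", RuntimeWarning
        )
    if coefficients == "as-printed":
        w0, w1 = ks - 1, n - ks + 1
    else:
        w0, w1 = ks, n - ks
    obj = w0 * np.log(np.maximum(v0, VARIANCE_FLOOR)) + w1 * np.log(
        np.maximum(v1, VARIANCE_FLOOR)
    )
    best = int(np.argmin(obj))  # first occurrence: ties toward smallest k
    return ChangePoint(k=int(ks[best]), objective=float(obj[best]))


class DegenerateVarianceError(ValueError):
    """Variance undefined (constant signal) in the log-variance objective."""


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def detect_vt1(
    record: CpetRecord,
    min_size: int = 10,
    *,
    vslope_series: str = "vco2",
    coefficients: str = "as-printed",
) -> Vt1Estimate:
    """Estimate VT1 by averaging the V-slope and ExCO2 change points.

    The V-slope detection series defaults to the breath-indexed V̇CO2 signal
    (the response variable of the V-slope plot); ``vslope_series="slope"``
    uses the per-breath slope increments ΔV̇CO2/ΔV̇O2 instead.  The averaged
    index is rounded half-up; ``time_at_k`` is the time of breath k_mean.
    """
    vo2 = record.channel("vo2")
    vco2 = record.channel("vco2")
    if vslope_series == "vco2":
        vs = vco2
        vs_offset = 0
    elif vslope_series == "slope":
        dvo2 = np.diff(vo2)
        if np.any(dvo2 == 0):
            raise ValueError("slope series undefined: repeated V̇O2 values")
        vs = np.diff(vco2) / dvo2
        vs_offset = 1  # increment t covers breaths t..t+1
    else:
        raise ValueError("vslope_series must be 'vco2' or 'slope'")
    try:
        cp_vs = logvar_changepoint(vs, min_size, coefficients=coefficients)
    except ValueError as exc:
        raise ValueError(f"V-slope change point failed: {exc}") from exc
    try:
        cp_ex = logvar_changepoint(
            exco2_series(vo2, vco2), min_size, coefficients=coefficients
        )
    except ValueError as exc:
        raise ValueError(f"ExCO2 change point failed: {exc}") from exc
    k_vslope = cp_vs.k + vs_offset
    k_exco2 = cp_ex.k
    k_mean = _round_half_up((k_vslope + k_exco2) / 2.0)
    time_at_k = float(record.breaths["time"].iloc[k_mean - 1])
    return Vt1Estimate(
        k_vslope=k_vslope,
        k_exco2=k_exco2,
        k_mean=k_mean,
        time_at_k=time_at_k,
        objective_vslope=cp_vs.objective,
        objective_exco2=cp_ex.objective,
        options={
            "min_size": min_size,
            "vslope_series": vslope_series,
            "coefficients": coefficients,
        },
    )
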