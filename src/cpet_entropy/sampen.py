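"""Sample entropy (SampEn) for short, weakly stationary signals.

SampEn(x, m, r) = −log(A/B) where B is the probability that two distinct
length-m templates of x lie within Chebyshev distance r, and A the same for
length m+1.  Both template sets are drawn from the common start range
i ∈ {1..N−m}, so the pair universe is identical, A ≤ B is guaranteed, and
both are genuine probabilities with Z = (N−m)(N−m−1) ordered pairs.  The
degenerate cases are explicit statuses: B = 0 → undefined; B > 0, A = 0 →
infinite.  The radius r lives on the standardized-signal scale (r = 0.2
means 0.2 SD).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .io_cpet import METRICS, CpetRecord
from .preprocess import Signal, difference, make_stationary_segments, standardize
from .vt1 import Vt1Estimate

__all__ = [
    "SampEnParams",
    "SampEnResult",
    "match_probabilities",
    "sample_entropy",
    "default_params",
    "cohort_entropy_table",
    "whole_signal_entropy_table",
    "R_GRID",
]

logger = logging.getLogger(__name__)

#: Candidate similarity radii (in SD units) scanned by :func:`default_params`.
R_GRID = (0.10, 0.15, 0.20, 0.25, 0.30, 0.35)


@dataclasses.dataclass(frozen=True)
class SampEnParams:
    m: int  # embedding dimension
    r: float  # similarity radius, standardized scale

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if not self.r > 0:
            raise ValueError("similarity radius r must be positive")


@dataclasses.dataclass(frozen=True)
class SampEnResult:
    """Match probabilities and the entropy value with its definedness status."""

    params: SampEnParams
    b: float
    a: float
    value: float  # NaN when undefined, +inf when infinite
    n_templates: int
    status: str  # "defined" | "infinite" | "undefined"

    def value_repr(self) -> str:
        """Serialization-safe value (statuses as sentinels, never floats)."""
        if self.status == "defined":
            return repr(self.value)
        return self.status


def _values(x: Signal | Sequence[float] | np.ndarray) -> np.ndarray:
    if isinstance(x, Signal):
        return x.values
    return np.asarray(x, dtype=float)


def match_probabilities(
    x: Signal | np.ndarray, m: int, r: float
) -> tuple[float, float, dict[str, int]]:
    """Template match probabilities (b for length m, a for length m+1).

    Exact O(N²·m) computation over all ordered pairs of distinct templates
    under Chebyshev distance, with both template lengths drawn from the
    common start range (N−m templates each).
    """
    params = SampEnParams(m=m, r=r)
    v = _values(x)
    n = v.size
    if n < m + 2:
        raise ValueError(f"need N >= m + 2 = {m + 2} observations, got {n}")
    emb = sliding_window_view(v, m + 1)  # (N−m, m+1)
    t = emb.shape[0]
    diff = np.abs(emb[:, None, :] - emb[None, :, :])
    d_m = diff[:, :, :m].max(axis=-1) if m > 0 else np.zeros((t, t))
    d_m1 = np.maximum(d_m, diff[:, :, m])
    b_count = int((d_m <= params.r).sum()) - t  # remove self-pairs (distance 0)
    a_count = int((d_m1 <= params.r).sum()) - t
    z = t * (t - 1)
    counts = {"b": b_count, "a": a_count, "pairs": z, "n_templates": t}
    return b_count / z, a_count / z, counts


def sample_entropy(x: Signal | np.ndarray, params: SampEnParams) -> SampEnResult:
    """SampEn with explicit handling of the undefined/infinite cases."""
    b, a, counts = match_probabilities(x, params.m, params.r)
    if b == 0.0:
        status, value = "undefined", float("nan")
    elif a == 0.0:
        status, value = "infinite", float("inf")
    else:
        status, value = "defined", float(-np.log(a / b))
    return SampEnResult(
        params=params,
        b=b,
        a=a,
        value=value,
        n_templates=counts["n_templates"],
        status=status,
    )


def default_params(signals: Iterable[Signal | np.ndarray]) -> SampEnParams:
    """Short-signal parameter heuristic.

    m = 2 when every signal has at least 60 points, else 1 (below ~60
    observations the (m+1)-template pair pool thins out quickly); r is the
    smallest grid value for which every signal yields a defined SampEn, so
    the radius is as discriminative as the collection allows.  Signals are
    expected already standardized, so r is in SD units.
    """
    sigs = [_values(s) for s in signals]
    if not sigs:
        raise ValueError("default_params needs a nonempty signal collection")
    m = 2 if min(s.size for s in sigs) >= 60 else 1
    for r in R_GRID:
        params = SampEnParams(m=m, r=r)
        if all(sample_entropy(s, params).status == "defined" for s in sigs):
            return params
    warnings.warn(
        f"no grid radius gave defined SampEn for every signal; using r={R_GRID[-1]}",
        RuntimeWarning,
    )
    return SampEnParams(m=m, r=R_GRID[-1])


def _record_row(record: CpetRecord) -> dict:
    if record.sex is None or record.pubertal_status is None:
        raise ValueError(
            f"record {record.participant_id!r} lacks sex/pubertal metadata "
            "required for cohort analysis"
        )
    return {
        "participant_id": record.participant_id,
        "sex": record.sex.value,
        "pubertal": record.pubertal_status.value,
    }


def cohort_entropy_table(
    records: Sequence[CpetRecord],
    vt1: Mapping[str, Vt1Estimate | int],
    params: Mapping[str, SampEnParams] | SampEnParams,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, list[dict]]:
    """One SampEn observation per (participant, metric, VT1 side).

    Each record is sliced at its VT1 estimate, differenced, standardized and
    entropy-scored per metric.  Undefined/infinite entropies and degenerate
    (zero-variance) segments are excluded from the table and returned as a
    logged exclusion list.
    """
    rows: list[dict] = []
    exclusions: list[dict] = []
    for record in records:
        base = _record_row(record)
        est = vt1[record.participant_id]
        k = est.k_mean if isinstance(est, Vt1Estimate) else int(est)
        segments = make_stationary_segments(record, k, alpha=alpha)
        for (metric, side), seg in segments.items():
            p = params[metric] if isinstance(params, Mapping) else params
            row = dict(base, metric=metric, side=side)
            if seg.degenerate or seg.signal is None:
                exclusions.append(dict(row, reason="degenerate segment"))
                continue
            result = sample_entropy(seg.signal, p)
            if result.status != "defined":
                exclusions.append(dict(row, reason=f"sampen {result.status}"))
                continue
            rows.append(dict(row, sampen=result.value))
    if exclusions:
        logger.info("cohort_entropy_table excluded %d segment(s)", len(exclusions))
    columns = ["participant_id", "metric", "sex", "pubertal", "side", "sampen"]
    return pd.DataFrame(rows, columns=columns), exclusions


def whole_signal_entropy_table(
    records: Sequence[CpetRecord],
    params: Mapping[str, SampEnParams] | SampEnParams,
) -> tuple[pd.DataFrame, list[dict]]:
    """SampEn of each whole (un-split) differenced, standardized channel.

    Used for the pubertal contrast, where the model carries no VT1 plate.
    """
    rows: list[dict] = []
    exclusions: list[dict] = []
    for record in records:
        base = _record_row(record)
        for metric in METRICS:
            p = params[metric] if isinstance(params, Mapping) else params
            row = dict(base, metric=metric)
            sig = Signal(record.channel(metric), metric=metric, segment="whole")
            try:
                prep = standardize(difference(sig))
            except Exception:
                exclusions.append(dict(row, reason="degenerate segment"))
                continue
            result = sample_entropy(prep, p)
            if result.status != "defined":
                exclusions.append(dict(row, reason=f"sampen {result.status}"))
                continue
            rows.append(dict(row, sampen=result.value))
    columns = ["participant_id", "metric", "sex", "pubertal", "sampen"]
    return pd.DataFrame(rows, columns=columns), exclusions
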