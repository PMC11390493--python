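"""Reading, validation, and peak-effort QC of breath-by-breath CPET records.

A record is one participant's ramp test: one row per breath with gas-exchange
channels (V̇O2, V̇CO2, V̇E), respiratory rate, tidal volume, and the
instantaneous heart rate sampled at that breath, plus participant metadata
(sex, pubertal status, optional body mass).  Input is UTF-8 delimited text
with a header row; metadata travels in a JSON sidecar next to the table.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Sex",
    "PubertalStatus",
    "CpetRecord",
    "QcReport",
    "PeakVo2",
    "Dialect",
    "CpetSchemaError",
    "CpetValidationError",
    "read_breath_table",
    "write_breath_table",
    "qc_peak_effort",
    "peak_vo2",
    "BREATH_COLUMNS",
    "METRICS",
    "MIN_BREATHS",
]

#: Canonical breath-table columns (``time`` in seconds from test start).
BREATH_COLUMNS = ("time", "vo2", "vco2", "ve", "rr", "vt", "hr")

#: The CPET metric set M analysed for entropy.
METRICS = ("vo2", "vco2", "ve", "rr", "vt", "hr")

#: Minimum breaths for a record to be usable downstream.
MIN_BREATHS = 40


class CpetSchemaError(ValueError):
    """A required column is missing or cannot be parsed."""


class CpetValidationError(ValueError):
    """A parsed table violates a record invariant."""


class Sex(str, enum.Enum):
    male = "male"
    female = "female"


class PubertalStatus(str, enum.Enum):
    early = "early"
    late = "late"


@dataclasses.dataclass(frozen=True)
class Dialect:
    """How to read a delimited breath table.

    ``columns`` maps canonical names (``vo2`` ...) to the names used in the
    file; unmapped canonical names are looked up verbatim.
    """

    delimiter: str = ","
    columns: Mapping[str, str] = dataclasses.field(default_factory=dict)

    def source_name(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)


@dataclasses.dataclass(frozen=True)
class CpetRecord:
    """One participant's breath-by-breath CPET series plus metadata.

    ``breaths`` has the canonical columns of :data:`BREATH_COLUMNS`:
    time (s, strictly increasing), vo2 and vco2 (mL/min), ve (L/min),
    rr (breaths/min), vt (L), hr (beats/min).  All channels must be finite
    and positive, and the record must hold at least :data:`MIN_BREATHS`
    breaths.  ``sex``/``pubertal_status`` may be ``None`` for anonymous
    single-record use; cohort-level analysis requires them.
    """

    participant_id: str
    breaths: pd.DataFrame
    sex: Sex | None = None
    pubertal_status: PubertalStatus | None = None
    body_mass: float | None = None  # kg

    def __post_init__(self) -> None:
        _validate_breaths(self.breaths)
        if self.body_mass is not None and not self.body_mass > 0:
            raise CpetValidationError("body_mass must be positive (kg)")

    @property
    def n_breaths(self) -> int:
        return len(self.breaths)

    @property
    def duration(self) -> float:
        """Seconds spanned from the first to the last breath."""
        t = self.breaths["time"].to_numpy()
        return float(t[-1] - t[0])

    def channel(self, metric: str) -> np.ndarray:
        if metric not in METRICS:
            raise KeyError(f"unknown CPET metric {metric!r}")
        return self.breaths[metric].to_numpy(dtype=float)


def _validate_breaths(df: pd.DataFrame) -> None:
    missing = [c for c in BREATH_COLUMNS if c not in df.columns]
    if missing:
        raise CpetSchemaError(f"missing breath-table column(s): {', '.join(missing)}")
    if len(df) < MIN_BREATHS:
        raise CpetValidationError(
            f"record has {len(df)} breaths; at least {MIN_BREATHS} required"
        )
    arr = df[list(BREATH_COLUMNS)].to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        row = int(np.argwhere(~np.isfinite(arr))[0, 0])
        raise CpetValidationError(f"non-finite value at row {row}")
    t = df["time"].to_numpy(dtype=float)
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        raise CpetValidationError(
            f"time must be strictly increasing; violation at row {int(bad[0]) + 1}"
        )
    for col in ("vo2", "vco2", "ve", "rr", "vt", "hr"):
        vals = df[col].to_numpy(dtype=float)
        if np.any(vals <= 0):
            row = int(np.flatnonzero(vals <= 0)[0])
            raise CpetValidationError(f"{col} must be positive; violation at row {row}")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def read_breath_table(
    path: str | Path,
    dialect: Dialect | None = None,
    *,
    participant_id: str | None = None,
) -> CpetRecord:
    """Read a delimited breath table (plus JSON metadata sidecar if present).

    Rows are sorted by time before validation.  Raises
    :class:`CpetSchemaError` if a required column cannot be mapped and
    :class:`CpetValidationError` if an invariant fails (the message names
    the first offending row).
    """
    path = Path(path)
    dialect = dialect or Dialect()
    raw = pd.read_csv(path, sep=dialect.delimiter)
    missing = [c for c in BREATH_COLUMNS if dialect.source_name(c) not in raw.columns]
    if missing:
        raise CpetSchemaError(
            "missing breath-table column(s): "
            + ", ".join(dialect.source_name(c) for c in missing)
        )
    df = pd.DataFrame(
        {c: pd.to_numeric(raw[dialect.source_name(c)], errors="raise") for c in BREATH_COLUMNS}
    )
    # Duplicate timestamps are a validation error, not silently reordered.
    if df["time"].duplicated().any():
        row = int(np.flatnonzero(df["time"].duplicated().to_numpy())[0])
        raise CpetValidationError(f"duplicated timestamp at row {row}")
    df = df.sort_values("time", kind="mergesort").reset_index(drop=True)

    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    pid = participant_id or meta.get("participant_id") or path.stem
    sex = Sex(meta["sex"]) if "sex" in meta else None
    pub = PubertalStatus(meta["pubertal_status"]) if "pubertal_status" in meta else None
    mass = meta.get("body_mass")
    return CpetRecord(
        participant_id=pid,
        breaths=df,
        sex=sex,
        pubertal_status=pub,
        body_mass=float(mass) if mass is not None else None,
    )


def write_breath_table(record: CpetRecord, path: str | Path) -> None:
    """Write the breath table as CSV plus a JSON metadata sidecar."""
    path = Path(path)
    record.breaths.to_csv(path, index=False)
    meta: dict = {"participant_id": record.participant_id}
    if record.sex is not None:
        meta["sex"] = record.sex.value
    if record.pubertal_status is not None:
        meta["pubertal_status"] = record.pubertal_status.value
    if record.body_mass is not None:
        meta["body_mass"] = record.body_mass
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


@dataclasses.dataclass(frozen=True)
class QcReport:
    """Peak-effort validity: RER > 1.0 (windowed) and/or max HR > 185."""

    rer_peak: float
    hr_peak: float
    valid: bool
    reasons: tuple[str, ...]


@dataclasses.dataclass(frozen=True)
class PeakVo2:
    """Peak V̇O2: highest 20-s rolling average within the final minute."""

    ml_min: float
    ml_min_kg: float | None
    window_start: float  # seconds


def _window_means(
    time: np.ndarray, values: np.ndarray, window_s: float, tail_s: float
) -> tuple[np.ndarray, np.ndarray]:
    """Means of ``values`` over all distinct windows [t, t+window_s) fully
    contained in the final ``tail_s`` seconds.

    Breath timestamps are irregular, so the window content only changes when
    the start time crosses a breath time or a (breath time − window) offset;
    scanning those candidate starts covers every distinct window.
    """
    end = time[-1]
    lo, hi = end - tail_s, end - window_s
    starts = np.unique(np.concatenate([time, time - window_s]))
    starts = starts[(starts >= lo - 1e-9) & (starts <= hi + 1e-9)]
    starts = np.union1d(starts, [lo])
    means, kept = [], []
    for t0 in starts:
        sel = (time >= t0) & (time < t0 + window_s)
        if sel.any():
            means.append(values[sel].mean())
            kept.append(t0)
    return np.asarray(kept), np.asarray(means)


def qc_peak_effort(
    record: CpetRecord,
    *,
    rer_threshold: float = 1.0,
    hr_threshold: float = 185.0,
    window_s: float = 20.0,
    tail_s: float = 60.0,
) -> QcReport:
    """Decide peak-effort validity.

    RER is smoothed the same way as peak V̇O2: over each 20-s window in the
    final minute, RER = mean(V̇CO2)/mean(V̇O2), and ``rer_peak`` is the
    maximum.  HR is the instantaneous maximum over the whole test.  The test
    is valid if either criterion is met (RER alone is sufficient).
    """
    if record.duration < window_s:
        raise CpetValidationError(
            f"record spans {record.duration:.1f}s; QC needs at least {window_s:.0f}s"
        )
    time = record.breaths["time"].to_numpy(dtype=float)
    tail = min(tail_s, record.duration)
    _, vo2_means = _window_means(time, record.channel("vo2"), window_s, tail)
    _, vco2_means = _window_means(time, record.channel("vco2"), window_s, tail)
    rer_peak = float(np.max(vco2_means / vo2_means))
    hr_peak = float(record.channel("hr").max())
    reasons = []
    if rer_peak <= rer_threshold:
        reasons.append(f"rer_peak {rer_peak:.3f} <= {rer_threshold}")
    if hr_peak <= hr_threshold:
        reasons.append(f"hr_peak {hr_peak:.1f} <= {hr_threshold}")
    valid = rer_peak > rer_threshold or hr_peak > hr_threshold
    return QcReport(rer_peak=rer_peak, hr_peak=hr_peak, valid=valid, reasons=tuple(reasons))


def peak_vo2(
    record: CpetRecord, *, window_s: float = 20.0, tail_s: float = 60.0
) -> PeakVo2:
    """Highest ``window_s``-second rolling-average V̇O2 in the final ``tail_s``.

    A window is the breath set with time in [t, t+window), averaged
    arithmetically; all windows fully contained in the final minute are
    scanned exhaustively.
    """
    if record.duration < tail_s:
        raise CpetValidationError(
            f"record spans {record.duration:.1f}s; peak V̇O2 needs {tail_s:.0f}s"
        )
    time = record.breaths["time"].to_numpy(dtype=float)
    starts, means = _window_means(time, record.channel("vo2"), window_s, tail_s)
    best = int(np.argmax(means))
    ml_min = float(means[best])
    per_kg = ml_min / record.body_mass if record.body_mass else None
    return PeakVo2(ml_min=ml_min, ml_min_kg=per_kg, window_start=float(starts[best]))
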