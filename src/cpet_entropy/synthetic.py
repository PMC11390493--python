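"""Synthetic ramp-CPET cohorts with known ground truth.

Real pediatric CPET records are not publicly deposited, so every pipeline
stage is exercised on generated cohorts that emulate the relevant structure
of a ramp test: trending, nonstationary channels of ~100-250 breaths, a
regime change at a known VT1 breath index, entropy-controllable noise, and
a heart-rate trajectory that plateaus beyond VT1.

The entropy dial is a MIX-style process — a unit-variance blend of a
sinusoid and i.i.d. uniform noise with mixing probability p — whose sample
entropy increases monotonically with p.  Gas channels switch their noise p
downward at VT1 (entropy decrease), respiratory rate switches upward, and
the HR noise p drops with the plateau strength, reproducing the directional
pattern the analysis is designed to detect.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_cpet import CpetRecord, PubertalStatus, Sex, write_breath_table

__all__ = [
    "CellSpec",
    "SyntheticTruth",
    "mix_process",
    "simulate_record",
    "generate_cohort",
    "simulate_entropy_observations",
    "write_cohort",
]


@dataclasses.dataclass(frozen=True)
class CellSpec:
    """Generator settings for one (sex, pubertal) cohort cell.

    ``mix_p_before``/``mix_p_after`` set the gas-channel noise regularity on
    each side of VT1 (lower p after VT1 ⇒ entropy decrease);
    ``hr_plateau_strength`` ∈ [0, 1] scales both the flattening of the HR
    trajectory beyond VT1 and the drop in HR noise entropy.
    """

    sex: Sex
    pubertal: PubertalStatus
    n_participants: int = 10
    mix_p_before: float = 0.70
    mix_p_after: float = 0.45
    hr_plateau_strength: float = 0.80
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        for name in ("mix_p_before", "mix_p_after", "hr_plateau_strength"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclasses.dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth serialized alongside every generated record."""

    participant_id: str
    vt1_index_true: int
    cell_entropy_order: dict
    generator_params: dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        return cls(**json.loads(text))


def mix_process(
    n: int,
    p: float,
    period: int = 12,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """MIX(p): x_t = (1−z_t)·sin(2πt/period) + z_t·e_t.

    z_t ~ Bernoulli(p), e_t ~ Uniform(−√3, √3) (unit variance); higher p
    gives a less regular, higher-entropy signal.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("mixing probability p must lie in [0, 1]")
    if n < 2 * period:
        raise ValueError(f"need n >= 2*period = {2 * period}")
    rng = np.random.default_rng(rng)
    t = np.arange(n)
    z = rng.random(n) < p
    e = rng.uniform(-np.sqrt(3.0), np.sqrt(3.0), size=n)
    return np.where(z, e, np.sin(2.0 * np.pi * t / period))


def _switching_mix(
    n: int, k_star: int, p_before: float, p_after: float, rng: np.random.Generator,
    period: int = 12,
) -> np.ndarray:
    """MIX noise whose regularity parameter switches at the VT1 index."""
    t = np.arange(n)
    p = np.where(t < k_star, p_before, p_after)
    z = rng.random(n) < p
    e = rng.uniform(-np.sqrt(3.0), np.sqrt(3.0), size=n)
    return np.where(z, e, np.sin(2.0 * np.pi * t / period))


def simulate_record(
    spec: CellSpec,
    participant_index: int,
    n_breaths: int = 200,
    vt1_frac: float = 0.55,
    *,
    noise_scale: float = 1.0,
) -> tuple[CpetRecord, SyntheticTruth]:
    """One ramp-protocol record with a built-in VT1 at round(vt1_frac·N).

    Work intensity rises throughout: V̇O2 ramps ~0.5→2.4 L/min, V̇CO2
    follows with a gain that steepens beyond VT1 (so the V-slope/ExCO2
    detection series carry a change point), breaths quicken (RR 22→48,
    shrinking the inter-breath interval), and HR saturates with a post-VT1
    plateau.  ``noise_scale=0`` gives the noiseless limiting record.
    """
    if n_breaths < 80:
        raise ValueError("n_breaths must be >= 80")
    if not 0.0 < vt1_frac < 1.0:
        raise ValueError("vt1_frac must lie in (0, 1)")
    cell_code = {"male": 0, "female": 1}[spec.sex.value] * 2 + {
        "early": 0,
        "late": 1,
    }[spec.pubertal.value]
    ss = np.random.SeedSequence(
        entropy=spec.seed, spawn_key=(cell_code, participant_index)
    )
    rng = np.random.default_rng(ss)
    n = n_breaths
    k_star = int(round(vt1_frac * n))
    idx = np.arange(n, dtype=float)
    frac = idx / (n - 1)
    # Breaths 1..k_star (idx < k_star) are pre-VT1; the clean-trajectory kink
    # places breath k_star + 1 first on the new slope.
    post = np.maximum(idx - (k_star - 1), 0.0)

    def noise(p_before, p_after, amp):
        return amp * noise_scale * _switching_mix(
            n, k_star, p_before, p_after, rng
        )

    p0, p1 = spec.mix_p_before, spec.mix_p_after
    h = spec.hr_plateau_strength

    # Breath timing: interval shrinks as RR climbs 22 -> 48 breaths/min.
    rr_traj = 22.0 + 26.0 * frac
    dt = 60.0 / rr_traj * (1.0 + noise_scale * rng.uniform(-0.05, 0.05, size=n))
    time = np.cumsum(dt)

    # Gas exchange: linear V̇O2 ramp; V̇CO2 rides at RER ≈ 1 up to VT1 and
    # steepens beyond it, and breath-to-breath scatter widens markedly
    # post-VT1 (erratic breathing near maximal effort) — the joint slope and
    # variance change the detection series carry.
    vo2_clean = 500.0 + 1900.0 * frac
    amp_vo2 = np.where(idx < k_star, 30.0, 150.0)
    vo2 = vo2_clean + amp_vo2 * noise_scale * _switching_mix(n, k_star, p0, p1, rng)
    gain_pre, gain_post = 1.0, 1.22
    vco2_clean = gain_pre * vo2_clean + (gain_post - gain_pre) * 1900.0 / (n - 1) * post
    amp_vco2 = np.where(idx < k_star, 30.0, 200.0)
    vco2 = vco2_clean + amp_vco2 * noise_scale * _switching_mix(n, k_star, p0, p1, rng)

    # Ventilation tracks V̇CO2 (ventilatory equivalent ~27), extra rise post-VT1.
    ve_clean = 0.027 * vco2_clean + 0.010 * (gain_post - gain_pre) * 1900.0 / (n - 1) * post
    ve = ve_clean + noise(p0, p1, 1.6)

    # Tidal volume saturates mid-test.
    vt_clean = 0.55 + 0.95 * (1.0 - np.exp(-2.5 * frac))
    vt = vt_clean + noise(p0, p1, 0.045)

    # Respiratory rate: noise regularity INCREASES in entropy after VT1.
    rr = rr_traj + noise(0.45, 0.85, 1.4)

    # Heart rate: rising limb, post-VT1 slope shrunk by the plateau
    # strength; noise regularity tightens further with the plateau.  HR noise
    # is far more regular than the gas channels throughout (autonomic control
    # versus breath-to-breath respiratory scatter), so HR entropy sits below
    # every gas-exchange entropy on both sides of VT1.
    hr_slope = 85.0 / k_star
    hr_clean = 98.0 + hr_slope * np.minimum(idx, k_star - 1.0) + (1.0 - h) * hr_slope * post
    hr_clean = np.minimum(hr_clean, 196.0)
    p_hr_before = 0.30
    p_hr_after = p_hr_before * (1.0 - h) + 0.03
    hr = hr_clean + 1.6 * noise_scale * _switching_mix(n, k_star, p_hr_before, p_hr_after, rng)

    breaths = pd.DataFrame(
        {"time": time, "vo2": vo2, "vco2": vco2, "ve": ve, "rr": rr, "vt": vt, "hr": hr}
    )
    pid = f"{spec.sex.value[0]}{spec.pubertal.value[0]}{participant_index:03d}"
    record = CpetRecord(
        participant_id=pid,
        breaths=breaths,
        sex=spec.sex,
        pubertal_status=spec.pubertal,
        body_mass=float(np.round(30.0 + 35.0 * rng.random(), 1)),
    )
    truth = SyntheticTruth(
        participant_id=pid,
        vt1_index_true=k_star,
        cell_entropy_order={
            "vo2": "decrease",
            "vco2": "decrease",
            "ve": "decrease",
            "vt": "decrease",
            "rr": "increase",
            "hr": "decrease",
        },
        generator_params=dict(
            dataclasses.asdict(spec),
            sex=spec.sex.value,
            pubertal=spec.pubertal.value,
            participant_index=participant_index,
            n_breaths=n_breaths,
            vt1_frac=vt1_frac,
            noise_scale=noise_scale,
        ),
    )
    return record, truth


def generate_cohort(
    participants_per_cell: int = 10,
    seed: int = 0,
    n_breaths: int = 200,
    **cell_overrides,
) -> tuple[list[CpetRecord], list[SyntheticTruth]]:
    """A full 2×2 (sex × pubertal) cohort with the default effect directions.

    Group-level entropy offsets are mild: females carry slightly higher
    noise p than males, late-pubertal slightly lower than early — matching
    the directions of the sex and maturational contrasts the analysis
    targets.
    """
    records, truths = [], []
    for sex in (Sex.male, Sex.female):
        for pub in (PubertalStatus.early, PubertalStatus.late):
            p_shift = (0.04 if sex is Sex.female else 0.0) - (
                0.04 if pub is PubertalStatus.late else 0.0
            )
            spec = CellSpec(
                sex=sex,
                pubertal=pub,
                n_participants=participants_per_cell,
                mix_p_before=min(1.0, 0.70 + p_shift),
                mix_p_after=min(1.0, 0.45 + p_shift),
                seed=seed,
                **cell_overrides,
            )
            for i in range(participants_per_cell):
                rec, truth = simulate_record(spec, i, n_breaths=n_breaths)
                records.append(rec)
                truths.append(truth)
    return records, truths


def write_cohort(
    records: Sequence[CpetRecord], truths: Sequence[SyntheticTruth], out_dir: str | Path
) -> None:
    """Write per-participant CSV + JSON sidecar + truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rec, truth in zip(records, truths):
        write_breath_table(rec, out / f"{rec.participant_id}.csv")
        (out / f"{rec.participant_id}.truth.json").write_text(truth.to_json())


def simulate_entropy_observations(
    cells: Sequence[tuple[dict, float, float]],
    nu: float,
    n_per_cell: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Direct Student-t draws of SampEn observations, one row per draw.

    ``cells`` is a sequence of (factor-level dict, μ, σ); output follows the
    cohort entropy-table schema (factor columns + ``sampen``).
    """
    if nu <= 0:
        raise ValueError("nu must be positive")
    if n_per_cell < 1:
        raise ValueError("n_per_cell must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for i, (levels, mu, sigma) in enumerate(cells):
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        draws = mu + sigma * rng.standard_t(nu, size=n_per_cell)
        for j, v in enumerate(draws):
            rows.append(dict(levels, participant_id=f"c{i}p{j:03d}", sampen=float(v)))
    return pd.DataFrame(rows)
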