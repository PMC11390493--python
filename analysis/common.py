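"""Shared configuration for the analysis drivers.

One seeded default cohort (10 participants per sex × pubertal cell, 200
breaths each) flows through every numbered script; intermediate tables live
under results/, bulky per-participant breath files under scratch/.
"""

from __future__ import annotations

from pathlib import Path

COHORT_SEED = 42
PARTICIPANTS_PER_CELL = 10
FIT_SEED = 3

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "cohort"


def load_cohort():
    from cpet_entropy.synthetic import generate_cohort

    return generate_cohort(participants_per_cell=PARTICIPANTS_PER_CELL, seed=COHORT_SEED)


def load_vt1(records):
    from cpet_entropy.vt1 import detect_vt1

    return {r.participant_id: detect_vt1(r) for r in records}
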