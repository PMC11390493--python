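"""Generate the synthetic study cohort and summarize peak effort.

Writes per-participant breath tables (CSV + JSON sidecar + truth JSON) to
scratch/cohort/ and a per-participant QC/peak-V̇O2 summary to
results/cohort_summary.csv.
"""

import pandas as pd

from common import RESULTS, SCRATCH, load_cohort

from cpet_entropy.io_cpet import peak_vo2, qc_peak_effort
from cpet_entropy.synthetic import write_cohort


def main() -> None:
    records, truths = load_cohort()
    write_cohort(records, truths, SCRATCH)

    rows = []
    for rec in records:
        qc = qc_peak_effort(rec)
        pk = peak_vo2(rec)
        rows.append({
            "participant_id": rec.participant_id,
            "sex": rec.sex.value,
            "pubertal": rec.pubertal_status.value,
            "n_breaths": rec.n_breaths,
            "duration_s": round(rec.duration, 1),
            "rer_peak": round(qc.rer_peak, 3),
            "hr_peak": round(qc.hr_peak, 1),
            "qc_valid": qc.valid,
            "peak_vo2_ml_min": round(pk.ml_min, 0),
            "peak_vo2_ml_min_kg": round(pk.ml_min_kg, 1),
        })
    summary = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    summary.to_csv(RESULTS / "cohort_summary.csv", index=False)

    print(f"wrote {len(records)} records to {SCRATCH}")
    print(f"QC valid: {summary.qc_valid.sum()}/{len(summary)}")
    print(
        "peak V̇O2 (mL/min): "
        f"median {summary.peak_vo2_ml_min.median():.0f}, "
        f"range {summary.peak_vo2_ml_min.min():.0f}-{summary.peak_vo2_ml_min.max():.0f}"
    )


if __name__ == "__main__":
    main()
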