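#!/usr/bin/env python
"""Simulate the demonstration cohort and summarise its shape.

Writes the raw records and per-visit lesion masks under scratch/ (large,
regenerable) and a small cohort summary under results/.
"""

import json

from common import DEMO_SEED, RESULTS, SCRATCH, demo_cohort

from perilesion.lesions import write_mask


def main() -> None:
    cohort = demo_cohort()
    records = cohort.records

    out = SCRATCH / "cohort"
    out.mkdir(parents=True, exist_ok=True)
    records.to_csv(out / "records.csv", index=False)
    cohort.truth.to_csv(out / "truth.csv", index=False)
    mask_dir = out / "masks"
    mask_dir.mkdir(exist_ok=True)
    for (pid, month), mask in cohort.masks.items():
        write_mask(mask, mask_dir / f"{pid}_m{month:g}.png")

    visits = records.groupby("participant_id")["visit_month"].nunique()
    summary = {
        "seed": DEMO_SEED,
        "participants": int(records["participant_id"].nunique()),
        "tests_total": int(len(cohort.masks)),
        "mean_visits_per_participant": round(float(visits.mean()), 2),
        "records": int(len(records)),
        "scotoma_fraction": round(float(records["scotoma"].mean()), 3),
        "mean_sensitivity_db": round(float(records["sensitivity_db"].mean()), 2),
    }
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "cohort_summary.json").write_text(json.dumps(summary, indent=1))

    print(f"simulated {summary['participants']} participants, "
          f"{summary['tests_total']} microperimetry tests, {summary['records']} records")
    print(f"mean visits per participant: {summary['mean_visits_per_participant']}")
    print(f"absolute-scotoma fraction: {summary['scotoma_fraction']:.1%}; "
          f"mean sensitivity {summary['mean_sensitivity_db']} dB")
    print(f"records + masks -> {out}")


if __name__ == "__main__":
    main()
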