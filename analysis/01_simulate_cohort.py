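"""Simulate the study cohort: one synthetic actigraphy/PSG night per participant.

Writes the raw cohort (per-participant CSVs, sync table, subgroup labels,
manifest) under scratch/cohort and a small truth summary under results/.
"""

import pandas as pd

from actisleep.synthetic import simulate_cohort, write_cohort
from study_config import RESULTS, SCRATCH, STUDY_CONFIG


def main() -> None:
    cohort = simulate_cohort(STUDY_CONFIG)
    out = write_cohort(cohort, SCRATCH / "cohort", overwrite=True)

    truth = pd.DataFrame(
        [
            {
                "participant_id": pid,
                "subgroup": cohort.subgroup[pid] or "none",
                "tst": t.tst,
                "waso": t.waso,
                "se": t.se,
                "onset": t.onset_index,
            }
            for pid, t in cohort.truth.items()
        ]
    )
    RESULTS.mkdir(exist_ok=True)
    truth.to_csv(RESULTS / "cohort_truth_summary.csv", index=False)

    print(f"cohort of {STUDY_CONFIG.n_participants} nights written to {out}")
    print(f"truth TST  mean {truth.tst.mean():.1f} min (SD {truth.tst.std():.1f})")
    print(f"truth WASO mean {truth.waso.mean():.1f} min (SD {truth.waso.std():.1f})")
    print(f"truth SE   mean {truth.se.mean():.1f} %")
    print("subgroups:", truth.subgroup.value_counts().to_dict())


if __name__ == "__main__":
    main()
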