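"""Repeat the agreement analyses within each sleep-problem subgroup.

Participants labelled apnea/insomnia/RLS/CPAP are re-analysed separately
(pooled accuracy, kappa, MCC and AUC per algorithm), mirroring the
exploratory subgroup analysis of the full study.  Inference and outlier
screening are skipped at subgroup size.
"""

import pandas as pd

from actisleep.pipeline import run_validation
from actisleep.synthetic import simulate_cohort, subset_cohort
from study_config import RESULTS, STUDY_CONFIG


def main() -> None:
    cohort = simulate_cohort(STUDY_CONFIG)
    groups: dict[str, list[str]] = {}
    for pid, label in cohort.subgroup.items():
        if label:
            groups.setdefault(label, []).append(pid)

    rows = []
    for label, ids in sorted(groups.items()):
        if len(ids) < 3:
            print(f"subgroup {label}: only {len(ids)} participants, skipped")
            continue
        rep = run_validation(cohort=subset_cohort(cohort, ids), outlier_analysis=False)
        pooled = rep.pooled_summary.query("metric in ['accuracy', 'kappa', 'mcc']")
        for _, r in pooled.iterrows():
            rows.append(
                {"subgroup": label, "n": len(ids), "variant": r["variant"],
                 "rescored": r["rescored"], "metric": r["metric"], "mean": r["mean"]}
            )
        for _, r in rep.roc.iterrows():
            rows.append(
                {"subgroup": label, "n": len(ids), "variant": r["algorithm"],
                 "rescored": False, "metric": "auc", "mean": r["auc"]}
            )
        acc = pooled.query("metric == 'accuracy' and not rescored")["mean"]
        print(
            f"subgroup {label} (n={len(ids)}): NRS accuracy "
            f"{acc.min():.3f}-{acc.max():.3f}, AUC {rep.roc.auc.min():.3f}-{rep.roc.auc.max():.3f}"
        )

    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(RESULTS / "subgroup_summary.csv", index=False)


if __name__ == "__main__":
    main()
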