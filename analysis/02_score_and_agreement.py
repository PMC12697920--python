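"""Score the cohort with all seven algorithm variants and compare epoch-by-epoch.

Runs the full validation pipeline (scoring, minute collapse, Webster
rescoring, confusion metrics, kappa/MCC, pooled ROC/AUC) and writes the
agreement tables under results/.
"""

from actisleep.pipeline import run_validation
from study_config import RESULTS, SCRATCH, STUDY_CONFIG


def main() -> None:
    rep = run_validation(config=STUDY_CONFIG)
    RESULTS.mkdir(exist_ok=True)
    (SCRATCH / "tables").mkdir(parents=True, exist_ok=True)
    # bulky per-participant table to scratch; pooled summaries to results
    rep.epoch_results.to_csv(SCRATCH / "tables" / "epoch_results.csv", index=False)
    rep.pooled_summary.to_csv(RESULTS / "pooled_summary.csv", index=False)
    rep.roc.to_csv(RESULTS / "roc_auc.csv", index=False)

    acc = (
        rep.pooled_summary.query("metric == 'accuracy'")
        .pivot(index="variant", columns="rescored", values="mean")
        .rename(columns={False: "NRS", True: "RS"})
    )
    print("pooled epoch-weighted accuracy (NRS vs RS):")
    print(acc.round(3).to_string())
    kappa = rep.pooled_summary.query("metric == 'kappa' and not rescored")
    print("\nCohen kappa (NRS):")
    print(kappa.set_index("variant")["mean"].round(3).to_string())
    print("\npooled AUC per algorithm:")
    print(rep.roc.set_index("algorithm")["auc"].round(3).to_string())
    print(
        "\nPSG 30-s pair distribution: "
        + ", ".join(f"{k} {100 * v:.2f}%" for k, v in rep.pair_distribution.items())
    )


if __name__ == "__main__":
    main()
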