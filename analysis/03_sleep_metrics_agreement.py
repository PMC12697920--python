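"""Bland-Altman agreement of actigraphy-derived TST/SE/WASO with PSG.

Writes the night-metric and Bland-Altman tables under results/ and the
per-metric Bland-Altman panels (non-rescored variants) under
scratch/figures.
"""

import matplotlib.pyplot as plt

from actisleep.comparison_stats import bland_altman
from actisleep.pipeline import run_validation
from actisleep.plotting import bland_altman_plot
from study_config import RESULTS, SCRATCH, STUDY_CONFIG


def main() -> None:
    rep = run_validation(config=STUDY_CONFIG)
    RESULTS.mkdir(exist_ok=True)
    (SCRATCH / "tables").mkdir(parents=True, exist_ok=True)
    rep.night_metrics.to_csv(SCRATCH / "tables" / "night_metrics.csv", index=False)
    rep.bland_altman.to_csv(RESULTS / "bland_altman.csv", index=False)

    fig_dir = SCRATCH / "figures"
    fig_dir.mkdir(parents=True, exist_ok=True)
    psg = rep.night_metrics.query("method == 'psg'").set_index("participant_id")
    variants = sorted(rep.bland_altman["variant"].unique())
    for metric in ("tst", "se", "waso"):
        fig, axes = plt.subplots(2, 4, figsize=(16, 7))
        for ax, vname in zip(axes.ravel(), variants):
            sel = rep.night_metrics.query(
                "method == @vname and not rescored"
            ).set_index("participant_id")
            a = sel[metric].to_numpy()
            b = psg.loc[sel.index, metric].to_numpy()
            bland_altman_plot(a, b, bland_altman(a, b, metric=metric), ax=ax, title=vname)
        for ax in axes.ravel()[len(variants):]:
            ax.set_axis_off()
        fig.suptitle(f"Bland-Altman, {metric.upper()}, non-rescored")
        fig.tight_layout()
        fig.savefig(fig_dir / f"bland_altman_{metric}.png", dpi=100)
        plt.close(fig)

    nrs = rep.bland_altman.query("not rescored")
    for metric in ("tst", "se", "waso"):
        tab = nrs.query("metric == @metric").set_index("variant")
        best = tab["mean_difference"].abs().idxmin()
        row = tab.loc[best]
        print(
            f"{metric.upper():4s}: best agreement {best} "
            f"(MD {row.mean_difference:+.2f}, LoA [{row.loa_low:.2f}, {row.loa_high:.2f}])"
        )
    print(f"figures under {fig_dir}")


if __name__ == "__main__":
    main()
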