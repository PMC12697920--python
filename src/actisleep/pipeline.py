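"""End-to-end validation study over a cohort of paired nights.

For every participant-night: synchronize and crop to in-bed, score the
30-s counts with all algorithm variants, collapse raw scores to minutes
(summing) and PSG to minutes (wake-wins), classify, optionally apply
Webster rescoring, then derive epoch-by-epoch agreement and night-level
sleep metrics.  Across participants: epoch-weighted pooled summaries,
pooled ROC/AUC per algorithm, Bland-Altman agreement for TST/SE/WASO,
repeated-measures ANOVA with Greenhouse-Geisser correction plus
Bonferroni post hocs per metric, the raw-count outlier sensitivity
analysis and the PSG pair-distribution audit.

Everything is deterministic in the cohort (itself deterministic in its
config seed), so identical config + seed reproduce identical outputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement as agr
from . import comparison_stats as cstats
from .epoch_io import EpochSeries, synchronize
from .epoch_transform import collapse_psg_to_minutes, collapse_scores_to_minutes, pair_distribution
from .rescoring import webster_rescore
from .scoring import (
    AlgorithmSpec,
    ScoreSeries,
    classify,
    load_registry,
    score_series,
    sleep_orientation,
    variant_specs,
)
from .sleep_metrics import compute_night_metrics
from .synthetic import Cohort, NightConfig, simulate_cohort

SLEEP_METRIC_NAMES = ("tst", "se", "waso")


@dataclass
class ValidationReport:
    """Tables produced by one full validation run."""

    epoch_results: pd.DataFrame       # participant x variant x rescored agreement
    pooled_summary: pd.DataFrame      # epoch-weighted mean/SD per metric
    roc: pd.DataFrame                 # pooled AUC per algorithm
    night_metrics: pd.DataFrame       # long-format TST/SE/WASO per method
    bland_altman: pd.DataFrame        # metric x variant x rescored vs PSG
    anova: pd.DataFrame               # RM-ANOVA per metric x rescored
    posthoc: pd.DataFrame             # Bonferroni pairwise results
    pair_distribution: dict           # pooled PSG 30-s pair audit
    outliers: cstats.OutlierReport | None
    rescoring_changes: pd.DataFrame   # per-rule minute change counts
    subgroup: dict[str, str] = field(default_factory=dict)


def run_validation(
    cohort: Cohort | None = None,
    config: NightConfig | None = None,
    rescore: bool = True,
    registry: dict[str, AlgorithmSpec] | None = None,
    outlier_analysis: bool = True,
) -> ValidationReport:
    """Run the complete study on ``cohort`` (simulated from ``config`` if absent)."""
    if cohort is None:
        if config is None:
            raise ValueError("provide a cohort or a NightConfig")
        cohort = simulate_cohort(config)
    registry = registry or load_registry()
    variants = variant_specs(registry)
    flags = [False, True] if rescore else [False]

    epoch_rows: list[dict] = []
    night_rows: list[dict] = []
    rule_rows: list[dict] = []
    roc_scores: dict[str, list[np.ndarray]] = {}
    roc_truth: list[np.ndarray] = []
    raw30_counts: dict[str, np.ndarray] = {}
    pair_counts = np.zeros(3)  # both_sleep, both_wake, mixed

    for pid in cohort.participant_ids:
        act, psg = synchronize(
            cohort.activity[pid], cohort.psg[pid], cohort.sync[pid], crop_to_in_bed=True
        )
        raw30_counts[pid] = act.values
        psg_min = collapse_psg_to_minutes(psg)
        dist = pair_distribution(psg)
        n_pairs = len(psg) // 2
        pair_counts += np.array([dist["both_sleep"], dist["both_wake"], dist["mixed"]]) * n_pairs
        roc_truth.append(psg_min.values)

        night_rows.append(
            {"participant_id": pid, "method": "psg", "rescored": False,
             **_metrics_dict(compute_night_metrics(psg_min, "psg", cohort.sync[pid]))}
        )

        minute_scores: dict[str, np.ndarray] = {}
        for base_name, spec in registry.items():
            raw30 = score_series(act, spec)
            raw60 = collapse_scores_to_minutes(raw30)
            minute_scores[base_name] = raw60.values
            roc_scores.setdefault(base_name, []).append(raw60.values)

        for vname, vspec in variants.items():
            base = vspec.name
            raw60 = ScoreSeries(pid, base, 60, minute_scores[base])
            # the original per-epoch threshold is applied unchanged to the
            # minute sum (sum-raw-then-threshold), matching the source
            # procedure even though summing doubles the score scale
            nrs = classify(raw60, vspec)
            series_by_flag = {False: nrs}
            if rescore:
                rs, changes = webster_rescore(nrs)
                series_by_flag[True] = rs
                rule_rows.append({"participant_id": pid, "variant": vname, **changes})
            for flag in flags:
                pred = series_by_flag[flag]
                res = agr.agreement_metrics(agr.confusion(pred, psg_min))
                epoch_rows.append(
                    {"participant_id": pid, "variant": vname, "rescored": flag,
                     "n_minutes": res.counts.total,
                     "tp": res.counts.tp, "fp": res.counts.fp,
                     "tn": res.counts.tn, "fn": res.counts.fn,
                     **{m: getattr(res, m) for m in agr.METRIC_NAMES}}
                )
                night_rows.append(
                    {"participant_id": pid, "method": vname, "rescored": flag,
                     **_metrics_dict(compute_night_metrics(pred, vname, cohort.sync[pid]))}
                )

    epoch_results = pd.DataFrame(epoch_rows)
    night_metrics = pd.DataFrame(night_rows)
    pooled_summary = _pool(epoch_results)
    roc_table = _pooled_roc(registry, roc_scores, roc_truth)
    ba_table = _bland_altman_tables(night_metrics, variants, flags)
    anova_table, posthoc_table = _comparison_tables(epoch_results, flags)
    pair_total = pair_counts.sum()
    pair_dist = {
        "both_sleep": pair_counts[0] / pair_total,
        "both_wake": pair_counts[1] / pair_total,
        "mixed": pair_counts[2] / pair_total,
    }
    outliers = None
    if outlier_analysis and len(cohort.participant_ids) >= 10:
        outliers = cstats.outlier_sensitivity(
            raw30_counts, _outlier_metrics_fn(epoch_results)
        )
    return ValidationReport(
        epoch_results=epoch_results,
        pooled_summary=pooled_summary,
        roc=roc_table,
        night_metrics=night_metrics,
        bland_altman=ba_table,
        anova=anova_table,
        posthoc=posthoc_table,
        pair_distribution=pair_dist,
        outliers=outliers,
        rescoring_changes=pd.DataFrame(rule_rows),
        subgroup=dict(cohort.subgroup),
    )


def _metrics_dict(nm) -> dict:
    return {"onset": nm.onset_index, "offset": nm.offset_index, "tst": nm.tst,
            "waso": nm.waso, "in_bed": nm.in_bed, "se": nm.se, "no_sleep": nm.no_sleep}


def _pool(epoch_results: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (variant, flag), grp in epoch_results.groupby(["variant", "rescored"]):
        w = grp["n_minutes"].to_numpy(float)
        for m in agr.METRIC_NAMES:
            mean, sd = agr.weighted_summary(grp[m].to_numpy(float), w)
            rows.append({"variant": variant, "rescored": flag, "metric": m,
                         "mean": mean, "sd": sd})
    return pd.DataFrame(rows)


def _pooled_roc(registry, roc_scores, roc_truth) -> pd.DataFrame:
    from .epoch_io import BINARY

    truth = np.concatenate(roc_truth)
    truth_series = EpochSeries("pooled", "1970-01-01", 60, BINARY, truth)
    rows = []
    for base_name, spec in registry.items():
        scores = ScoreSeries("pooled", base_name, 60, np.concatenate(roc_scores[base_name]))
        res = agr.roc_auc(scores, truth_series, sleep_orientation(spec))
        rows.append({"algorithm": base_name, "auc": res.auc, "n_minutes": len(truth),
                     "undefined": res.undefined})
    return pd.DataFrame(rows)


def _bland_altman_tables(night_metrics, variants, flags) -> pd.DataFrame:
    psg = night_metrics[night_metrics["method"] == "psg"].set_index("participant_id")
    rows = []
    for vname in variants:
        for flag in flags:
            sel = night_metrics[
                (night_metrics["method"] == vname) & (night_metrics["rescored"] == flag)
            ].set_index("participant_id")
            common = sel.index.intersection(psg.index)
            if len(common) < 3:
                continue
            for metric in SLEEP_METRIC_NAMES:
                res = cstats.bland_altman(
                    sel.loc[common, metric].to_numpy(float),
                    psg.loc[common, metric].to_numpy(float),
                    metric=metric,
                    method_pair=(vname, "psg"),
                )
                rows.append({"metric": metric, "variant": vname, "rescored": flag,
                             "n": res.n, "mean_difference": res.mean_difference,
                             "sd_difference": res.sd_difference,
                             "loa_low": res.loa_low, "loa_high": res.loa_high,
                             "prop_bias_slope": res.prop_bias_slope,
                             "prop_bias_r2": res.prop_bias_r2,
                             "prop_bias_p": res.prop_bias_p})
    return pd.DataFrame(rows)


def _metric_matrix(epoch_results: pd.DataFrame, metric: str, flag: bool) -> pd.DataFrame:
    sub = epoch_results[epoch_results["rescored"] == flag]
    mat = sub.pivot(index="participant_id", columns="variant", values=metric)
    return mat.dropna(axis=0)  # complete cases only


def _comparison_tables(epoch_results, flags):
    anova_rows, posthoc_rows = [], []
    for flag in flags:
        for metric in agr.METRIC_NAMES:
            mat = _metric_matrix(epoch_results, metric, flag)
            if mat.shape[0] < 3 or mat.shape[1] < 2:
                continue
            try:
                res = cstats.rm_anova(mat, metric=metric)
            except cstats.DegenerateDataError:
                continue
            anova_rows.append({"metric": metric, "rescored": flag, **asdict(res)})
            for ph in cstats.posthoc_pairs(mat):
                posthoc_rows.append({"metric": metric, "rescored": flag, **asdict(ph)})
    return pd.DataFrame(anova_rows), pd.DataFrame(posthoc_rows)


def _outlier_metrics_fn(epoch_results: pd.DataFrame):
    """Pooled NRS metrics per variant, recomputable on any participant subset."""
    nrs = epoch_results[~epoch_results["rescored"]]

    def fn(included_ids):
        sub = nrs[nrs["participant_id"].isin(list(included_ids))]
        out = {}
        for variant, grp in sub.groupby("variant"):
            w = grp["n_minutes"].to_numpy(float)
            for m in ("accuracy", "sensitivity", "specificity", "kappa", "mcc"):
                mean, _ = agr.weighted_summary(grp[m].to_numpy(float), w)
                out[f"{m}_{variant}"] = mean
        return out

    return fn


def write_report(report: ValidationReport, out_dir) -> Path:
    """Write all report tables as CSV (plus the audits as JSON)."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.epoch_results.to_csv(out / "epoch_results.csv", index=False)
    report.pooled_summary.to_csv(out / "pooled_summary.csv", index=False)
    report.roc.to_csv(out / "roc_auc.csv", index=False)
    report.night_metrics.to_csv(out / "night_metrics.csv", index=False)
    report.bland_altman.to_csv(out / "bland_altman.csv", index=False)
    report.anova.to_csv(out / "rm_anova.csv", index=False)
    report.posthoc.to_csv(out / "posthoc.csv", index=False)
    if not report.rescoring_changes.empty:
        report.rescoring_changes.to_csv(out / "rescoring_changes.csv", index=False)
    (out / "pair_distribution.json").write_text(json.dumps(report.pair_distribution, indent=2))
    if report.outliers is not None:
        (out / "outlier_report.json").write_text(
            json.dumps(
                {"flagged": report.outliers.flagged,
                 "relative_change": report.outliers.relative_change,
                 "within_criterion": report.outliers.within_criterion},
                indent=2,
            )
        )
    return out
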