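# actisleep

Classical actigraphy sleep–wake scoring and its epoch-by-epoch validation
against polysomnography (PSG).

Wrist actigraphs summarize movement as per-epoch activity counts, and for
decades sleep research has inferred sleep/wake from those counts with a
handful of linear weighted-window algorithms. `actisleep` implements the
five canonical 30-second-epoch scorers — Cole–Kripke, UCSD, Kripke 2010,
Philips-Respironics (Actiwatch) and Sadeh — together with the full
validation workflow used to benchmark them against PSG ground truth:
Webster rescoring, 30 s→1 min epoch harmonization, night-level sleep
metrics (TST, SE, WASO), agreement statistics (confusion metrics, Cohen κ,
MCC, ROC/AUC), Bland–Altman method comparison, and repeated-measures
inference across algorithms. A synthetic paired-night generator with known
ground truth makes every stage testable without access-controlled clinical
data.

## The scoring model

Four of the scorers compute, for each 30 s epoch *i* with activity counts
*A*, a scaled weighted sum over a window around the scored epoch,

    D_i = P · Σ_k  w_k · A_{i+k},

with window positions outside the recording contributing zero, and score
the epoch sleep when *D* < 1 (Cole–Kripke, UCSD, Kripke 2010) or when the
total activity *A* ≤ *T* for a wake threshold *T* ∈ {20, 40, 80}
(Philips). Sadeh instead computes a probability-of-sleep discriminant

    PS = 7.601 − 0.065·AVG − 1.08·NATS − 0.056·SD − 0.703·LG

from features of an 11-epoch window (mean activity, number of epochs with
counts in [50, 100), SD of the first six window epochs, log of the scored
epoch's counts, counts clipped at 300), scoring sleep when PS ≥ 0. All
weights, scales and thresholds live in a JSON registry
(`src/actisleep/data/algorithms.json`), not in code.

Validation follows the standard protocol: raw 30 s scores are summed to
1-minute epochs and thresholded; PSG labels are collapsed minute-wise with
the wake-wins rule (a minute is sleep only if both halves are sleep); the
five Webster rules optionally rescore short sleep runs adjacent to long
wake runs; PSG is the actual class and sleep = 1 the positive class.

## Worked example

```python
from actisleep import NightConfig, run_validation

report = run_validation(config=NightConfig(n_participants=20, seed=7))

acc = report.pooled_summary.query("metric == 'accuracy' and not rescored")
print(acc.set_index("variant")["mean"].round(3))
```

```
variant
cole_kripke    0.915
kripke2010     0.779
philips_20     0.733
philips_40     0.826
philips_80     0.909
sadeh          0.956
ucsd           0.979
```

These are epoch-weighted pooled accuracies of each non-rescored algorithm
variant against PSG over 20 synthetic nights: every minute of every night
is compared, and per-participant accuracies are pooled weighted by the
number of compared minutes. The same report carries the other confusion
metrics, κ and MCC, pooled ROC/AUC per algorithm
(`report.roc`), and Bland–Altman agreement for the night metrics, e.g.
for total sleep time:

```python
tst = report.bland_altman.query("metric == 'tst' and not rescored")
print(tst.set_index("variant")[["mean_difference", "loa_low", "loa_high"]].round(1))
```

```
             mean_difference  loa_low  loa_high
variant
cole_kripke            -40.7    -59.3     -22.1
ucsd                    -2.6     -9.8       4.7
kripke2010            -106.0   -139.7     -72.3
philips_20            -128.0   -158.7     -97.2
philips_40             -83.4   -104.8     -61.9
philips_80             -43.6    -58.4     -28.9
sadeh                  -18.4    -31.9      -4.9
```

A negative mean difference means the algorithm underestimates TST
(in minutes) relative to PSG on these synthetic nights; the limits of
agreement are MD ± 1.96·SD of the per-night differences.

## Analysis scripts

The numbered scripts under `analysis/` run the study end to end on the
shared synthetic cohort (`analysis/study_config.py`): `01` simulates and
writes the cohort, `02` scores it and tabulates epoch-by-epoch agreement
and ROC/AUC, `03` compares TST/SE/WASO with Bland–Altman plots, `04` runs
the repeated-measures ANOVA (Greenhouse–Geisser corrected), Bonferroni
post hocs with Hedges *g*, and the raw-count outlier sensitivity screen,
and `05` repeats the agreement analyses within sleep-problem subgroups.
Pooled tables land in `results/`; bulky per-night tables and figures in
`scratch/`.

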