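# Methods

## Scope and data model

`actisleep` validates classical actigraphy sleep–wake scoring against
polysomnography (PSG) on paired single-night recordings. Both modalities
are carried as `EpochSeries`: fixed-length epochs (30 s or 60 s), indexed
from 0, each covering the half-open interval `[start + i·Δ, start +
(i+1)·Δ)`. Activity counts are finite and nonnegative; sleep–wake labels
are binary with wake = 0 and sleep = 1. Alignment is driven by an explicit
per-participant `SyncSpec` (signed PSG start offset in 30 s epochs, plus
the in-bed interval); no automatic cross-correlation alignment is
attempted, mirroring how clinical datasets ship a synchronization table.
The in-bed interval is likewise an explicit input — lights-out/lights-on
conventions vary enough between datasets that deriving it from the data
would be false precision.

## Scoring algorithms

Cole–Kripke, UCSD, Kripke 2010 and Philips are weighted-window operators
`score[i] = scale · Σ_k w_k · counts[i + offset_k]`, evaluated on 30 s
counts with out-of-range window positions contributing zero activity
(missing-as-zero, applied uniformly to all algorithms). Sadeh is a
discriminant over an 11-epoch window; counts are clipped at 300 before
feature extraction. Decision rules: sleep iff D < 1 (Cole–Kripke, UCSD,
Kripke 2010), sleep iff A ≤ T with T ∈ {20, 40, 80} (Philips; each
threshold is a separate variant), sleep iff PS ≥ 0 (Sadeh; the historical
PS > −4 rule is available by overriding the registry threshold).

All constants live in a versioned JSON registry. Three entries are
editorial readings of typographically ambiguous sources and are marked as
such in the registry notes: the Cole–Kripke centre weight (121), the
Kripke 2010 trailing weight (0.0100), and the final Philips window
position (+4, completing the symmetric ±4 window). Each is data, not
code, so a corrected value is a one-line change.

Numerical choices for Sadeh: `LG = ln(counts + 1)` so that zero activity
is well-defined; `SD` is the sample standard deviation (ddof = 1) of the
six window positions at offsets −5..0. `NATS` counts window positions
with activity ≥ 50 and < 100.

## Epoch harmonization

Raw 30 s scores are collapsed to minutes by summing the two constituent
scores, and the original per-epoch threshold is applied unchanged to the
minute sum. This is deliberate fidelity to the established processing
chain even though summing doubles the score scale and therefore biases
minute decisions toward wake; a classify-then-pair alternative
(wake-wins applied to binarized 30 s decisions) is available for
sensitivity analyses (`epoch_transform.classify_then_pair`). PSG minutes
use the wake-wins rule: sleep iff both halves sleep. Pairs are formed in
phase with epoch 0 — (0,1), (2,3), … — and an unpaired trailing epoch is
dropped and logged. The `pair_distribution` audit reports the
both-sleep/both-wake/mixed proportions that quantify how much the
collapse can distort.

## Webster rescoring

The five rules (4→1, 10→3, 15→4 trailing; ≤6 min bouts inside ≥10 min
wake flanks; ≤10 min bouts inside ≥20 min flanks) are applied
sequentially, each pass operating on the previous pass's output. Within
one pass, wake/sleep runs are computed once from that pass's input and
all conversions applied together, so a conversion cannot re-trigger the
same rule in its own pass; runs are maximal, "after at least N minutes of
wake" means a maximal run of ≥ N wake minutes immediately precedes the
sleep in question. Sleep bouts at the record boundary have no flank and
are never touched by the surround rules. Only sleep→wake changes occur,
so wake time is monotonically nondecreasing under rescoring — a property
the test suite checks exhaustively. Idempotence is not asserted; a debug
log notes when a second sweep would change nothing.

## Sleep metrics

With the series cropped to the in-bed interval: onset is the first sleep
minute (no N-consecutive-minutes criterion; one is available behind
`onset_rule` for sensitivity checks), offset the last; TST and WASO are
the sleep and wake minutes within [onset, offset], so TST + WASO = offset
− onset + 1; SE = 100 · TST / in-bed minutes, with the denominator taken
from the `SyncSpec`. A night with no scored sleep yields zeros with a
`no_sleep` flag rather than an exception.

## Agreement statistics

PSG is the actual class, actigraphy the predicted class, sleep = 1 the
positive class (so sensitivity measures sleep detection). κ uses chance
agreement from the marginals; MCC is the standard determinant form and
equals the Pearson correlation of the two binary vectors (tested to
1e-12). Degenerate denominators (e.g. MCC under a constant predictor)
yield NaN plus a reason code, never a silent 0. ROC sweeps every distinct
raw-score value via scikit-learn with sleep-oriented scores (the D/A-type
scorers are negated; Sadeh's PS used as-is); AUC is the trapezoidal
integral and equals the Mann–Whitney U statistic divided by n₊n₋ (tested
to 1e-10). Pooling across participants uses frequency weights
(compared-minutes per participant) for both mean and SD; undefined
per-participant values are dropped with their weights.

## Inference layer

The one-way within-subject ANOVA uses the textbook SS decomposition;
Greenhouse–Geisser ε comes from orthonormal (Helmert) contrasts of the
sample condition covariance, ε = tr(S̃)²/((k−1)·tr(S̃S̃)), with ε ≡ 1 for
k = 2 and for exactly compound-symmetric covariance. Mauchly's W uses the
chi-square approximation with the second-order correction term (as in
ezANOVA); the implementation is cross-checked against pingouin in the
test suite rather than delegating to it. Generalized eta squared is
SS_condition/(SS_condition + SS_subject + SS_error), the appropriate form
for a one-way within design. F is reported as 0 (p = 1) when the
condition SS is zero up to float noise against identical columns; fully
constant data raise a degenerate-variance error.

Post hoc contrasts are paired t tests (the base test is a configuration
point — the convention in this literature is not fixed), Bonferroni
corrected with family size m defaulting to the number of pairs. Hedges g
uses the averaged-condition-SD standardizer with correction J = 1 −
3/(4·(2n−2) − 1) — not the SD of difference scores, which would inflate
g for highly correlated conditions — and is labelled very
small/small/medium/large at the 0.2/0.5/0.8 cutpoints.

Bland–Altman agreement reports MD, SD (ddof = 1), LoA = MD ± 1.96·SD and
proportional bias as the OLS regression of differences on pair means
(slope, R², two-sided p). Under normal differences the LoA cover ≈95% of
pairs, verified by simulation in the acceptance suite.

The outlier screen interprets the two-tier rule as: tier 1, Tukey fences
(1.5·IQR) on the sample distribution of per-participant raw-count IQRs —
the only reading of the garbled source sentence consistent with "1.5
times" and quartiles; tier 2, |z| ≥ 2 of the participant's mean count
against the sample of participant means. Flags are the union; pooled
metrics are recomputed without flagged participants and relative changes
tabulated against the 5% criterion.

## Synthetic cohort generator

The generator emulates the *structure* of one-night PSG-synchronized
actigraphy: a minute-resolution truth hypnogram (gamma-distributed sleep
latency, mean 15 min, SD 8; alternating exponential sleep bouts at
`wake_bout_rate` 2/h and gamma wake bouts of mean 3 min), expanded to
30 s epochs; PSG labels are the truth itself; counts are sampled
conditional on state (wake: gamma, mean 150, shape 1.5; sleep: zero with
probability 0.85, else a small gamma burst, mean 20). Defaults describe a
moderately fragmented older-adult night of 480 in-bed minutes.
Phenotypes scale these knobs (fragmented: 3× bout rate, 1.5× bout length;
long-latency: 3× latency), and subgroup labels (apnea 7.2%, insomnia
5.8%, RLS 4.6%, CPAP 4.3% prevalence) map to phenotypes
(fragmented/long-latency) for the exploratory subgroup analyses.

Because truth is generated at minute resolution and replicated to 30 s,
the wake-wins collapse reconstructs it exactly and the stored truth
metrics are exactly recoverable — a deliberate invariant the tests rely
on. The corresponding limitation: PSG 30 s pairs are never mixed, so the
pair-distribution audit reports 0% mixed on synthetic cohorts, unlike
real recordings where stage transitions occur mid-minute. The generator
also does not emulate sleep stages, circadian structure, device-specific
count modes, or artefacts (off-wrist, nonwear); passing tests therefore
demonstrate correctness of the pipeline's computations and orderings, not
field performance of the algorithms on clinical data.

The noiseless preset (`noiseless_config`: wake counts ≡ 200, sleep counts
≡ 0, latency only, no wake bouts) isolates the scorers' deterministic
behaviour from count noise and bout-boundary blur. Consolidated nights
are the right substrate for exact recovery checks: window scorers
necessarily misclassify a few epochs after every wake→sleep transition
(about 4 min for the 13-epoch Kripke 2010 window), so recovery bounds of
a few minutes per night are only meaningful when each night has a single
onset transition. Boundary blur on fragmented nights is characterized
separately by the main simulation study.

## Problem sizes and determinism

The analysis scripts use 100 participants × 480 in-bed minutes; the
acceptance script simulates 100 nights plus a 50-night noiseless cohort;
the null-calibration check uses 2,000 replicates of a 100 × 7 design,
mirroring the seven algorithm variants at a cohort-like sample size where
the GG ε estimate's small-sample conservatism is negligible. All
randomness flows through `numpy.random.default_rng` seeded per
participant from the config seed, so identical config + seed reproduce
byte-identical cohorts, tables and JSON output.

## Known limitations

- The three registry constants flagged above are editorial readings of
  ambiguous sources; results for Cole–Kripke, Kripke 2010 and Philips
  depend on them.
- Webster rule interpretation ("maximal runs, no within-pass cascading")
  follows the common reading; rescoring software lineages differ.
- The minute-collapse threshold convention (unchanged threshold on the
  doubled-scale sum) biases decisions toward wake; use
  `classify_then_pair` to quantify the effect on a given dataset.
- Synthetic counts are not fitted to any device; absolute agreement
  numbers on synthetic cohorts are not comparable to published clinical
  benchmarks.
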