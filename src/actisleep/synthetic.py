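"""Synthetic paired actigraphy/PSG night generator with known ground truth.

Emulates the structure of one-night polysomnography-synchronized wrist
actigraphy recordings: a minute-resolution truth hypnogram (sleep-onset
latency, alternating sleep bouts and brief awakenings) is expanded to
paired 30-second epochs; PSG labels are the truth itself, and activity
counts are sampled conditional on state (near-zero during sleep, elevated
gamma-distributed counts during wake).  Sleep-problem phenotypes alter
fragmentation (more/longer wake bouts) or latency.

The truth hypnogram is generated at 1-minute resolution and replicated to
30-s epochs, so the wake-wins minute collapse reconstructs it exactly and
the generator's stored night metrics are exactly recoverable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .epoch_io import (
    ACTIVITY,
    BINARY,
    EpochSeries,
    SyncSpec,
    write_epoch_series,
    write_sync_table,
)
from .sleep_metrics import NightMetrics, compute_night_metrics

PHENOTYPES = ("typical", "fragmented", "long_latency")

# one-night study: every participant gets the same nominal lights-out clock time
_BASE_START = pd.Timestamp("2015-06-01 23:00:00")

# sleep-problem prevalences used for subgroup labels (fractions of cohort)
SUBGROUP_PREVALENCE = {"apnea": 0.072, "insomnia": 0.058, "rls": 0.046, "cpap": 0.043}
_SUBGROUP_PHENOTYPE = {
    "apnea": "fragmented",
    "rls": "fragmented",
    "cpap": "fragmented",
    "insomnia": "long_latency",
}


@dataclass(frozen=True)
class NightConfig:
    """Generator configuration; defaults describe a typical older-adult night.

    Rates and durations are in minutes unless noted.  ``counts_wake_shape``
    of ``None`` makes wake counts deterministic at ``counts_wake_mean``
    (the noiseless setting); ``counts_sleep_zero_prob`` of 1 makes sleep
    counts identically zero.
    """

    n_participants: int = 50
    in_bed_minutes: int = 480
    latency_mean: float = 15.0
    latency_dispersion: float = 8.0
    wake_bout_rate: float = 2.0  # bouts per hour of sleep period
    wake_bout_mean_minutes: float = 3.0
    counts_wake_mean: float = 150.0
    counts_wake_shape: float | None = 1.5
    counts_sleep_zero_prob: float = 0.85
    counts_sleep_burst_mean: float = 20.0
    counts_sleep_burst_shape: float = 1.0
    phenotype: str = "typical"
    subgroups: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.phenotype!r}")
        if not 0.0 <= self.counts_sleep_zero_prob <= 1.0:
            raise ValueError("counts_sleep_zero_prob must be in [0, 1]")
        for name in ("latency_mean", "wake_bout_rate", "wake_bout_mean_minutes",
                     "counts_wake_mean", "counts_sleep_burst_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def resolved(self) -> "NightConfig":
        """Apply the phenotype's fragmentation/latency adjustments."""
        if self.phenotype == "fragmented":
            return replace(
                self,
                wake_bout_rate=self.wake_bout_rate * 3.0,
                wake_bout_mean_minutes=self.wake_bout_mean_minutes * 1.5,
            )
        if self.phenotype == "long_latency":
            return replace(self, latency_mean=self.latency_mean * 3.0)
        return self


def noiseless_config(**overrides) -> NightConfig:
    """Consolidated noiseless preset: wake counts fixed at 200, sleep counts 0,
    latency only (no wake bouts), isolating scorer behaviour from count noise
    and bout-boundary blur."""
    base = dict(
        wake_bout_rate=0.0,
        counts_wake_mean=200.0,
        counts_wake_shape=None,
        counts_sleep_zero_prob=1.0,
        latency_mean=15.0,
        latency_dispersion=4.0,
    )
    base.update(overrides)
    return NightConfig(**base)


def _sample_gamma(rng: np.random.Generator, mean: float, shape: float, size=None):
    return rng.gamma(shape, mean / shape, size=size)


def _truth_hypnogram(cfg: NightConfig, rng: np.random.Generator) -> np.ndarray:
    """Minute-resolution truth: wake latency, then alternating sleep/wake bouts."""
    n = cfg.in_bed_minutes
    if cfg.latency_dispersion > 0 and cfg.latency_mean > 0:
        shape = (cfg.latency_mean / cfg.latency_dispersion) ** 2
        lat = _sample_gamma(rng, cfg.latency_mean, shape)
    else:
        lat = cfg.latency_mean
    latency = int(round(lat))
    if latency > n - 1:
        latency = n - 1  # cap: at least one sleep minute per night

    x = np.zeros(n)
    pos = latency
    sleep_bout_mean = 60.0 / cfg.wake_bout_rate if cfg.wake_bout_rate > 0 else float(n)
    state = 1
    while pos < n:
        if state == 1:
            if cfg.wake_bout_rate > 0:
                length = max(1, int(round(rng.exponential(sleep_bout_mean))))
            else:
                length = n - pos
            x[pos : pos + length] = 1
        else:
            length = max(1, int(round(_sample_gamma(rng, cfg.wake_bout_mean_minutes, 1.5))))
        pos += length
        state = 1 - state
    return x


def _sample_counts(cfg: NightConfig, labels30: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = labels30.size
    counts = np.zeros(n)
    wake = labels30 == 0
    if cfg.counts_wake_shape is None:
        counts[wake] = cfg.counts_wake_mean
    else:
        counts[wake] = _sample_gamma(
            rng, cfg.counts_wake_mean, cfg.counts_wake_shape, size=int(wake.sum())
        )
    sleep = ~wake
    n_sleep = int(sleep.sum())
    if n_sleep and cfg.counts_sleep_zero_prob < 1.0:
        burst = rng.random(n_sleep) >= cfg.counts_sleep_zero_prob
        vals = np.zeros(n_sleep)
        if burst.any():
            vals[burst] = _sample_gamma(
                rng, cfg.counts_sleep_burst_mean, cfg.counts_sleep_burst_shape,
                size=int(burst.sum()),
            )
        counts[sleep] = vals
    return counts


def simulate_night(
    cfg: NightConfig, participant_index: int
) -> tuple[EpochSeries, EpochSeries, SyncSpec, NightMetrics]:
    """Simulate one paired night; deterministic in (cfg, participant_index).

    Returns 30-s activity counts, 30-s PSG labels, the sync record, and
    the generator-truth night metrics (computed from the truth hypnogram
    with the same metric definitions the pipeline uses).
    """
    eff = cfg.resolved()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, participant_index]))
    pid = f"p{participant_index:04d}"
    start = _BASE_START

    truth_min = _truth_hypnogram(eff, rng)
    truth_series = EpochSeries(pid, start, 60, BINARY, truth_min)
    truth_metrics = compute_night_metrics(truth_series, method="truth")

    labels30 = np.repeat(truth_min, 2)
    counts30 = _sample_counts(eff, labels30, rng)
    act = EpochSeries(pid, start, 30, ACTIVITY, counts30)
    psg = EpochSeries(pid, start, 30, BINARY, labels30)
    sync = SyncSpec(
        participant_id=pid,
        psg_offset_epochs=0,
        in_bed_start=start,
        in_bed_end=start + pd.Timedelta(minutes=cfg.in_bed_minutes),
    )
    return act, psg, sync, truth_metrics


@dataclass
class Cohort:
    """In-memory cohort bundle: one simulated night per participant."""

    config: NightConfig
    activity: dict[str, EpochSeries]
    psg: dict[str, EpochSeries]
    sync: dict[str, SyncSpec]
    truth: dict[str, NightMetrics]
    subgroup: dict[str, str]  # participant -> label ('' = none)

    @property
    def participant_ids(self) -> list[str]:
        return list(self.activity)


def _assign_subgroups(cfg: NightConfig, rng: np.random.Generator) -> list[str]:
    labels = []
    names = list(SUBGROUP_PREVALENCE)
    probs = np.array([SUBGROUP_PREVALENCE[n] for n in names])
    for _ in range(cfg.n_participants):
        u = rng.random()
        cum = np.cumsum(probs)
        idx = int(np.searchsorted(cum, u))
        labels.append(names[idx] if idx < len(names) else "")
    return labels


def simulate_cohort(cfg: NightConfig) -> Cohort:
    """Simulate the full cohort (one night per participant).

    With ``cfg.subgroups`` true, participants are assigned sleep-problem
    labels at the configured prevalences and their nights are generated
    under the matching phenotype (fragmented or long-latency).
    """
    label_rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 0xA55157])
    )
    labels = _assign_subgroups(cfg, label_rng) if cfg.subgroups else [""] * cfg.n_participants

    activity, psg, sync, truth, subgroup = {}, {}, {}, {}, {}
    for i in range(cfg.n_participants):
        night_cfg = cfg
        if labels[i]:
            night_cfg = replace(cfg, phenotype=_SUBGROUP_PHENOTYPE[labels[i]])
        a, p, s, t = simulate_night(night_cfg, i)
        activity[a.participant_id] = a
        psg[p.participant_id] = p
        sync[s.participant_id] = s
        truth[t.participant_id] = t
        subgroup[a.participant_id] = labels[i]
    return Cohort(cfg, activity, psg, sync, truth, subgroup)


def subset_cohort(cohort: Cohort, participant_ids) -> Cohort:
    """Restrict a cohort to the given participants (e.g. one subgroup)."""
    ids = [p for p in cohort.participant_ids if p in set(participant_ids)]
    if not ids:
        raise ValueError("subset contains no participants")
    return Cohort(
        config=cohort.config,
        activity={p: cohort.activity[p] for p in ids},
        psg={p: cohort.psg[p] for p in ids},
        sync={p: cohort.sync[p] for p in ids},
        truth={p: cohort.truth[p] for p in ids},
        subgroup={p: cohort.subgroup[p] for p in ids},
    )


def config_hash(cfg: NightConfig) -> str:
    return hashlib.sha256(json.dumps(asdict(cfg), sort_keys=True).encode()).hexdigest()[:16]


def write_cohort(cohort: Cohort, out_dir, overwrite: bool = False) -> Path:
    """Write per-participant CSVs, sync table, subgroup labels and manifest."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} exists and is non-empty; pass overwrite=True")
    out.mkdir(parents=True, exist_ok=True)
    for pid in cohort.participant_ids:
        write_epoch_series(cohort.activity[pid], out / f"{pid}_activity.csv")
        write_epoch_series(cohort.psg[pid], out / f"{pid}_psg.csv")
    write_sync_table(cohort.sync, out / "sync.csv")
    pd.DataFrame(
        {"participant_id": cohort.participant_ids,
         "subgroup": [cohort.subgroup[p] for p in cohort.participant_ids]}
    ).to_csv(out / "subgroups.csv", index=False)
    manifest = {
        "config": asdict(cohort.config),
        "config_hash": config_hash(cohort.config),
        "n_participants": cohort.config.n_participants,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
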