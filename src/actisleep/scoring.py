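"""Classical actigraphy sleep-wake scoring algorithms.

Five widely used 30-second-epoch scorers are implemented as data-driven
weighted-window operators: Cole-Kripke, UCSD, Kripke 2010 and
Philips-Respironics compute a scaled weighted sum of activity counts in a
window around the scored epoch; Sadeh computes a discriminant score
(probability of sleep, PS) from four window features.  Window positions
that fall outside the recording contribute zero activity.

All weights, scales, window offsets, thresholds and decision rules live in
the shipped JSON registry (``data/algorithms.json``) so corrected values
can be swapped without touching code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .epoch_io import ACTIVITY, BINARY, EpochSeries, ValidationError

SLEEP_IF_LT = "sleep_if_score_lt_threshold"
SLEEP_IF_LE = "sleep_if_score_le_threshold"
SLEEP_IF_GE = "sleep_if_score_ge_threshold"

_DECISIONS = (SLEEP_IF_LT, SLEEP_IF_LE, SLEEP_IF_GE)


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class AlgorithmSpec:
    """One scoring algorithm: window shape, weights, scale and decision rule.

    ``kind`` is ``weighted_window`` for the linear scorers or ``sadeh`` for
    the discriminant scorer (whose parameters sit in ``extra``).
    """

    name: str
    kind: str
    window_offsets: tuple[int, ...]
    weights: tuple[float, ...]
    scale: float
    threshold: float
    decision: str
    thresholds: tuple[float, ...] | None = None
    extra: Mapping | None = None

    def __post_init__(self) -> None:
        if self.kind == "weighted_window":
            if len(self.weights) != len(self.window_offsets):
                raise ConfigurationError("weights and window_offsets must align")
            if self.scale <= 0:
                raise ConfigurationError("scale must be positive")
        if self.decision not in _DECISIONS:
            raise ConfigurationError(f"unknown decision rule {self.decision!r}")

    def with_threshold(self, threshold: float) -> "AlgorithmSpec":
        return replace(self, threshold=float(threshold))


@dataclass
class ScoreSeries:
    """Per-epoch raw algorithm scores before thresholding."""

    participant_id: str
    algorithm: str
    epoch_length_s: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("raw scores must be finite")

    def __len__(self) -> int:
        return int(self.values.size)


def load_registry(path=None) -> dict[str, AlgorithmSpec]:
    """Load the algorithm registry (shipped defaults unless ``path`` given)."""
    if path is None:
        text = resources.files("actisleep.data").joinpath("algorithms.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = json.loads(text)
    registry: dict[str, AlgorithmSpec] = {}
    for name, entry in raw["algorithms"].items():
        kind = entry.get("kind", "weighted_window")
        if kind == "sadeh":
            spec = AlgorithmSpec(
                name=name,
                kind="sadeh",
                window_offsets=tuple(range(-5, 6)),
                weights=(),
                scale=1.0,
                threshold=float(entry["threshold"]),
                decision=entry["decision"],
                extra={
                    "coefficients": dict(entry["coefficients"]),
                    "clip": float(entry["clip"]),
                    "log_offset": float(entry["log_offset"]),
                },
            )
        else:
            spec = AlgorithmSpec(
                name=name,
                kind="weighted_window",
                window_offsets=tuple(int(o) for o in entry["offsets"]),
                weights=tuple(float(w) for w in entry["weights"]),
                scale=float(entry["scale"]),
                threshold=float(entry["threshold"]),
                decision=entry["decision"],
                thresholds=tuple(float(t) for t in entry.get("thresholds", [])) or None,
            )
        registry[name] = spec
    return registry


def variant_specs(registry: Mapping[str, AlgorithmSpec] | None = None) -> dict[str, AlgorithmSpec]:
    """Expand the registry into the scored variants.

    Threshold-parameterized algorithms (Philips) contribute one variant per
    threshold (``philips_20`` etc.); all others contribute themselves.
    """
    registry = registry or load_registry()
    out: dict[str, AlgorithmSpec] = {}
    for name, spec in registry.items():
        if spec.thresholds:
            for t in spec.thresholds:
                out[f"{name}_{t:g}"] = spec.with_threshold(t)
        else:
            out[name] = spec
    return out


def weighted_window_score(counts: EpochSeries, spec: AlgorithmSpec) -> ScoreSeries:
    """score[i] = scale * sum_k weights[k] * counts[i + offset[k]].

    Window positions outside the series contribute zero (missing-as-zero).
    """
    if counts.kind != ACTIVITY:
        raise ValidationError("weighted_window_score expects an activity-count series")
    if spec.kind != "weighted_window":
        raise ConfigurationError(f"{spec.name} is not a weighted-window algorithm")
    x = counts.values
    n = x.size
    s = np.zeros(n)
    for w, off in zip(spec.weights, spec.window_offsets):
        if abs(off) >= n:
            continue  # entire window position falls outside the series
        if off >= 0:
            s[: n - off] += w * x[off:]
        else:
            s[-off:] += w * x[: n + off]
    return ScoreSeries(counts.participant_id, spec.name, counts.epoch_length_s, spec.scale * s)


def sadeh_features(
    counts: EpochSeries, clip: float = 300.0, log_offset: float = 1.0
) -> dict[str, np.ndarray]:
    """Per-epoch Sadeh window features (AVG, NATS, SD, LG) after clipping.

    The window spans offsets -5..+5 around the scored epoch; positions
    outside the recording count as zero activity.  SD is the sample
    standard deviation (ddof=1) of the first six window positions
    (offsets -5..0); LG is ln(scored-epoch activity + ``log_offset``).
    """
    x = np.minimum(counts.values, clip)
    padded = np.pad(x, 5)
    win = np.lib.stride_tricks.sliding_window_view(padded, 11)  # row i = offsets -5..+5
    return {
        "avg": win.mean(axis=1),
        "nats": ((win >= 50) & (win < 100)).sum(axis=1),
        "sd": win[:, :6].std(axis=1, ddof=1),
        "lg": np.log(x + log_offset),
    }


def sadeh_score(counts: EpochSeries, spec: AlgorithmSpec | None = None) -> ScoreSeries:
    """Sadeh probability-of-sleep score on an 11-epoch window.

    Counts above the clip value (300) are clipped first.  Features over the
    window (5 before, the scored epoch, 5 after; missing epochs count as 0):

    * AVG  - mean activity over the 11 positions
    * NATS - number of positions with activity >= 50 and < 100
    * SD   - sample standard deviation of the first 6 positions (-5..0)
    * LG   - natural log of the scored epoch's activity + 1

    PS = 7.601 - 0.065*AVG - 1.08*NATS - 0.056*SD - 0.703*LG
    """
    if counts.kind != ACTIVITY:
        raise ValidationError("sadeh_score expects an activity-count series")
    if spec is None:
        spec = load_registry()["sadeh"]
    coef = spec.extra["coefficients"]
    feats = sadeh_features(counts, clip=spec.extra["clip"], log_offset=spec.extra["log_offset"])
    ps = (
        coef["intercept"]
        - coef["avg"] * feats["avg"]
        - coef["nats"] * feats["nats"]
        - coef["sd"] * feats["sd"]
        - coef["lg"] * feats["lg"]
    )
    return ScoreSeries(counts.participant_id, spec.name, counts.epoch_length_s, ps)


def score_series(counts: EpochSeries, spec: AlgorithmSpec) -> ScoreSeries:
    """Dispatch to the right scorer for ``spec``."""
    if spec.kind == "sadeh":
        return sadeh_score(counts, spec)
    return weighted_window_score(counts, spec)


def classify(
    score: ScoreSeries, spec: AlgorithmSpec, threshold: float | None = None
) -> EpochSeries:
    """Apply the algorithm's sleep-wake decision rule to raw scores.

    Returns a binary series (wake=0, sleep=1).  ``threshold`` overrides the
    spec threshold, e.g. to evaluate Philips wake-threshold variants.
    """
    t = spec.threshold if threshold is None else float(threshold)
    if spec.decision == SLEEP_IF_LT:
        sleep = score.values < t
    elif spec.decision == SLEEP_IF_LE:
        sleep = score.values <= t
    elif spec.decision == SLEEP_IF_GE:
        sleep = score.values >= t
    else:  # pragma: no cover - blocked by AlgorithmSpec validation
        raise ConfigurationError(f"decision rule unset for {spec.name}")
    return EpochSeries(
        participant_id=score.participant_id,
        start_time=pd.Timestamp("1970-01-01"),
        epoch_length_s=score.epoch_length_s,
        kind=BINARY,
        values=sleep.astype(float),
    )


def sleep_orientation(spec: AlgorithmSpec) -> str:
    """Whether low or high raw scores indicate sleep (for ROC sweeps)."""
    return "high_is_sleep" if spec.decision == SLEEP_IF_GE else "low_is_sleep"
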