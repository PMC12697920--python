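"""Harmonization of 30-second series to 1-minute epochs.

Actigraphy raw algorithm scores are collapsed by summing the two
constituent 30-s scores; the per-epoch decision threshold is then applied
unchanged to the minute sum (the default, ``sum_raw`` mode).  PSG binary
labels are collapsed with the wake-wins rule: a minute is sleep only if
both halves are sleep.  Pairs are formed in phase with epoch 0, i.e.
(0,1), (2,3), ...; a trailing unpaired epoch is dropped.
"""

from __future__ import annotations

import logging

import numpy as np

from .epoch_io import BINARY, EpochSeries, ValidationError
from .scoring import ScoreSeries

log = logging.getLogger(__name__)


def _paired(values: np.ndarray, label: str) -> np.ndarray:
    if values.size < 1:
        raise ValidationError("empty input")
    n_pairs = values.size // 2
    if values.size % 2:
        log.info("dropping unpaired trailing 30-s epoch (%s)", label)
    return values[: 2 * n_pairs].reshape(n_pairs, 2)


def collapse_scores_to_minutes(score: ScoreSeries) -> ScoreSeries:
    """Sum adjacent 30-s raw scores into 1-minute scores."""
    if score.epoch_length_s != 30:
        raise ValidationError("expected a 30-s score series")
    pairs = _paired(score.values, f"scores {score.participant_id}/{score.algorithm}")
    return ScoreSeries(score.participant_id, score.algorithm, 60, pairs.sum(axis=1))


def collapse_psg_to_minutes(psg: EpochSeries) -> EpochSeries:
    """Wake-wins collapse: minute is sleep iff both 30-s halves are sleep."""
    if psg.epoch_length_s != 30 or psg.kind != BINARY:
        raise ValidationError("expected a 30-s binary sleep-wake series")
    pairs = _paired(psg.values, f"psg {psg.participant_id}")
    return EpochSeries(
        participant_id=psg.participant_id,
        start_time=psg.start_time,
        epoch_length_s=60,
        kind=BINARY,
        values=pairs.min(axis=1),
    )


def pair_distribution(psg: EpochSeries) -> dict[str, float]:
    """Proportions of non-overlapping adjacent 30-s pair states.

    Returns ``{'both_sleep', 'both_wake', 'mixed'}`` proportions summing
    to 1; used to audit how much information the wake-wins collapse loses.
    """
    if psg.epoch_length_s != 30 or psg.kind != BINARY:
        raise ValidationError("expected a 30-s binary sleep-wake series")
    if len(psg) < 2:
        raise ValidationError("need at least one pair of epochs")
    pairs = _paired(psg.values, f"pairs {psg.participant_id}")
    s = pairs.sum(axis=1)
    n = float(len(s))
    return {
        "both_sleep": float((s == 2).sum() / n),
        "both_wake": float((s == 0).sum() / n),
        "mixed": float((s == 1).sum() / n),
    }


def classify_then_pair(binary30: EpochSeries) -> EpochSeries:
    """Alternative collapse for sensitivity analyses: wake-wins on the
    already-binarized 30-s actigraphy decisions instead of summing raw
    scores.  Not the default path."""
    return collapse_psg_to_minutes(binary30)
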