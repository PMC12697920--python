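"""Webster rescoring rules for minute-level sleep-wake series.

Actigraphy scorers systematically call quiet wakefulness "sleep".  The
five Webster rules convert short sleep runs adjacent to long wake runs
back to wake:

1. after >= 4 min wake, the next 1 min of sleep becomes wake
2. after >= 10 min wake, the next 3 min of sleep become wake
3. after >= 15 min wake, the next 4 min of sleep become wake
4. sleep bouts <= 6 min flanked by >= 10 min wake on both sides become wake
5. sleep bouts <= 10 min flanked by >= 20 min wake on both sides become wake

Rules are applied sequentially (1 -> 5), each on the output of the
previous.  Within one rule pass the wake/sleep runs are computed once from
that pass's input and all conversions applied together, so a conversion
never re-triggers the same rule in the same pass.  Only sleep -> wake
changes ever occur.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np

from .epoch_io import BINARY, EpochSeries, ValidationError

log = logging.getLogger(__name__)

# (rule name, minimum preceding wake run, sleep minutes rescored)
TRAILING_RULES = (("rule1", 4, 1), ("rule2", 10, 3), ("rule3", 15, 4))
# (rule name, minimum flanking wake run both sides, maximum bout length)
SURROUND_RULES = (("rule4", 10, 6), ("rule5", 20, 10))


def _runs(x: np.ndarray) -> list[tuple[float, int, int]]:
    """Maximal runs as (value, start, stop) with stop exclusive."""
    edges = np.flatnonzero(np.diff(x)) + 1
    bounds = np.concatenate(([0], edges, [x.size]))
    return [(x[a], int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]


def _apply_trailing(x: np.ndarray, min_wake: int, n_sleep: int) -> np.ndarray:
    out = x.copy()
    runs = _runs(x)
    for i, (val, a, b) in enumerate(runs):
        if val == 0 and (b - a) >= min_wake and i + 1 < len(runs):
            nxt_val, na, nb = runs[i + 1]
            if nxt_val == 1:
                out[na : min(na + n_sleep, nb)] = 0
    return out


def _apply_surround(x: np.ndarray, min_flank: int, max_bout: int) -> np.ndarray:
    out = x.copy()
    runs = _runs(x)
    for i, (val, a, b) in enumerate(runs):
        if val != 1 or (b - a) > max_bout:
            continue
        if i == 0 or i == len(runs) - 1:
            continue  # bouts at the record boundary have no flank
        before = runs[i - 1]
        after = runs[i + 1]
        if (before[2] - before[1]) >= min_flank and (after[2] - after[1]) >= min_flank:
            out[a:b] = 0
    return out


def webster_rescore(binary: EpochSeries) -> tuple[EpochSeries, dict[str, int]]:
    """Apply the five Webster rules; return the rescored series and a
    per-rule count of minutes changed."""
    if binary.epoch_length_s != 60 or binary.kind != BINARY:
        raise ValidationError("webster_rescore expects a 1-minute binary series")
    x = binary.values.astype(int)
    changes: dict[str, int] = {}
    for name, min_wake, n_sleep in TRAILING_RULES:
        nxt = _apply_trailing(x, min_wake, n_sleep)
        changes[name] = int((x != nxt).sum())
        x = nxt
    for name, min_flank, max_bout in SURROUND_RULES:
        nxt = _apply_surround(x, min_flank, max_bout)
        changes[name] = int((x != nxt).sum())
        x = nxt
    # a second sweep changing nothing means we are already at a fixed point
    y = x
    for _, mw, ns in TRAILING_RULES:
        y = _apply_trailing(y, mw, ns)
    for _, mf, mb in SURROUND_RULES:
        y = _apply_surround(y, mf, mb)
    if np.array_equal(y, x):
        log.debug("webster rescoring reached a fixed point in one pass")
    return replace(binary, values=x.astype(float)), changes
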