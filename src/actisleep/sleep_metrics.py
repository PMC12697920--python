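"""Night-level sleep metrics from minute-resolution sleep-wake series.

Definitions (minute epochs, series already cropped to the in-bed interval):

* onset  - first minute scored sleep; offset - last minute scored sleep
* TST    - sleep minutes within [onset, offset]
* WASO   - wake minutes within [onset, offset]
* SE     - 100 * TST / in-bed minutes

so TST + WASO = offset - onset + 1 whenever any sleep occurs.  Sleep onset
is the first single sleep minute (no N-consecutive-minutes criterion); a
consecutive-minutes rule is available via ``onset_rule`` for sensitivity
checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .epoch_io import BINARY, EpochSeries, SyncSpec, ValidationError


@dataclass
class NightMetrics:
    """TST/SE/WASO for one participant-night under one scoring method."""

    participant_id: str
    method: str
    onset_index: int | None
    offset_index: int | None
    tst: float
    waso: float
    in_bed: float
    se: float
    no_sleep: bool = False


def compute_night_metrics(
    binary: EpochSeries,
    method: str = "psg",
    in_bed: SyncSpec | float | None = None,
    onset_rule: int = 1,
) -> NightMetrics:
    """Derive night metrics from a minute-level binary series.

    ``in_bed`` is the in-bed duration in minutes (or a SyncSpec carrying
    it); it defaults to the series length, which is correct when the series
    is already cropped to the in-bed interval.  A night with no sleep at
    all yields TST=WASO=SE=0 with ``no_sleep`` flagged rather than raising.
    """
    if binary.epoch_length_s != 60 or binary.kind != BINARY:
        raise ValidationError("night metrics require a 1-minute binary series")
    if in_bed is None:
        in_bed_min = float(len(binary))
    elif isinstance(in_bed, SyncSpec):
        in_bed_min = float(in_bed.in_bed_minutes)
    else:
        in_bed_min = float(in_bed)

    x = binary.values
    sleep_idx = np.flatnonzero(x == 1)
    if onset_rule > 1 and sleep_idx.size:
        kernel = np.ones(onset_rule)
        runs = np.convolve(x, kernel, mode="valid")
        starts = np.flatnonzero(runs == onset_rule)
        sleep_idx = sleep_idx[sleep_idx >= starts[0]] if starts.size else np.array([], int)
    if sleep_idx.size == 0:
        return NightMetrics(binary.participant_id, method, None, None, 0.0, 0.0, in_bed_min, 0.0, True)
    onset, offset = int(sleep_idx[0]), int(sleep_idx[-1])
    period = x[onset : offset + 1]
    tst = float(period.sum())
    waso = float(period.size - tst)
    se = 100.0 * tst / in_bed_min
    return NightMetrics(binary.participant_id, method, onset, offset, tst, waso, in_bed_min, se)
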