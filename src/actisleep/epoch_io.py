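"""Epoch-series containers and delimited-text I/O.

Actigraphy activity counts and polysomnography (PSG) sleep-wake labels are
both carried as fixed-length epoch series (30 s or 1 min per epoch).  Epochs
are indexed from 0 and cover the half-open interval
``[start + i*epoch_length_s, start + (i+1)*epoch_length_s)``.

Files are plain delimited text with a header.  Column names are mapped
through an explicit schema because source datasets do not share a layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

ACTIVITY = "activity_counts"
BINARY = "binary_sleep_wake"
RAW_SCORE = "raw_score"

_KINDS = (ACTIVITY, BINARY, RAW_SCORE)

DEFAULT_SCHEMA = {"participant_id": "participant_id", "timestamp": "timestamp", "value": "value"}


class SchemaError(ValueError):
    """A declared column is missing from the input file."""


class ValidationError(ValueError):
    """Series values violate the invariants of their kind."""


class TimingError(ValueError):
    """Timestamps are not evenly spaced at the declared epoch length."""


class SynchronizationError(ValueError):
    """The two series do not overlap after applying the offset."""


@dataclass
class EpochSeries:
    """One participant-night of fixed-length epochs.

    Parameters
    ----------
    participant_id : str
        Opaque identifier.
    start_time : pandas.Timestamp
        Timestamp of the start of epoch 0.
    epoch_length_s : int
        Epoch length in seconds, 30 or 60.
    kind : str
        ``activity_counts`` (finite, >= 0), ``binary_sleep_wake``
        (wake=0, sleep=1) or ``raw_score`` (any finite value).
    values : numpy.ndarray
        One value per epoch, length >= 1.
    """

    participant_id: str
    start_time: pd.Timestamp
    epoch_length_s: int
    kind: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.start_time = pd.Timestamp(self.start_time)
        self.values = np.asarray(self.values, dtype=float)
        if self.epoch_length_s not in (30, 60):
            raise ValidationError(f"epoch_length_s must be 30 or 60, got {self.epoch_length_s}")
        if self.kind not in _KINDS:
            raise ValidationError(f"unknown series kind {self.kind!r}")
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValidationError("values must be a non-empty 1-d sequence")
        if not np.all(np.isfinite(self.values)):
            bad = np.flatnonzero(~np.isfinite(self.values))
            raise ValidationError(f"non-finite values at epochs {bad[:5].tolist()}")
        if self.kind == ACTIVITY and np.any(self.values < 0):
            bad = np.flatnonzero(self.values < 0)
            raise ValidationError(f"negative activity counts at epochs {bad[:5].tolist()}")
        if self.kind == BINARY and not np.isin(self.values, (0.0, 1.0)).all():
            bad = np.flatnonzero(~np.isin(self.values, (0.0, 1.0)))
            raise ValidationError(f"non-binary sleep-wake values at epochs {bad[:5].tolist()}")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.start_time + pd.to_timedelta(
            np.arange(len(self)) * self.epoch_length_s, unit="s"
        )

    @property
    def end_time(self) -> pd.Timestamp:
        return self.start_time + pd.Timedelta(seconds=len(self) * self.epoch_length_s)

    def crop(self, start: int, stop: int) -> "EpochSeries":
        """Return epochs ``[start, stop)`` as a new series."""
        if not 0 <= start < stop <= len(self):
            raise ValueError(f"invalid crop [{start}, {stop}) for length {len(self)}")
        return replace(
            self,
            start_time=self.start_time + pd.Timedelta(seconds=start * self.epoch_length_s),
            values=self.values[start:stop].copy(),
        )


@dataclass(frozen=True)
class SyncSpec:
    """Per-participant synchronization record.

    ``psg_offset_epochs`` is the signed number of 30-s epochs by which the
    PSG recording starts after (+) or before (-) the actigraphy recording.
    The in-bed interval is taken as an explicit input (lights-out to
    lights-on), not derived from the data.
    """

    participant_id: str
    psg_offset_epochs: int
    in_bed_start: pd.Timestamp = field(default=None)
    in_bed_end: pd.Timestamp = field(default=None)

    def __post_init__(self) -> None:
        object.__setattr__(self, "in_bed_start", pd.Timestamp(self.in_bed_start))
        object.__setattr__(self, "in_bed_end", pd.Timestamp(self.in_bed_end))
        if self.in_bed_start >= self.in_bed_end:
            raise ValidationError("in_bed_start must precede in_bed_end")

    @property
    def in_bed_minutes(self) -> int:
        return int((self.in_bed_end - self.in_bed_start).total_seconds() // 60)


def read_epoch_series(
    path,
    kind: str,
    schema: Mapping[str, str] | None = None,
    participant_id: str | None = None,
    epoch_length_s: int = 30,
) -> EpochSeries:
    """Read one participant's epoch series from a delimited text file.

    Raises :class:`SchemaError` for missing columns, :class:`TimingError`
    for uneven epoch spacing and :class:`ValidationError` for invariant
    violations, each naming the offending rows (1-based, header excluded).
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = pd.read_csv(path, float_precision="round_trip")
    for key in ("timestamp", "value"):
        if schema[key] not in df.columns:
            raise SchemaError(f"column {schema[key]!r} (for {key}) not found in {path}")
    if participant_id is None:
        col = schema["participant_id"]
        if col not in df.columns:
            raise SchemaError(f"column {col!r} (for participant_id) not found in {path}")
        ids = df[col].astype(str).unique()
        if len(ids) != 1:
            raise SchemaError(f"expected a single participant in {path}, found {len(ids)}")
        participant_id = ids[0]

    try:
        ts = pd.to_datetime(df[schema["timestamp"]])
    except (ValueError, TypeError) as exc:
        raise TimingError(f"unparseable timestamps in {path}: {exc}") from None
    if len(ts) > 1:
        deltas = ts.diff().dt.total_seconds().to_numpy()[1:]
        bad = np.flatnonzero(deltas != epoch_length_s)
        if bad.size:
            raise TimingError(
                f"non-constant epoch spacing at rows {(bad + 2).tolist()[:5]} "
                f"(expected {epoch_length_s} s, got {deltas[bad[:5]].tolist()} s)"
            )
    values = pd.to_numeric(df[schema["value"]], errors="coerce").to_numpy(dtype=float)
    if np.isnan(values).any():
        rows = (np.flatnonzero(np.isnan(values)) + 1).tolist()
        raise ValidationError(f"malformed numeric values at rows {rows[:5]}")
    if kind == ACTIVITY and (values < 0).any():
        rows = (np.flatnonzero(values < 0) + 1).tolist()
        raise ValidationError(f"negative activity counts at rows {rows[:5]}")
    return EpochSeries(participant_id, ts.iloc[0], epoch_length_s, kind, values)


def write_epoch_series(series: EpochSeries, path) -> None:
    """Write a series as CSV (participant_id, timestamp, value); round-trips exactly."""
    pd.DataFrame(
        {
            "participant_id": series.participant_id,
            "timestamp": series.timestamps.strftime("%Y-%m-%dT%H:%M:%S"),
            "value": series.values,
        }
    ).to_csv(path, index=False)


def read_sync_table(path) -> dict[str, SyncSpec]:
    df = pd.read_csv(path)
    required = {"participant_id", "psg_offset_epochs", "in_bed_start", "in_bed_end"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"sync table missing columns {sorted(missing)}")
    return {
        str(r.participant_id): SyncSpec(
            str(r.participant_id),
            int(r.psg_offset_epochs),
            pd.Timestamp(r.in_bed_start),
            pd.Timestamp(r.in_bed_end),
        )
        for r in df.itertuples()
    }


def write_sync_table(specs: Mapping[str, SyncSpec] | list[SyncSpec], path) -> None:
    if isinstance(specs, Mapping):
        specs = list(specs.values())
    pd.DataFrame(
        {
            "participant_id": [s.participant_id for s in specs],
            "psg_offset_epochs": [s.psg_offset_epochs for s in specs],
            "in_bed_start": [s.in_bed_start.isoformat() for s in specs],
            "in_bed_end": [s.in_bed_end.isoformat() for s in specs],
        }
    ).to_csv(path, index=False)


def synchronize(
    act: EpochSeries,
    psg: EpochSeries,
    sync: SyncSpec,
    crop_to_in_bed: bool = False,
) -> tuple[EpochSeries, EpochSeries]:
    """Align a paired actigraphy/PSG night onto their overlapping window.

    Actigraphy epoch ``i`` is simultaneous with PSG epoch ``i - offset``
    where ``offset = sync.psg_offset_epochs``.  Both returned series have
    equal length and cover exactly the overlap; with ``crop_to_in_bed`` they
    are further restricted to epochs starting inside the in-bed interval.
    """
    if act.epoch_length_s != 30 or psg.epoch_length_s != 30:
        raise ValidationError("synchronize expects 30-s epoch series")
    off = int(sync.psg_offset_epochs)
    a_lo = max(0, off)
    a_hi = min(len(act), len(psg) + off)
    if a_hi - a_lo < 1:
        raise SynchronizationError(
            f"no overlap between series (offset {off}, lengths {len(act)}/{len(psg)})"
        )
    act_s = act.crop(a_lo, a_hi)
    psg_s = psg.crop(a_lo - off, a_hi - off)
    if crop_to_in_bed:
        starts = act_s.timestamps
        keep = np.flatnonzero((starts >= sync.in_bed_start) & (starts < sync.in_bed_end))
        if keep.size < 1:
            raise SynchronizationError("in-bed interval does not overlap the aligned window")
        act_s = act_s.crop(int(keep[0]), int(keep[-1]) + 1)
        psg_s = psg_s.crop(int(keep[0]), int(keep[-1]) + 1)
    return act_s, psg_s
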