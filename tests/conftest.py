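import numpy as np
import pandas as pd
import pytest

from actisleep.epoch_io import ACTIVITY, BINARY, EpochSeries, SyncSpec
from actisleep.scoring import load_registry

T0 = pd.Timestamp("2015-06-01 23:00:00")


@pytest.fixture(scope="session")
def registry():
    return load_registry()


def activity_series(values, pid="p1", epoch_s=30, start=T0):
    return EpochSeries(pid, start, epoch_s, ACTIVITY, np.asarray(values, float))


def binary_series(values, pid="p1", epoch_s=60, start=T0):
    return EpochSeries(pid, start, epoch_s, BINARY, np.asarray(values, float))


def sync_for(series, pid=None, offset=0):
    return SyncSpec(
        participant_id=pid or series.participant_id,
        psg_offset_epochs=offset,
        in_bed_start=series.start_time,
        in_bed_end=series.end_time,
    )


@pytest.fixture
def make_activity():
    return activity_series


@pytest.fixture
def make_binary():
    return binary_series
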