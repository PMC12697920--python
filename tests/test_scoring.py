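import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from actisleep.scoring import (
    classify,
    sadeh_features,
    sadeh_score,
    score_series,
    variant_specs,
    weighted_window_score,
)

from conftest import activity_series

LINEAR = ("cole_kripke", "ucsd", "kripke2010", "philips")


def naive_window_score(counts, spec):
    """Independent per-epoch loop oracle for the weighted-window operators."""
    n = len(counts)
    out = np.zeros(n)
    for i in range(n):
        s = 0.0
        for w, off in zip(spec.weights, spec.window_offsets):
            j = i + off
            if 0 <= j < n:
                s += w * counts[j]
        out[i] = spec.scale * s
    return out


def single_spike(pos, value, length=21):
    x = np.zeros(length)
    x[pos] = value
    return activity_series(x)


class TestWeightedWindowScore:
    @pytest.mark.parametrize("name", LINEAR)
    def test_all_zero_counts_score_zero(self, registry, name):
        s = weighted_window_score(activity_series(np.zeros(30)), registry[name])
        assert np.all(s.values == 0.0)

    def test_cole_kripke_center_spike(self, registry):
        # single count of 100 at the scored epoch: D = 0.0001*121*100 = 1.21 -> wake
        s = weighted_window_score(single_spike(10, 100), registry["cole_kripke"])
        assert s.values[10] == pytest.approx(1.21, rel=1e-12)
        binary = classify(s, registry["cole_kripke"])
        assert binary.values[10] == 0  # wake

    def test_cole_kripke_leading_edge_spike(self, registry):
        # count 100 four epochs ahead of the scored one: D = 0.0001*50*100 = 0.5 -> sleep
        s = weighted_window_score(single_spike(10, 100), registry["cole_kripke"])
        assert s.values[14] == pytest.approx(0.5, rel=1e-12)

    def test_kripke2010_previous_epoch_spike(self, registry):
        # count 50 at offset -1: D = 0.30*0.0664*50 = 0.996 < 1 -> sleep
        s = weighted_window_score(single_spike(10, 50), registry["kripke2010"])
        assert s.values[11] == pytest.approx(0.996, rel=1e-12)
        assert classify(s, registry["kripke2010"]).values[11] == 1

    def test_kripke2010_high_spike_is_wake(self, registry):
        s = weighted_window_score(single_spike(10, 500), registry["kripke2010"])
        assert s.values[11] == pytest.approx(9.96, rel=1e-12)
        assert classify(s, registry["kripke2010"]).values[11] == 0

    def test_ucsd_center_spikes(self, registry):
        spec = registry["ucsd"]
        s = weighted_window_score(single_spike(10, 200), spec)
        assert s.values[10] == pytest.approx(0.05 * 0.085 * 200, rel=1e-12)
        assert classify(s, spec).values[10] == 1  # 0.85 < 1 -> sleep
        s2 = weighted_window_score(single_spike(10, 500), spec)
        assert s2.values[10] == pytest.approx(2.125, rel=1e-12)
        assert classify(s2, spec).values[10] == 0

    def test_philips_total_activity_and_thresholds(self, registry):
        spec = registry["philips"]
        s = weighted_window_score(single_spike(10, 30), spec)
        assert s.values[10] == pytest.approx(60.0, rel=1e-12)
        # A=60: wake at T=20 and T=40, sleep at T=80
        assert classify(s, spec, threshold=20).values[10] == 0
        assert classify(s, spec, threshold=40).values[10] == 0
        assert classify(s, spec, threshold=80).values[10] == 1

    def test_philips_neighbour_weight(self, registry):
        s = weighted_window_score(single_spike(10, 10), registry["philips"])
        assert s.values[12] == pytest.approx(0.2 * 10, rel=1e-12)  # offset -2 weight

    def test_window_truncation_drops_out_of_range_positions(self, registry):
        # missing-as-zero: the spike contributes nothing to epochs outside the series
        spec = registry["cole_kripke"]
        x = np.zeros(3)
        x[0] = 100
        s = weighted_window_score(activity_series(x), spec)
        expected = 0.0001 * np.array([121 * 100, 28 * 100, 14 * 100])
        np.testing.assert_allclose(s.values, expected, rtol=1e-12)

    @pytest.mark.parametrize("name", LINEAR)
    def test_matches_naive_loop_oracle(self, registry, name):
        rng = np.random.default_rng(42)
        for _ in range(20):
            x = rng.integers(0, 500, size=rng.integers(1, 80)).astype(float)
            got = weighted_window_score(activity_series(x), registry[name]).values
            np.testing.assert_allclose(got, naive_window_score(x, registry[name]), rtol=1e-12, atol=1e-12)

    @pytest.mark.parametrize("name", LINEAR)
    @given(data=st.data())
    @settings(max_examples=25, deadline=None)
    def test_linearity_and_monotonicity(self, registry, name, data):
        spec = registry[name]
        x = np.array(
            data.draw(st.lists(st.floats(0, 1000), min_size=1, max_size=40)), float
        )
        a = data.draw(st.floats(0, 10))
        base = weighted_window_score(activity_series(x), spec).values
        scaled = weighted_window_score(activity_series(a * x), spec).values
        np.testing.assert_allclose(scaled, a * base, rtol=1e-9, atol=1e-9)
        if x.size:
            i = data.draw(st.integers(0, x.size - 1))
            bumped = x.copy()
            bumped[i] += data.draw(st.floats(0, 100))
            up = weighted_window_score(activity_series(bumped), spec).values
            assert np.all(up >= base - 1e-12)


class TestSadeh:
    def test_all_zero_series_scores_sleep(self, registry):
        # AVG=NATS=SD=0, LG=ln(1)=0 -> PS=7.601 >= 0 -> sleep
        s = sadeh_score(activity_series(np.zeros(20)))
        assert np.all(s.values == pytest.approx(7.601, rel=1e-12))
        assert np.all(classify(s, registry["sadeh"]).values == 1)

    def test_nats_counts_50_to_99_inclusive(self):
        # window {50, 99, 100, 49, 0 x7}: only 50 and 99 qualify -> NATS=2
        x = np.array([50, 99, 100, 49, 0, 0, 0, 0, 0, 0, 0], float)
        feats = sadeh_features(activity_series(x))
        assert feats["nats"][5] == 2  # epoch 5's window covers the whole series

    def test_counts_above_300_are_clipped(self):
        a = sadeh_score(activity_series(np.array([400.0] + [0.0] * 12)))
        b = sadeh_score(activity_series(np.array([300.0] + [0.0] * 12)))
        np.testing.assert_allclose(a.values, b.values, rtol=1e-13)

    def test_constant_sixty_matches_hand_computation(self):
        # interior epoch of a constant-60 record: AVG=60, NATS=11, SD=0,
        # LG=ln(61); PS = 7.601 - 3.9 - 11.88 - 0 - 0.703*ln(61)
        s = sadeh_score(activity_series(np.full(30, 60.0)))
        assert s.values[15] == pytest.approx(-11.06894432651384, rel=1e-12)

    def test_sd_uses_first_six_window_positions(self):
        x = np.zeros(30)
        x[9] = 120.0  # offset -1 for epoch 10, offset +5 for epoch 4
        feats = sadeh_features(activity_series(x))
        assert feats["sd"][10] == pytest.approx(np.std([0, 0, 0, 0, 120, 0], ddof=1))
        assert feats["sd"][4] == 0.0  # spike is outside the first six positions


class TestClassify:
    def test_zero_scores_are_sleep_for_cole_kripke(self, registry):
        spec = registry["cole_kripke"]
        s = weighted_window_score(activity_series(np.zeros(10)), spec)
        assert np.all(classify(s, spec).values == 1)

    def test_philips_threshold_nesting_on_random_scores(self, registry):
        rng = np.random.default_rng(3)
        x = rng.gamma(1.0, 80.0, size=2000)
        spec = registry["philips"]
        s = weighted_window_score(activity_series(x), spec)
        sleep = {t: classify(s, spec, threshold=t).values.astype(bool) for t in (20, 40, 80)}
        assert np.all(sleep[20] <= sleep[40])
        assert np.all(sleep[40] <= sleep[80])

    def test_variant_expansion_yields_seven(self, registry):
        names = set(variant_specs(registry))
        assert names == {
            "cole_kripke", "ucsd", "kripke2010", "sadeh",
            "philips_20", "philips_40", "philips_80",
        }

    def test_score_series_dispatches_sadeh(self, registry):
        s = score_series(activity_series(np.zeros(5)), registry["sadeh"])
        assert s.values[0] == pytest.approx(7.601)
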