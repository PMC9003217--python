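import math
import statistics

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from attnfusion.io_formats import PhysioStream
from attnfusion.physio import (
    CalibrationProfile,
    ClampRange,
    GAParams,
    SubjectInfo,
    calibrate,
    grade_of_attention,
    hrv_features,
    physio_attention_array,
    pnn50,
    rmssd,
    sdnn,
    sdsd,
)
from attnfusion.synthetic import BBModel, RegimeSchedule, RegimeSegment, SubjectSpec, simulate_bb_stream

from .conftest import random_physio_stream

bb_windows = st.lists(
    st.floats(min_value=300.0, max_value=1500.0), min_size=3, max_size=60
)


# --- independent naive oracles (statistics module, explicit loops) ---------


def naive_sdnn(bb):
    return statistics.stdev(bb)


def naive_sdsd(bb):
    return statistics.stdev([bb[i + 1] - bb[i] for i in range(len(bb) - 1)])


def naive_rmssd(bb):
    d = [bb[i + 1] - bb[i] for i in range(len(bb) - 1)]
    return math.sqrt(sum(x * x for x in d) / len(d))


def naive_pnn50(bb):
    d = [abs(bb[i + 1] - bb[i]) for i in range(len(bb) - 1)]
    return 100.0 * sum(x > 50.0 for x in d) / len(d)


class TestFeatures:
    def test_sdnn_constant(self):
        assert sdnn([800, 800, 800]) == 0.0

    def test_sdnn_two_points(self):
        assert sdnn([790, 810]) == pytest.approx(20 / math.sqrt(2))

    def test_sdsd_hand_case(self):
        assert sdsd([800, 850, 800]) == pytest.approx(math.sqrt(5000))

    def test_sdsd_arithmetic_progression(self):
        assert sdsd([800, 810, 820, 830]) == 0.0

    def test_rmssd_hand_case(self):
        assert rmssd([800, 850, 800]) == pytest.approx(50.0)

    def test_rmssd_constant(self):
        assert rmssd([750] * 10) == 0.0

    def test_pnn50_all_over(self):
        assert pnn50([800, 851, 800]) == pytest.approx(100.0)

    def test_pnn50_boundary_is_strict(self):
        assert pnn50([800, 850, 800]) == 0.0

    def test_pnn50_constant(self):
        assert pnn50([800] * 5) == 0.0

    @pytest.mark.parametrize(
        "fn,min_len", [(sdnn, 2), (sdsd, 3), (rmssd, 2), (pnn50, 2)]
    )
    def test_minimum_lengths(self, fn, min_len):
        with pytest.raises(ValueError):
            fn([800.0] * (min_len - 1))

    def test_oracle_suite(self, rng):
        for _ in range(1000):
            n = int(rng.integers(3, 50))
            bb = rng.uniform(400, 1200, size=n).tolist()
            assert sdnn(bb) == pytest.approx(naive_sdnn(bb), rel=1e-9)
            assert sdsd(bb) == pytest.approx(naive_sdsd(bb), rel=1e-9)
            assert rmssd(bb) == pytest.approx(naive_rmssd(bb), rel=1e-9)
            assert pnn50(bb) == pytest.approx(naive_pnn50(bb), rel=1e-9)

    @given(bb_windows)
    def test_sdsd_rmssd_relation(self, bb):
        # centered vs uncentered second moment of the differences
        n = len(bb) - 1
        feats = hrv_features(bb)
        assert feats.sdsd <= feats.rmssd * math.sqrt(n / (n - 1)) + 1e-9

    @given(bb_windows)
    def test_features_non_negative(self, bb):
        feats = hrv_features(bb)
        assert feats.sdnn >= 0 and feats.sdsd >= 0 and feats.rmssd >= 0
        assert 0.0 <= feats.pnn50 <= 100.0


class TestCalibrate:
    def test_constant_baseline_clamped_to_floor(self, subject_info):
        stream = PhysioStream(np.arange(120.0), [75.0] * 120, [800.0] * 120)
        profile = calibrate(subject_info, stream)
        assert profile.threshold_sdnn == 5.0  # demographic floor
        assert profile.threshold_rmssd == 5.0
        assert profile.threshold_sdsd == 5.0
        assert all(profile.clamped.values())

    def test_baseline_recovers_generator_sd(self, subject_info):
        spec = SubjectSpec(baseline_model=BBModel(mean_ms=800, sd_ms=30, phi=0.0))
        sched = RegimeSchedule([RegimeSegment(3000, "attentive")])
        spec.bb_models["attentive"] = spec.baseline_model
        stream = simulate_bb_stream(sched, spec, rng=np.random.default_rng(3))
        profile = calibrate(subject_info, stream, baseline_window_s=3000)
        assert profile.threshold_sdnn == pytest.approx(30.0, rel=0.15)
        # with phi=0 the successive-difference sd is sd*sqrt(2)
        assert profile.threshold_sdsd == pytest.approx(30.0 * math.sqrt(2), rel=0.15)

    def test_disjoint_baselines_agree(self, subject_info, rng):
        long = random_physio_stream(rng, 4000, sd=30.0)
        a = PhysioStream(np.arange(2000.0), long.hr[:2000], long.bb[:2000])
        b = PhysioStream(np.arange(2000.0), long.hr[2000:], long.bb[2000:])
        pa = calibrate(subject_info, a, baseline_window_s=2000)
        pb = calibrate(subject_info, b, baseline_window_s=2000)
        assert pa.threshold_sdnn == pytest.approx(pb.threshold_sdnn, rel=0.1)
        assert pa.threshold_rmssd == pytest.approx(pb.threshold_rmssd, rel=0.1)

    def test_short_baseline_uses_defaults(self, subject_info):
        stream = PhysioStream(np.arange(10.0), [75.0] * 10, [800.0] * 10)
        profile = calibrate(subject_info, stream)
        assert profile.threshold_sdnn == 50.0  # band default

    def test_short_baseline_without_defaults_errors(self, subject_info):
        stream = PhysioStream(np.arange(10.0), [75.0] * 10, [800.0] * 10)
        with pytest.raises(ValueError, match="baseline too short"):
            calibrate(subject_info, stream, allow_defaults=False)

    def test_no_baseline_uses_defaults(self, subject_info):
        profile = calibrate(subject_info, None)
        assert profile.threshold_rmssd == 42.0

    def test_profile_yaml_round_trip(self, tmp_path, profile):
        p = tmp_path / "profile.yaml"
        profile.to_yaml(p)
        assert CalibrationProfile.from_yaml(p) == profile

    def test_invalid_direction(self):
        with pytest.raises(ValueError):
            CalibrationProfile("s", 10, 10, 10, direction="sideways")

    def test_clamp_range(self):
        r = ClampRange(5.0, 300.0, 50.0)
        assert r.clamp(0.0) == 5.0
        assert r.clamp(1000.0) == 300.0
        assert r.clamp(42.0) == 42.0


class TestGradeOfAttention:
    def test_constant_window_below_direction_saturates(self, profile):
        params = GAParams(ws=100, inner_len=30)
        ga = grade_of_attention(np.full(100, 800.0), profile, params)
        assert ga == 3 * 100

    def test_upper_bound_on_random_inputs(self, profile, rng):
        params = GAParams(ws=60, inner_len=10)
        for _ in range(20):
            bb = rng.uniform(400, 1200, size=60)
            assert 0 <= grade_of_attention(bb, profile, params) <= 3 * 60

    def test_matched_process_is_near_half(self, subject_info, rng):
        # window drawn from the same process as the baseline: each of the
        # three comparisons is close to a fair coin, so GA ~ 1.5*ws
        stream = random_physio_stream(rng, 5000, sd=30.0)
        profile = calibrate(subject_info, stream, baseline_window_s=5000)
        params = GAParams(ws=200, inner_len=30)
        gas = []
        for start in range(0, 4800, 200):
            gas.append(
                grade_of_attention(stream.bb[start : start + 200], profile, params)
            )
        mean_ga = np.mean(gas)
        assert mean_ga == pytest.approx(1.5 * 200, rel=0.10)

    def test_wrong_length_rejected(self, profile):
        with pytest.raises(ValueError, match="segment length"):
            grade_of_attention(np.full(50, 800.0), profile, GAParams(ws=100))

    def test_monotone_as_variability_shrinks(self, profile, rng):
        # shrinking spread moves every inner stat below-ward, so with
        # direction=below GA never decreases
        params = GAParams(ws=100, inner_len=20)
        bb = rng.uniform(700, 900, size=100)
        ga_raw = grade_of_attention(bb, profile, params)
        shrunk = bb.mean() + 0.3 * (bb - bb.mean())
        assert grade_of_attention(shrunk, profile, params) >= ga_raw

    def test_direction_above_flips(self, rng):
        params = GAParams(ws=60, inner_len=10)
        below = CalibrationProfile("s", 30.0, 30.0, 30.0, direction="below")
        above = CalibrationProfile("s", 30.0, 30.0, 30.0, direction="above")
        bb = rng.uniform(400, 1200, size=60)
        assert (
            grade_of_attention(bb, below, params)
            + grade_of_attention(bb, above, params)
            <= 3 * 60
        )


class TestGAParams:
    @pytest.mark.parametrize("ws", [25, 50, 100, 200, 300])
    def test_tp_is_ratio_three_halves(self, ws):
        params = GAParams(ws=ws, inner_len=min(30, ws))
        assert params.threshold / ws == pytest.approx(1.5)

    def test_override(self):
        assert GAParams(ws=100, t_p=123.0).threshold == 123.0

    def test_inner_len_bounds(self):
        with pytest.raises(ValueError):
            GAParams(ws=100, inner_len=1)
        with pytest.raises(ValueError):
            GAParams(ws=10, inner_len=30)


def naive_physio_array(stream, profile, params):
    """Oracle: recompute every window's grade from scratch with explicit loops."""

    def inner_stats(bb_all, s):
        lo = max(s - params.inner_len + 1, 0)
        if s < params.inner_len - 1:
            seg = bb_all[: params.inner_len]
        else:
            seg = bb_all[lo : s + 1]
        return sdnn(seg), rmssd(seg), sdsd(seg)

    thresholds = (profile.threshold_sdnn, profile.threshold_rmssd, profile.threshold_sdsd)
    out = []
    for end in range(params.ws, len(stream) + 1):
        ga = 0
        for s in range(end - params.ws, end):
            for stat, th in zip(inner_stats(stream.bb, s), thresholds):
                if profile.direction == "below":
                    ga += stat < th
                else:
                    ga += stat > th
        out.append(ga > params.threshold)
    return out


class TestPhysioAttentionArray:
    def test_all_attention_on_constant_stream(self, profile):
        stream = PhysioStream(np.arange(150.0), [75.0] * 150, [800.0] * 150)
        arr = physio_attention_array(stream, profile, GAParams(ws=100))
        assert arr.attention.all()
        assert len(arr) == 51
        assert arr.t[0] == 100

    def test_cadence(self, profile, rng):
        stream = random_physio_stream(rng, 321)
        arr = physio_attention_array(stream, profile, GAParams(ws=100))
        assert len(arr) == 321 - 100 + 1

    def test_exact_threshold_is_distraction(self, profile):
        stream = PhysioStream(np.arange(100.0), [75.0] * 100, [800.0] * 100)
        params = GAParams(ws=100, t_p=300.0)  # grade saturates at exactly 300
        arr = physio_attention_array(stream, profile, params)
        assert not arr.attention.any()

    def test_too_short_stream_rejected(self, profile):
        stream = PhysioStream(np.arange(50.0), [75.0] * 50, [800.0] * 50)
        with pytest.raises(ValueError, match="shorter"):
            physio_attention_array(stream, profile, GAParams(ws=100))

    def test_extra_delay(self, profile):
        stream = PhysioStream(np.arange(150.0), [75.0] * 150, [800.0] * 150)
        arr = physio_attention_array(
            stream, profile, GAParams(ws=100), extra_delay_s=10
        )
        assert arr.t[0] == 110

    @pytest.mark.parametrize("direction", ["below", "above"])
    def test_matches_naive_oracle(self, direction, rng):
        stream = random_physio_stream(rng, 120)
        profile = CalibrationProfile("s", 25.0, 25.0, 25.0, direction=direction)
        params = GAParams(ws=40, inner_len=10)
        arr = physio_attention_array(stream, profile, params)
        assert list(arr.attention) == naive_physio_array(stream, profile, params)

    def test_regime_flip_latency(self, subject_info):
        # well-separated two-regime stream: the array flips within
        # ws + inner_len seconds of the true change point
        sched = RegimeSchedule(
            [RegimeSegment(600, "attentive"), RegimeSegment(600, "distracted")]
        )
        spec = SubjectSpec(seed=11)
        stream = simulate_bb_stream(sched, spec, rng=np.random.default_rng(11))
        baseline = PhysioStream(
            np.arange(180.0),
            np.full(180, 75.0),
            np.maximum(np.random.default_rng(12).normal(800, 30, 180), 100.0),
        )
        profile = calibrate(subject_info, baseline, baseline_window_s=180)
        params = GAParams(ws=100, inner_len=30)
        arr = physio_attention_array(stream, profile, params)
        margin = params.ws + params.inner_len
        before = arr.attention[(arr.t > 300) & (arr.t <= 600)]
        after = arr.attention[arr.t > 600 + margin]
        assert before.mean() > 0.9
        assert after.mean() < 0.1
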