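"""Timing metrics: interval differences, delays, sign conventions."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from eventqa import (
    CorruptionSpec,
    PulseSequence,
    duration_deviation,
    generate_experiment,
    interval_series,
    logging_inaccuracy,
    pair_pulses_to_events,
    parse_photodiode,
    response_inaccuracy,
    summarize,
    synthesize_photodiode,
    trigger_delay,
    trigger_jitter,
)
from eventqa.signal_parsing import paired_pulse_sequence
from eventqa.timing_metrics import clock_drift_slope, is_well_calibrated

from conftest import make_plan


def seq(*times):
    return PulseSequence(np.asarray(times, float))


class TestIntervalSeries:
    def test_direct(self):
        np.testing.assert_allclose(interval_series(seq(0.0, 1.0, 2.5)), [1.0, 1.5])

    def test_arithmetic_sequence_constant(self):
        t = np.arange(20) * 0.75
        np.testing.assert_allclose(interval_series(PulseSequence(t)), 0.75)

    def test_matches_pairwise_subtraction_oracle(self, rng):
        t = np.sort(rng.uniform(0, 100, 50))
        oracle = np.array([t[i + 1] - t[i] for i in range(len(t) - 1)])
        np.testing.assert_array_equal(interval_series(PulseSequence(t)), oracle)

    def test_too_few_times(self):
        with pytest.raises(ValueError, match="at least 2"):
            interval_series(seq(1.0))


class TestLoggingInaccuracy:
    def test_direct_arithmetic(self):
        d = logging_inaccuracy(seq(0.5, 1.516, 2.5), seq(0.0, 1.0, 2.0))
        np.testing.assert_allclose(d.values, [0.016, -0.016], atol=1e-12)
        assert d.mean == pytest.approx(0.0, abs=1e-12)
        assert d.sd == pytest.approx(0.016 * np.sqrt(2), rel=1e-6)
        assert d.kind == "log_timing"

    def test_constant_offset_cancels(self):
        log = seq(0.0, 1.0, 2.0, 3.5)
        photo = PulseSequence(log.onsets + 0.250)
        np.testing.assert_array_equal(logging_inaccuracy(photo, log).values, 0.0)

    def test_jitter_sd_scales_by_sqrt2(self):
        plan = make_plan(500)
        r = generate_experiment(plan, CorruptionSpec(jitter_sd=0.005), seed=20)
        d = logging_inaccuracy(r.truth, r.log.to_pulses())
        expected = 0.005 * np.sqrt(2)
        assert abs(d.sd - expected) < 0.15 * expected
        assert abs(d.mean) < 0.001


class TestDurationDeviation:
    def test_direct(self):
        plan = make_plan(2, planned_durations=0.5)
        r = generate_experiment(plan, CorruptionSpec(), seed=0)
        photo = PulseSequence(r.truth.onsets, r.truth.onsets + [0.5, 0.516])
        d = duration_deviation(photo, r.log)
        np.testing.assert_allclose(d.values, [0.0, 0.016], atol=1e-12)

    def test_missing_offsets_instructs_scheme(self):
        plan = make_plan(2)
        r = generate_experiment(plan, CorruptionSpec(), seed=0)
        with pytest.raises(ValueError, match="onset_and_offset"):
            duration_deviation(PulseSequence(r.truth.onsets), r.log)

    def test_clean_pipeline_zero_within_sample(self):
        r = generate_experiment(make_plan(20), CorruptionSpec(), seed=1)
        trace = synthesize_photodiode(r.truth, fs=1000, noise_sd=0)
        paired = pair_pulses_to_events(parse_photodiode(trace, 0.5), r.log)
        d = duration_deviation(paired_pulse_sequence(paired), r.log)
        assert d.max_abs <= 1.0 / 1000 + 1e-12


class TestTriggerMetrics:
    def test_jitter_direct(self):
        d = trigger_jitter(seq(0.5, 1.5, 2.5), seq(10.5, 11.52, 12.5))
        np.testing.assert_allclose(d.values, [-0.02, 0.02], atol=1e-12)

    def test_jitter_blind_to_constant_delay(self):
        photo = seq(0.5, 1.5, 2.5, 4.0)
        trig = PulseSequence(photo.onsets + 0.030)
        np.testing.assert_allclose(trigger_jitter(photo, trig).values, 0.0, atol=1e-12)

    def test_delay_paper_example(self):
        d = trigger_delay(seq(1.032), seq(1.000))
        np.testing.assert_allclose(d.values, [0.032])
        assert d.n == 1 and d.low_n

    def test_delay_identical_streams_zero(self):
        p = seq(1.0, 2.0, 3.0)
        np.testing.assert_array_equal(trigger_delay(p, p).values, 0.0)

    def test_count_mismatch(self):
        with pytest.raises(ValueError, match="count mismatch"):
            trigger_jitter(seq(1.0, 2.0), seq(1.0, 2.0, 3.0))

    def test_drift_slope_diagnostic(self):
        photo = PulseSequence(np.arange(100) * 1.0)
        trig = PulseSequence(photo.onsets * (1 - 1e-4) + 0.01)  # 100 ppm drift
        assert clock_drift_slope(photo, trig) == pytest.approx(1e-4, rel=1e-3)


class TestResponseInaccuracy:
    def test_identical_intervals_zero(self):
        d = response_inaccuracy(seq(1.0, 2.0, 3.0), seq(5.0, 6.0, 7.0))
        np.testing.assert_array_equal(d.values, 0.0)
        assert d.kind == "response_timing"

    def test_sign_convention_single_interval(self):
        # audio interval 1.0, logged interval 1.01 -> audio minus log = -0.01
        d = response_inaccuracy(seq(1.0, 2.0), seq(1.0, 2.01))
        np.testing.assert_allclose(d.values, [-0.010], atol=1e-12)

    def test_response_jitter_recovery(self):
        plan = make_plan(300, response_plan=[("f", 1)] * 300)
        r = generate_experiment(plan, CorruptionSpec(jitter_sd=0.003), seed=30)
        d = response_inaccuracy(r.response_truth, r.log)
        expected = 0.003 * np.sqrt(2)
        assert abs(d.sd - expected) < 0.20 * expected


class TestSummarize:
    def test_two_value_series(self):
        from eventqa.core import DeltaSeries

        s = summarize(DeltaSeries(np.array([0.016, -0.016]), "log_timing"))
        assert s["mean_s"] == pytest.approx(0.0, abs=1e-12)
        assert s["sd_s"] == pytest.approx(0.0226, abs=1e-4)

    def test_single_value_low_n(self):
        from eventqa.core import DeltaSeries

        s = summarize(DeltaSeries(np.array([0.005]), "trigger_delay"))
        assert s == {
            "kind": "trigger_delay",
            "mean_s": 0.005,
            "sd_s": 0.0,
            "n": 1,
            "max_abs_s": 0.005,
            "low_n": True,
        }

    def test_empty_rejected(self):
        from eventqa.core import DeltaSeries

        with pytest.raises(ValueError):
            summarize(DeltaSeries(np.array([]), "log_timing"))


class TestProperties:
    @given(st.floats(-1e4, 1e4), st.floats(-1e4, 1e4))
    def test_offset_invariance(self, c1, c2):
        photo = seq(0.5, 1.51, 2.5, 3.49)
        log = seq(0.0, 1.0, 2.0, 3.0)
        base = logging_inaccuracy(photo, log).values
        shifted = logging_inaccuracy(photo.shifted(c1), log.shifted(c2)).values
        np.testing.assert_allclose(shifted, base, atol=1e-9)

    def test_antisymmetry(self):
        a, b = seq(0.5, 1.51, 2.5), seq(0.0, 1.0, 2.0)
        np.testing.assert_allclose(
            trigger_jitter(a, b).values, -trigger_jitter(b, a).values, atol=1e-12
        )
        np.testing.assert_allclose(
            trigger_delay(a, b).values, -trigger_delay(b, a).values, atol=1e-12
        )

    def test_zero_law(self):
        p = seq(1.0, 2.2, 3.1)
        assert np.all(logging_inaccuracy(p, p).values == 0.0)
        assert np.all(trigger_delay(p, p).values == 0.0)

    def test_well_calibrated_threshold(self):
        from eventqa.core import DeltaSeries

        good = DeltaSeries(np.array([0.001, -0.001, 0.0005]), "log_timing")
        bad = DeltaSeries(np.array([0.02, -0.015, 0.01]), "log_timing")
        assert is_well_calibrated(good)
        assert not is_well_calibrated(bad)
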