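"""Fixture generator: parameter recovery, determinism, conservation."""
import io

import numpy as np
import pytest

from eventqa import (
    CorruptionSpec,
    ExperimentPlan,
    PulseSequence,
    generate_experiment,
    synthesize_keypress_audio,
    synthesize_photodiode,
    synthesize_triggers,
)
from eventqa.timing_metrics import trigger_delay, trigger_jitter

from conftest import make_plan


class TestGenerateExperiment:
    def test_identity_corruption_logs_truth_exactly(self, small_plan):
        r = generate_experiment(small_plan, CorruptionSpec(), seed=3)
        np.testing.assert_array_equal(r.log.onsets, r.truth.onsets)

    def test_constant_delay_shifts_every_logged_onset(self, small_plan):
        r = generate_experiment(small_plan, CorruptionSpec(clock_delay=0.032), seed=3)
        np.testing.assert_allclose(r.log.onsets - r.truth.onsets, 0.032, atol=1e-12)

    def test_gaussian_jitter_sd_recovered(self):
        plan = make_plan(500)
        r = generate_experiment(plan, CorruptionSpec(jitter_sd=0.005), seed=11)
        noise = r.log.onsets - r.truth.onsets
        assert abs(noise.std(ddof=1) - 0.005) < 0.15 * 0.005
        assert abs(noise.mean()) < 0.001

    def test_fixed_magnitude_jitter_hits_selected_rows_only(self):
        plan = make_plan(100)
        spec = CorruptionSpec(jitter_magnitude=0.016, jitter_proportion=0.2)
        r = generate_experiment(plan, spec, seed=5)
        err = r.log.onsets - r.truth.onsets
        assert len(r.jittered_rows) == 20
        np.testing.assert_allclose(np.abs(err[r.jittered_rows]), 0.016)
        untouched = np.setdiff1d(np.arange(100), r.jittered_rows)
        np.testing.assert_array_equal(err[untouched], 0.0)

    def test_label_errors_applied_to_exactly_k_rows(self, small_plan):
        r = generate_experiment(small_plan, CorruptionSpec(label_errors=3), seed=9)
        factors = r.log.factor_columns
        diff = (
            r.log.df[factors].to_numpy() != r.truth_log.df[factors].to_numpy()
        ).any(axis=1)
        assert diff.sum() == 3
        np.testing.assert_array_equal(np.nonzero(diff)[0], r.label_error_rows)

    def test_dropped_events_missing_from_log_but_not_truth(self, small_plan):
        r = generate_experiment(small_plan, CorruptionSpec(drop_events=2), seed=2)
        assert len(r.log) == small_plan.n_events - 2
        assert len(r.truth) == small_plan.n_events

    def test_determinism_byte_identical(self, small_plan):
        spec = CorruptionSpec(jitter_sd=0.002, label_errors=2, seed=42)
        outs = []
        for _ in range(2):
            buf = io.StringIO()
            generate_experiment(small_plan, spec).log.df.to_csv(buf)
            outs.append(buf.getvalue())
        assert outs[0] == outs[1]

    def test_non_monotonic_corruption_names_first_violator(self):
        plan = make_plan(20, planned_durations=0.01, inter_event_interval=0.0)
        with pytest.raises(ValueError, match="non-monotonic at event"):
            generate_experiment(plan, CorruptionSpec(jitter_sd=0.05), seed=0)

    def test_ground_truth_strictly_increasing(self, small_plan):
        r = generate_experiment(small_plan, CorruptionSpec(jitter_sd=0.003), seed=1)
        assert np.all(np.diff(r.truth.onsets) > 0)

    def test_response_plan_generates_uncontrolled_rows(self):
        plan = make_plan(4, response_plan=[("f", 1), ("j", 2), ("f", 1), ("j", 1)])
        r = generate_experiment(plan, CorruptionSpec(), seed=0)
        resp = r.log.uncontrolled
        assert list(resp.df["response_key"]) == ["f", "j", "j", "f", "j"]
        np.testing.assert_array_equal(resp.onsets, r.response_truth.onsets)


class TestSynthesizePhotodiode:
    def test_single_pulse_sample_placement(self):
        truth = PulseSequence(np.array([0.1]), source="truth")
        trace = synthesize_photodiode(
            truth, fs=1000, pulse_width=0.02, noise_sd=0, scheme="onset_only"
        )
        assert np.all(trace.samples[100:120] == 1.0)
        mask = np.ones(trace.n_samples, bool)
        mask[100:120] = False
        assert np.all(trace.samples[mask] == 0.0)

    def test_empty_truth_gives_constant_baseline(self):
        trace = synthesize_photodiode(
            PulseSequence(np.array([])), scheme="onset_only", noise_sd=0
        )
        assert np.all(trace.samples == 0.0)

    def test_onset_and_offset_scheme_doubles_pulses(self):
        truth = PulseSequence(np.array([1.0, 3.0]), np.array([2.0, 4.0]))
        trace = synthesize_photodiode(truth, fs=1000, noise_sd=0)
        rises = np.sum(np.diff((trace.samples > 0.5).astype(int)) == 1)
        assert rises == 4

    def test_overlapping_pulses_error_lists_events(self):
        truth = PulseSequence(np.array([1.0, 1.005]), source="truth")
        with pytest.raises(ValueError, match="overlapping.*event indices"):
            synthesize_photodiode(truth, fs=1000, pulse_width=0.02, scheme="onset_only")

    def test_unresolvable_pulse_width_rejected(self):
        truth = PulseSequence(np.array([1.0]))
        with pytest.raises(ValueError, match="cannot resolve"):
            synthesize_photodiode(truth, fs=100, pulse_width=0.0167, scheme="onset_only")


class TestSynthesizeAudio:
    def test_burst_energy_concentrated_at_press(self):
        presses = PulseSequence(np.array([1.0]))
        trace = synthesize_keypress_audio(presses, fs=44100, click_duration=0.01, snr=20)
        e = trace.samples**2
        inside = e[int(1.0 * 44100) : int(1.01 * 44100)]
        outside = np.delete(e, np.s_[int(1.0 * 44100) : int(1.01 * 44100)])
        assert inside.mean() > 100 * outside.mean()  # snr^2 = 400

    def test_zero_presses_noise_floor_only(self):
        trace = synthesize_keypress_audio(PulseSequence(np.array([])), snr=10)
        assert np.abs(trace.samples).max() < 1.0  # nothing but the 1/snr floor

    def test_overlapping_presses_rejected(self):
        presses = PulseSequence(np.array([1.0, 1.005]))
        with pytest.raises(ValueError, match="overlap"):
            synthesize_keypress_audio(presses, click_duration=0.01)


class TestSynthesizeTriggers:
    def test_no_corruption_timestamps_equal_truth(self):
        truth = PulseSequence(np.array([1.0, 2.0, 3.0]))
        trig = synthesize_triggers(truth, codes=["a", "b", "c"])
        np.testing.assert_array_equal(trig["timestamp_s"], truth.onsets)
        assert list(trig["code"]) == ["a", "b", "c"]

    def test_constant_delay_recovered_exactly_by_delay_estimator(self):
        # triggers arriving 30 ms late: photo - trig = -0.030, exactly, for
        # every event; the magnitude is the injected delay
        truth = PulseSequence(10.0 + np.arange(50) * 1.0)
        trig = synthesize_triggers(truth, delay=0.030, jitter_sd=0.0)
        series = trigger_delay(truth, PulseSequence(trig["timestamp_s"].to_numpy()))
        assert series.mean == pytest.approx(-0.030, abs=1e-12)
        assert series.sd == pytest.approx(0.0, abs=1e-12)
        assert series.max_abs == pytest.approx(0.030, abs=1e-12)

    def test_trigger_jitter_sd_scales_by_sqrt2(self):
        truth = PulseSequence(10.0 + np.arange(1000) * 1.0)
        trig = synthesize_triggers(truth, jitter_sd=0.002, seed=8)
        series = trigger_jitter(truth, PulseSequence(trig["timestamp_s"].to_numpy()))
        expected = 0.002 * np.sqrt(2)
        assert abs(series.sd - expected) < 0.15 * expected

    def test_code_count_mismatch_rejected(self):
        truth = PulseSequence(np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match="one code per event"):
            synthesize_triggers(truth, codes=["a"])
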