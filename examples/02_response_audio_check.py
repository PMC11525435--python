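"""Validate response logging with a microphone recording of key presses.

Follows a preplanned response sequence (including a deliberate double
press), synthesizes the microphone trace of the actual presses, extracts
press onsets from the audio envelope, and checks both the response content
(keys logged as planned?) and the response timestamping precision.
"""
import numpy as np

from eventqa import (
    CorruptionSpec,
    ExperimentPlan,
    ResponsePlan,
    check_response_plan,
    extract_audio_onsets,
    response_inaccuracy,
    summarize,
    synthesize_keypress_audio,
)
from eventqa import generate_experiment

presses = [("f", 1), ("j", 1), ("f", 2), ("j", 1), ("f", 1), ("j", 1)]
plan = ExperimentPlan(
    n_events=6,
    condition_factors={"category": ["face", "object"]},
    planned_durations=0.5,
    inter_event_interval=1.0,
    response_plan=presses,
)
experiment = generate_experiment(plan, CorruptionSpec(jitter_sd=0.002, seed=3))

audio = synthesize_keypress_audio(
    experiment.response_truth, fs=44100.0, click_duration=0.01, snr=15, seed=4
)
press_onsets = extract_audio_onsets(audio, refractory=0.05)

content = check_response_plan(experiment.log, ResponsePlan(presses))
timing = summarize(response_inaccuracy(press_onsets, experiment.log))

print(f"planned presses          : {content.n_events_tested} "
      f"({content.n_conditions_tested} key types)")
print(f"inaccurately logged      : {content.n_mismatches} / {content.n_events_tested}")
print(
    f"response timestamping    : mean {timing['mean_s'] * 1e3:+.2f} ms, "
    f"sd {timing['sd_s'] * 1e3:.2f} ms (n={timing['n']})"
)
print(
    "\nZero content mismatches means every planned press (including the"
    "\ndouble press) appears in the log with the right key. The timing sd"
    "\ntracks the injected 2 ms response-logging jitter times sqrt(2)"
    "\n(~2.8 ms), loosely at this small n."
)
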