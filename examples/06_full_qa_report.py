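"""Assemble the standardized QA report from a full synthetic test run.

Runs the complete pipeline on one synthetic experiment - photodiode
parsing, timing metrics, content audit, trigger checks, geometry - and
renders the standardized report in markdown.  Sections without artifacts
are reported as "not performed" rather than silently dropped.
"""
from eventqa import (
    CorruptionSpec,
    ExperimentPlan,
    PulseSequence,
    ScreenGeometry,
    StimulusGeometry,
    build_report,
    compare_event_content,
    generate_experiment,
    logging_inaccuracy,
    pair_pulses_to_events,
    parse_photodiode,
    render_report,
    stimulus_angles,
    synthesize_photodiode,
    synthesize_triggers,
    trigger_jitter,
)
from eventqa.signal_parsing import paired_pulse_sequence

plan = ExperimentPlan(
    n_events=40,
    condition_factors={"category": ["face", "object"]},
)
experiment = generate_experiment(plan, CorruptionSpec(jitter_sd=0.001, label_errors=1, seed=5))

trace = synthesize_photodiode(experiment.truth, fs=2000.0, noise_sd=0.02)
paired = pair_pulses_to_events(parse_photodiode(trace), experiment.log)
physical = paired_pulse_sequence(paired)

triggers = synthesize_triggers(experiment.truth, jitter_sd=0.0005, seed=6)
trig = PulseSequence(triggers["timestamp_s"].to_numpy(), source="trigger")

screen = ScreenGeometry(1920, 1080, 53.1, 29.9, viewing_distance_cm=60.0)
report = build_report(
    geometry=stimulus_angles(screen, StimulusGeometry(width=3.0, height=3.0)),
    content=compare_event_content(experiment.log, experiment.truth_log),
    timing={"log_timing": logging_inaccuracy(physical, experiment.log)},
    trigger_jitter=trigger_jitter(physical, trig),
)

print(render_report(report, format="markdown"))
print(
    "The content section fails (1 mislabelled event out of 40), which is"
    "\nexactly what the report should surface: content errors must be zero"
    "\nbefore data collection starts."
)
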