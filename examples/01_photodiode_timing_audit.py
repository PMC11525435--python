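"""Audit log-file event timing against a photodiode ground truth.

Builds a synthetic 100-event experiment whose log carries a 25 ms constant
clock delay plus 3 ms Gaussian timestamping jitter, renders the photodiode
luminance trace (a square flashing at every event onset and offset),
parses it back into pulse times, and quantifies the log's timestamping
inaccuracy and duration error.
"""
import numpy as np

from eventqa import (
    CorruptionSpec,
    ExperimentPlan,
    duration_deviation,
    generate_experiment,
    logging_inaccuracy,
    pair_pulses_to_events,
    parse_photodiode,
    summarize,
    synthesize_photodiode,
)
from eventqa.signal_parsing import paired_pulse_sequence

plan = ExperimentPlan(
    n_events=100,
    condition_factors={"category": ["face", "object"]},
    planned_durations=0.5,
    inter_event_interval=0.5,
)
corruption = CorruptionSpec(clock_delay=0.025, jitter_sd=0.003, seed=42)
experiment = generate_experiment(plan, corruption)

trace = synthesize_photodiode(experiment.truth, fs=2000.0, noise_sd=0.05)
pulses = parse_photodiode(trace)  # threshold -> binarize -> transitions
paired = pair_pulses_to_events(pulses, experiment.log)
physical = paired_pulse_sequence(paired)

timing = summarize(logging_inaccuracy(physical, experiment.log))
durations = summarize(duration_deviation(physical, experiment.log))

print(f"events logged / detected : {len(experiment.log)} / {len(paired)}")
print(
    f"log timestamping error   : mean {timing['mean_s'] * 1e3:+.2f} ms, "
    f"sd {timing['sd_s'] * 1e3:.2f} ms (n={timing['n']})"
)
print(
    f"duration vs plan         : mean {durations['mean_s'] * 1e3:+.2f} ms, "
    f"sd {durations['sd_s'] * 1e3:.2f} ms"
)
print(
    "\nThe mean timestamping error stays near zero even though the log is"
    "\n25 ms late everywhere: interval differences cancel constant clock"
    "\noffsets. The sd tracks the injected 3 ms per-event jitter scaled by"
    "\nsqrt(2) (~4.2 ms), up to sampling error at n=99, because each"
    "\ninterval difference mixes two noisy timestamps."
)
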