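"""Benchmark peripheral trigger timing against the photodiode.

Simulates an EEG-style trigger stream that runs 30 ms late and carries
1.5 ms jitter, then estimates (1) the jitter from interval differences
(blind to the delay by construction) and (2) the delay itself from
same-clock timestamp differences, plus a clock-drift diagnostic.
"""
import numpy as np

from eventqa import (
    PulseSequence,
    summarize,
    synthesize_triggers,
    trigger_delay,
    trigger_jitter,
)
from eventqa.timing_metrics import clock_drift_slope

photo = PulseSequence(10.0 + np.arange(300) * 1.2, source="photodiode")
triggers = synthesize_triggers(photo, delay=0.030, jitter_sd=0.0015, seed=9)
trig = PulseSequence(triggers["timestamp_s"].to_numpy(), source="trigger")

jitter = summarize(trigger_jitter(photo, trig))
delay = summarize(trigger_delay(photo, trig))
drift = clock_drift_slope(photo, trig)

print(
    f"trigger jitter  : mean {jitter['mean_s'] * 1e3:+.3f} ms, "
    f"sd {jitter['sd_s'] * 1e3:.3f} ms (n={jitter['n']})"
)
print(
    f"trigger delay   : mean {delay['mean_s'] * 1e3:+.2f} ms, "
    f"sd {delay['sd_s'] * 1e3:.2f} ms (same-clock recording required)"
)
print(f"clock drift     : {drift * 1e6:+.1f} ppm")
print(
    "\nThe interval method reports ~2.1 ms jitter (1.5 ms per event times"
    "\nsqrt(2)) and is unaffected by the 30 ms delay; the delay shows up"
    "\nonly in the same-clock timestamp comparison (photo - trigger)."
)
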