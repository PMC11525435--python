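# Methods

This note documents the models, conventions and numerical choices behind
`eventqa`, in the spirit of a statistics package's methods appendix.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Units and sign conventions

All times are seconds internally; reports convert to milliseconds only at
rendering.  Sign conventions are fixed once, because sign errors are the
most likely bug in timing audits:

- interval-based metrics (log timestamping inaccuracy, trigger jitter,
  response inaccuracy): **physical minus other**, i.e. photodiode (or
  microphone) interval minus log/trigger interval;
- trigger delay: **t_photo − t_trig** on raw timestamps (same clock
  required; the report flags the assertion);
- duration deviation: observed minus planned.

Consequences worth knowing: a constant clock offset between streams
cancels exactly in every interval-based metric (tested as a property); a
per-event Gaussian timestamp jitter of SD σ appears in the interval
differences with SD σ√2, because each difference mixes two independent
noisy timestamps; and a trigger stream that is systematically *late* by d
yields a delay series of −d (the printed reference case, photodiode event
32 ms after the trigger stamp, yields +32 ms).

No drift detrending is applied anywhere: interval differences over
successive events are already insensitive to slow clock drift.  A linear
drift slope (fit of timestamp difference against time) is computed as a
diagnostic only.

## Photodiode and audio parsing

The parsing pipeline is deliberately minimal: threshold → binarize (1 iff
sample ≥ threshold) → discrete difference → transitions at +1 (onset) and
−1 (offset), each stamped at the *first sample on the new side* and
converted to seconds via the sampling rate.  A refractory period (default
2 samples for the photodiode, 50 ms for audio) discards transitions too
close to the previously accepted one, suppressing threshold chatter.

Auto-thresholding uses the midpoint of the 1st and 99th percentiles of the
trace — robust to outliers, and valid whenever the pulses occupy more than
~1 % of samples (true for the default flash scheme: two one-frame flashes
per ~1 s event).  For microphone envelopes the click duty cycle can be far
below 1 %, where any fixed-percentile rule collapses onto the noise floor;
the audio auto threshold is therefore the midpoint of the envelope median
and maximum, with a silence guard (no burst 10× above the floor → empty
result).  Callers can always pass an explicit threshold.

Under the default flash scheme the square flashes briefly at each event
onset *and* offset, so a recording of n events must contain exactly 2n
pulses, paired in order.  Count mismatches are hard errors (photodiode
signal-quality failures require intervention, not silent repair); the
error reports both counts and the event at which inter-pulse intervals
first diverge from the log's expectation, using a tolerance of a quarter
of the smallest expected interval.

## Synthetic experiments (what the generator emulates)

The fixture generator produces the full set of QA inputs — event log,
ground-truth pulse times, trigger streams, photodiode and microphone
traces — with known injected corruptions, so that every metric is testable
by parameter recovery.  Corruptions: constant clock delay; Gaussian
per-event jitter; fixed-magnitude random-sign jitter on a random subset
(mirroring the impact simulator); dropped log rows; mislabelled condition
rows.  Determinism: identical (plan, corruption, seed) triples give
byte-identical output.

Choices where reality was simplified, hence what a green test does *not*
establish: photodiode pulses are ideal rectangles (no luminance rise time,
no refresh-rate quantization of the flash itself beyond sample rounding);
key-press clicks are white-noise bursts (no keyboard acoustics or
mechanical double-strikes); response latencies in fixtures are fixed at
450 ms plus 120 ms between repeated presses (content checks are positional
and do not use them).  Pulse width defaults to one frame at 60 Hz
(16.7 ms), configurable, since real flash durations vary by display.
Event timing in fixtures is grid-aligned when plans use round durations at
integer sample rates, which is what makes the clean round-trip exactly
zero rather than merely sub-sample.

## Geometry

Angles use `2·atan(size/2d)` (degrees out, radians internal); eccentricity
applies the same construction to the fixation-to-center offset, reported
separately for horizontal and vertical.  The px↔cm conversion is computed
from both screen axes; disagreement above 2 % warns (measurement error or
non-square pixels).  No screen-tilt correction is applied for off-center
stimuli; such measurements are labelled small-tilt approximations in the
report, which is accurate within ~1 % up to ~10° eccentricity.

## Content and design validation

Content comparison is a per-field equality check of logged rows against
ground-truth annotations in the same schema, keyed by event index, with
per-condition coverage accounting (a condition = realized combination of
declared factor levels; unrealized combinations are listed, not
penalized).  Response validation compares the logged key sequence
positionally against the preplanned sequence; missing presses (including
the missing repeat of a deliberate double press) and unexpected extras
are mismatches, not errors.  Design rules supported: expected counts per
factor-level combination (must sum to the event count), maximum run
length per factor, optional per-block counts, and arbitrary user
predicates.  All violations are located by row.

## Corruption-impact simulator

**Measures.**  P1 trials are epochs (−200…500 ms at 1000 Hz) of a
two-component Gaussian-bump waveform plus white sensor noise (10 µV per
sample): an adjacent negativity (C1-like, −12.5 µV, 69 ms, σ 10 ms)
immediately before the measurement window, and the P1 (2 µV mean, 100 ms,
σ 12 ms).  The measured amplitude is the mean over 90–110 ms minus the
mean over −100–0 ms.  The condition difference loads on the P1 amplitude
and is scaled so that the *measured* variable has Cohen's d = θ exactly.
RT trials are Gaussian with SD 20.5 ms and standardized difference θ.

**Corruptions.**  Label shuffle: a random subset of round(p·N) trials has
its labels permuted within the subset (label multiset preserved); the
expected standardized difference attenuates by ≈ (1−p).  Onset jitter:
round(p·N) trials get a logged-onset error of ±magnitude with random
sign.  For RT the error adds to the measured RT (pure variance
inflation).  For P1 the epoch shifts against the waveform, which both
attenuates the condition difference (the P1 partially leaves the window)
and inflates variance (the adjacent negativity swings into the window for
one error sign) — this second mechanism is what lets large jitters kill
effects at small corrupted proportions.

**Statistic.**  Welch's unequal-variance two-sample t across trials
(hand-written five-line formula so the degenerate zero-variance case can
return 0 by convention; scipy is the independent oracle in tests).  Each
grid cell reports the mean t over Monte-Carlo replicates; the
significance boundary is the smallest grid proportion with mean t < 1.96.

**Exact reduced sampler.**  Because the measurement is linear in the white
noise, the measured amplitude of a trial is exactly (deterministic
window/baseline mean of the shifted template) + N(0, σ_m²) with
σ_m = noise_sd·√(1/n_window + 1/n_baseline).  The sweep engine samples
this reduced form by default — identical in distribution to full epoch
synthesis and ~500× faster; the full-waveform path is retained
(`waveform_fidelity=True`) and the two are equivalence-tested.

**Calibration.**  The free parameters — trials per condition for each
measure, RT SD, and the adjacent negativity's amplitude — are not
identified by the corruption models alone, so they were tuned *once* by
`scripts/calibrate_simulation.py` to place the five reference boundaries
at θ = 0.2 (P1 shuffle 20 %, RT shuffle 5 %, P1 16 ms jitter 15 %, P1
32 ms jitter 5 %, RT 16 ms jitter 15 %), then frozen: P1 280 and RT 206
trials/condition, RT SD 20.5 ms, C1 amplitude −12.5 µV.  The script
maximizes the worst-case two-sided margin (the cell before each boundary
must stay above 1.96, the boundary cell below), analytically for the
wide-margin constraints and by high-precision Monte-Carlo for the RT
jitter boundary, whose adjacent grid cells are separated by only ~0.03
t-units — that boundary is intrinsically the least stable and is why
boundary computations use ≥ 20 000 replicates per cell.  These values are
a *stated world*, not estimates of any particular lab's physiology.

## Numerical details and edge cases

- Sample SD uses n−1 everywhere; an n=1 series reports SD 0 with an
  explicit low-n flag.
- Pulse placement rounds times to the nearest sample; round-trip recovery
  is therefore exact on grid-aligned fixtures and within 1 sample
  otherwise.
- A recording that starts mid-pulse drops the orphan leading offset.
- Timing sections of the QA report warn above a configurable SD threshold
  (default 5 ms, "a few milliseconds" being the healthy range); content
  and design sections fail on any mismatch.
- Random streams: `numpy` Generator seeded per cell with the composite
  (seed, θ-index, magnitude-index, proportion-index), so sweeps are
  deterministic and cells independent.

## Known limitations

- The simulator's t is across trials of a single simulated experiment;
  across-subject designs, autocorrelated EEG noise, and non-Gaussian RT
  shapes (ex-Gaussian tails) are out of scope.
- The audio path detects onsets only; it cannot attribute presses to keys
  (content comes from the response plan, timing from the microphone).
- Trigger content is checked as code-vs-log equality; protocol-level
  trigger corruption (bit errors producing *valid* wrong codes on the
  same event) is indistinguishable from a mislog.
- The auto threshold assumes a bimodal trace; slow luminance drift across
  a long recording may require parsing in segments with local thresholds.
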