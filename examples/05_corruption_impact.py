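"""Map how label shuffling and onset jitter erode a true effect.

Runs the calibrated Monte-Carlo study at effect size theta = 0.2: for each
corrupted proportion of trials, many replicate experiments are simulated
and tested with Welch's t; the boundary is the smallest proportion that
pulls the mean t below the significance threshold of 1.96.  The RT
boundaries sit within ~0.02 t-units of the threshold, so they need more
replicates than the P1 ones for a stable answer.
"""
from eventqa import SimulationConfig, corruption_boundary, run_sweep, significance_boundary

for measure, corruption, mag in [
    ("P1", "shuffle", 0.0),
    ("RT", "shuffle", 0.0),
    ("P1", "jitter", 16.0),
    ("P1", "jitter", 32.0),
    ("RT", "jitter", 16.0),
]:
    reps = 5000 if measure == "P1" else 30000
    cfg = SimulationConfig(
        measure=measure, theta=0.2, corruption=corruption, reps=reps, seed=1
    )
    b = corruption_boundary(cfg, magnitude_ms=mag)
    label = f"{measure} {corruption}" + (f" {mag:.0f} ms" if mag else "")
    print(f"{label:18s} -> effect lost at {b:.0%} of trials")

# a small explicit sweep: the full mean-t surface for RT label shuffling
cfg = SimulationConfig(
    measure="RT", theta=0.2, corruption="shuffle", reps=2000,
    proportions=(0.02, 0.05, 0.10, 0.20, 0.40), seed=2,
)
sweep = run_sweep(cfg)
print("\nRT shuffle sweep (theta=0.2):")
for _, row in sweep.table.iterrows():
    flag = " <- below 1.96" if row.mean_t < sweep.threshold else ""
    print(f"  {row.proportion:4.0%} shuffled: mean t = {row.mean_t:5.2f}{flag}")
print(
    "\nEven a 5% labelling error rate destroys a theta=0.2 reaction-time"
    "\neffect at realistic trial counts - content QA is not optional."
)
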