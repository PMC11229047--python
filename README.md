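# gazesweep

Scanpath-efficiency analysis for head-mounted eye tracking in room-search
tasks.

Trained operators clear a room with a structured, persistent visual sweep —
near corner first, then systematically around the walls — while novices
scan erratically, doubling back over areas already searched.  `gazesweep`
is a reusable pipeline for quantifying that difference from raw gaze
traces: it filters 120 Hz angular gaze data, detects fixations and
saccades, scores scanpath efficiency against a 12-segment wall layout, and
runs the group × time statistics of a pre/post training experiment.  A
seeded synthetic-data generator with full ground truth makes every stage
testable without any recordings.

## What it computes

**Event detection.**  Gaze azimuth/elevation is despiked with a
three-frame median filter and smoothed with a second-order zero-lag
(forward–backward) Butterworth filter — 30 Hz cut-off for fixation
detection, 50 Hz for saccade detection.  Fixations are maximal sample
clusters within a 1° spatial tolerance lasting ≥ 100 ms (dispersion
algorithm).  Saccades are intervals where gaze acceleration exceeds
5 × the trial's median absolute acceleration, with onset/offset refined
to the flanking acceleration extrema.

**Scanpath metrics.**

- *Gaze transition entropy* — Shannon conditional entropy of
  AOI-to-AOI fixation transitions:
  `H = −Σᵢ p(i) Σ_{j≠i} p(j|i) log₂ p(j|i)` (bits).  Low entropy means a
  predictable, structured search; the maximum for 12 AOIs is
  log₂ 11 ≈ 3.459.
- *Saccadic anisotropy* — saccade direction θ = atan2(r_y, r_x) and the
  intersaccadic angle θ_d (wrapped change in direction between successive
  saccades).  Saccades with |θ_d| > 90° are *antipersistent* (the search
  doubled back); the metric is the percentage of antipersistent saccades.
- *Search rate* — number of fixations divided by their mean duration.
- *Time to fixate first target* — latency from room entry to the first
  gaze sample inside a target region.
- *Search order compliance* — whether a near-door corner was fixated
  before the back wall, as the trained drill prescribes.

**Statistics.**  Per metric, a 3 (group: feed-forward training, feed-back
training, control) × 2 (time: pre, post) split-plot ANCOVA with an
optional participant-pool covariate that is retained only when it relates
significantly to the dependent variable (p < .05), partial η² effect
sizes, and Bonferroni–Holm-corrected post-hoc comparisons (pairwise
between groups at each phase, paired pre/post within groups).

## Worked example

```python
import gazesweep as gs

layout = gs.default_room_layout()                      # 12 wall segments + targets
profile = gs.ScanProfile(sweep_persistence=0.9,        # mostly-orderly searcher
                         noise_sd=0.1, trial_duration=20.0)
recording, truth, _ = gs.simulate_trial(profile, layout, seed=42)

fixations, saccades = gs.detect_events(recording)      # filter + detect
fixations = gs.assign_aois(fixations, layout)
metrics = gs.compute_trial_metrics(fixations, saccades, layout,
                                   recording=recording)

print(f"fixations: {metrics.n_fixations}  (ground truth: {len(truth.fixations)})")
print(f"mean fixation duration: {metrics.mean_fixation_duration:.3f} s")
print(f"transition entropy: {metrics.entropy:.3f} bits")
print(f"antipersistent saccades: {metrics.pct_antipersistent:.1f} %")
```

prints

```
fixations: 61  (ground truth: 61)
mean fixation duration: 0.276 s
transition entropy: 1.002 bits
antipersistent saccades: 22.4 %
```

The detector recovers all 61 simulated fixations.  Because this searcher
sweeps persistently (persistence 0.9), the scanpath is predictable —
1.0 bits of transition entropy against a 3.46-bit maximum — and only 22 %
of saccades double back.  A fully erratic profile (persistence 0) scores
around 1.6–2 bits and ~97 % antipersistent saccades on the same seeds.

A full experiment runs the same way at cohort scale:

```python
design = gs.StudyDesign(n_per_group=(13, 13, 12), trials_per_phase=20,
                        effect_spec={"entropy": {("FFEMT", "post"): -0.4}})
table = gs.generate_study(design)                      # tidy participant × phase table
results = gs.analyze_study(table, covariate="pool")
print(gs.report(results)[0])
```

There is also a CLI (`gazesweep simulate / detect / metrics / stats / run`)
for working with gaze CSV files on disk.

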