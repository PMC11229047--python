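# Methods

This note documents the models, conventions and numerical choices behind
`gazesweep`, in the order the pipeline applies them.

## Coordinate frame and timing

Gaze is represented in 2D angular coordinates — azimuth and elevation in
degrees — on the unwrapped wall surface of the searched room.  The wall
loop is cut at the doorway, so azimuth runs from −180° (left of the door)
to +180° (right of the door) and the 12 ordered wall segments tile that
band; segment 1 is the first area left of the door, segment 12 the last
on the right.  All in-scope metrics (dispersion, saccade direction,
transition entropy) are defined in this plane.  Time is in seconds with
t = 0 at room entry; the generator stamps trial onset at entry, since
log-alignment conventions differ between tracking systems.

One consequence of unwrapping a closed surface: a gaze shift across the
doorway (e.g. segment 12 → segment 1) appears as a single large-amplitude
saccade.  The pipeline treats it like any other saccade.

## Filtering

Raw azimuth/elevation channels are filtered independently (the angular
ranges involved make channel coupling negligible):

1. **Three-frame median filter** — despikes single-sample glitches; the
   first and last samples pass through unchanged.
2. **Zero-lag Butterworth** — a second-order low-pass applied forward and
   backward (`scipy.signal.filtfilt`, odd-reflection padding).  The two
   passes cancel phase exactly and square the magnitude response of the
   underlying design.  A 30 Hz cut-off stream feeds fixation detection
   and a 50 Hz stream feeds saccade detection; both come from the same
   median-filtered input.

**Gap policy.**  Tracking-loss runs of ≤ 75 ms (`max_interp_s`) are
linearly interpolated; the limit is deliberately below the 100 ms minimum
fixation duration so interpolation can never fabricate a fixation.
Longer gaps split the trace into independently filtered segments, and
segments shorter than 12 samples (too short to hold any detectable event
and shorter than the filter's padding) are excluded.  Events never cross
gap boundaries.

## Event detection

**Fixations (dispersion algorithm, I-DT family).**  A fixation is a
maximal run of samples clustered within a 1° spatial tolerance that spans
at least 100 ms.  Two-stage clustering on the 30 Hz stream: the window
grows while every sample lies within 1° of the running centroid; the
boundaries are then extended outward over samples still within 1° of the
fixed final centroid, recovering edge samples blurred inward by the
low-pass filter.  Scanning resumes after each emitted event, so events
are disjoint.  "Dispersion of 1°" is read as a 1° tolerance radius around
the cluster centroid — the convention of the dispersion-toolbox family
this detector follows.  A range-based criterion ((max−min az) +
(max−min el) ≤ 1°) was evaluated and rejected: at realistic fixational
jitter (0.1–0.2° per channel) it splits genuine fixations, because the
two-channel range sum of even clipped noise regularly exceeds 1°.

The minimum-duration test uses the sample span: at 120 Hz a window must
cover ≥ 12 inter-sample intervals (exactly 100 ms).  Boundary
localisation is limited by the 30 Hz filter's transition smear to roughly
±1–2 samples, more for very large flanking saccades; mean duration error
on synthetic ground truth stays below one sample.

**Saccades (adaptive acceleration threshold).**  Gaze acceleration is the
magnitude of the second derivative of the 50 Hz-filtered position
(central differences).  Candidate events are runs where acceleration
exceeds 5 × the trial's median absolute acceleration — the median is
computed per trial over all valid samples, the natural unit when the
threshold's scope is not otherwise fixed.  Because a smooth saccade's
acceleration magnitude passes through zero at its velocity peak, runs
separated by < 30 ms are merged.  Onset and offset are then refined from
the signed acceleration projected onto the saccade's displacement
direction: its maximum (acceleration peak) marks onset, its minimum
(deceleration peak) marks offset — for a raised-cosine saccade these sit
exactly at the true boundaries.  Saccades displacing < 0.1° are discarded
(atan2 is numerically unstable at near-zero displacement).

Fixation/saccade reconciliation (truncating fixations at saccade
boundaries and re-testing the 100 ms minimum) is available but off by
default: the two detectors run on differently filtered streams and there
is no canonical way to privilege one over the other.

## Scanpath metrics

**Gaze transition entropy.**  With fixations labelled by the wall segment
containing their centroid, consecutive same-AOI fixations collapsed, and
unlabelled fixations dropped:

    H = − Σᵢ p(i) Σ_{j≠i} p(j|i) log₂ p(j|i)

where p(i) is the marginal source distribution of observed transitions
(row totals over total transitions) and p(j|i) the row-normalised
conditional, with 0·log 0 ≡ 0.  H is the transition-weighted conditional
Shannon entropy, non-negative and bounded by log₂(n−1).  Fewer than two
transitions give H = 0.  Two conventions worth stating: entropy is
computed as standard (non-negative) conditional entropy, and the
transition alphabet is the 12 wall segments only — target sub-regions are
assignable (`targets_first`) but excluded from the entropy alphabet by
default, since targets move between room configurations while the
segment frame is fixed.

**Anisotropy.**  Saccade direction θ = atan2(r_y, r_x) in degrees,
wrapped to (−180, 180] (0 rightward, 180 leftward, +90 up), computed from
detected saccade displacements, not fixation-centroid differences.  The
intersaccadic angle θ_d is the wrapped difference between successive
saccade directions.  |θ_d| ≤ 90° is persistent ("within 90° in either
direction", boundary inclusive); |θ_d| > 90° is antipersistent.  The
reported metric is 100 × (antipersistent count) / (number of θ_d values);
it is invariant under global rotation of all saccade directions and
under adding full turns to any direction.

**Search measures.**  Search rate = n_fixations / mean fixation duration.
Time to fixate first target scans valid samples from entry time for the
first gaze point inside any target polygon (None if never).  Search-order
compliance is TRUE iff the earliest fixation on a near-corner segment
precedes the earliest fixation on a back-wall segment; a trial with a
near-corner fixation and no back-wall fixation is compliant, a trial with
neither is not.  The compliance direction (corner before back wall, not
the reverse) follows the trained drill, which starts at the near corner;
aggregation reports the percentage of compliant trials.  Which segments
are "near corner" (default 1 and 12) and "back wall" (default 6 and 7) is
a property of the room layout and supplied per layout.

AOI assignment tests polygons in id order, so a centroid on a shared
boundary goes to the lower-numbered AOI.

## Statistics

Each metric's participant × phase table is analysed with a 3 (group) × 2
(time) split-plot model fit as two orthogonal strata: participant means
(pre+post)/2 for the between stratum (group effect, covariate test) and
change scores post−pre for the within stratum (time = intercept,
group × time = group term).  With a two-level within factor this equals
the classical mixed ANOVA exactly (verified against an independent
implementation and a textbook cell-means oracle), and no sphericity
correction arises.  Sums of squares are type-II by model comparison with
sum-to-zero group coding; with balanced cells and no covariate they
coincide with the classical decomposition.

The participant-pool covariate enters **both strata**, so retaining it
costs one denominator degree of freedom in every test — F(1, N−4) for
the within effects with three groups — matching the conventional ANCOVA
table for this design.  Retention is a pure rule: keep the covariate iff
its between-stratum p < .05, otherwise refit without it.  Effect sizes
are partial η² = SS_effect / (SS_effect + SS_error-of-stratum), labelled
explicitly since η² variants are often left ambiguous.

Post-hoc comparisons are emitted when the interaction p ≤ 0.06 by default
(`posthoc_band`), slightly above α so near-threshold interactions are
still explored: three pairwise independent-sample t-tests between groups
at each phase and three paired pre/post t-tests, Holm-corrected within
each of the three families.  `holm_adjust` is the standard step-down
procedure (via statsmodels), order-preserving and capped at 1.

## Synthetic data generator

The generator emulates what the analysis assumes about the signal, not
the visual content of the task.

**Scan structure.**  A trial is a walk over the 12 segments controlled by
`sweep_persistence` p: with probability p the walk continues to the
adjacent segment in the current sweep direction (wrapping past the door,
i.e. re-sweeping from segment 1 — the one deliberate large gaze shift of
an orderly search); with probability 1−p it reverses to a segment behind
the current gaze direction, at a geometrically distributed distance
(doubling back mostly revisits nearby, recently scanned areas).  p = 1
gives a monotone sweep (low entropy, few antipersistent saccades); p = 0
reverses every transition (≈100 % antipersistent, high entropy because
the reversal destination varies).  Fixation centroids are drawn near
segment centres (Gaussian, clipped to the central half of the segment) so
adjacent-segment saccades keep a dominantly horizontal direction.

**Kinematics and rendering.**  Fixation durations are Gaussian
(default mean 0.30 s, sd 0.10 s) floored at 0.12 s — one 120 Hz sample
interval above the 100 ms criterion, because an event exactly at the
threshold spans 12 sample intervals only when phase-aligned and is
otherwise undetectable in principle.  Saccades follow a raised-cosine
position profile; peak velocity is `saccade_peak_velocity_scale`
(default 35 /s) times amplitude, which makes every saccade's duration
π/(2·scale) ≈ 45 ms.  This linear peak-velocity law has no main-sequence
plateau, so very large gaze shifts are rendered faster than eye-only
physiology allows; the trade keeps transition edges crisp at 120 Hz and
ground-truth boundaries well defined (a saturating variant was evaluated
and produced second-long quasi-pursuit sweeps that no saccade detector
should be expected to segment).  Rendering samples at uniform 1/rate
spacing, adds per-sample Gaussian jitter clipped at ±2.5 sd (default
sd 0.1°, typical of a research-grade HMD tracker), and marks blink
intervals (Poisson, default 10/min, 150 ms) invalid rather than rendering
artefact positions.

**Study generation.**  The design mirrors the emulated experiment: three
groups (feed-forward training, feed-back training, control) with
13/13/12 complete participants by default, two phases, 20 trials per
phase, and a two-level participant pool assigned ~35/65.  Per-participant
skill blends the novice profile toward the expert profile (Gaussian
skill, identical distribution in every cell, so the null design is null
in expectation).  Injected effects are additive shifts on the
participant-phase aggregate of a named metric, hence realised exactly in
expectation.  Two paths exist: `method="scanpath"` simulates every
trial's ground-truth event list and computes metrics from it (and can
return rendered recordings for full-pipeline runs); `method="parametric"`
draws aggregated metrics from a Gaussian participant/trial model with
fixed per-metric baselines — used for statistical calibration studies
where thousands of replicates are needed.

**What the generator does not emulate** — and therefore what passing
tests do not establish about real recordings: head-pose and
vestibulo-ocular interaction, smooth pursuit of moving targets,
calibration drift and spatially varying tracker error, main-sequence
saccade kinematics, post-saccadic oscillations, and any correlation
between scan structure and task performance.  The performance outcomes
(failures to inhibit, time to shoot, hostiles cleared) are pass-through
fields drawn at plausible levels, not behaviourally linked to the gaze
simulation.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run at sizes chosen to give
stable statistics on a single CPU: 20-second trials at 120 Hz, 50 seeded
trials for detection recovery (fixational jitter 0.2°, the upper end of
the range the recovery claim covers), 2000 null replicates for the
type-I-error calibration at the 13/13/12 cell sizes, and 20 seed-paired
cohort comparisons for the expert/novice discrimination check.

## Known limitations

- Unwrapped-wall geometry makes cross-door gaze shifts single giant
  saccades; on real data a head-turn model would be preferable.
- The dispersion detector's boundary localisation is limited by the
  30 Hz filter smear (±1–2 samples); onset-sensitive latency measures
  inherit that uncertainty.
- The acceleration-threshold detector assumes trials where most samples
  are fixational; on saccade-dominated traces the median-based threshold
  rises and small saccades are missed.
- The ANCOVA treats the covariate as acting identically in both strata;
  no interaction between covariate and group or time is modelled.
- `time_to_first_target` uses raw valid samples, so a single noisy sample
  crossing a target polygon counts as an intersection.
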