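# Methods

## The assay and its coordinate conventions

The package models a four-quadrant optogenetic arena: a circular chamber
of radius 50 mm (10 cm diameter, 3 mm high) holding ~20 walking flies,
filmed at 30 frames/s.  Odorized or clean air enters at the four corners
and is withdrawn through a hole at the centre, so the local airflow points
inward everywhere and a fly facing *away* from the centre faces upwind.
Quadrant q spans polar angles `[phase + q·π/2, phase + (q+1)·π/2)` around
the centre; diagonal quadrants carry the same stimulus (odor A/B, or
lit/unlit), and `quadrant_phase` is a configuration parameter because the
boundary orientation relative to the inlets is hardware-specific.

All positions are in millimetres in arena-centred coordinates (x
rightward, y upward); angles are radians, counter-clockwise from +x.
Time intervals are half-open `[t0, t1)` and frame n covers
`[n/fps, (n+1)/fps)`, so no frame is counted in two adjacent epochs.
Tracking dropouts are kept as gaps: every differenced quantity (speed,
heading change, cumulative turning) is computed only over pairs of
consecutive frames and is missing wherever the window crosses a gap.
Interpolating through dropouts would manufacture data; with the observed
per-frame loss rates (a few percent) the missing-pair convention costs a
proportional amount of data and no bias.

## Stimulus schedules

Three named protocols are built exactly:

* `conditioning_v1` — train(A + 30 × 1 s LED pulses separated by 1 s gaps,
  over 60 s; then 60 s odor B unlit), 60 s test, train, train, test
  (480 s total).  The reciprocal partner of a run swaps the A/B roles via
  the quadrant labels, not the schedule.
* `activation_v1` — six cycles of 10 s LED on followed by 100 s off
  (660 s total).
* `light_preference_v1` — 30 s with one diagonal quadrant pair lit, 150 s
  recovery, 30 s with the opposite pair lit (210 s).

Concurrent stimulus streams live on separate channels (`odor`, `led`,
`assay`); epochs must be non-overlapping within a channel only, so the
1 s LED pulses legitimately sit inside a 60 s odor epoch.

## Per-frame kinematics

*Heading* is the tracker-supplied body orientation when present; otherwise
the direction of the frame-to-frame displacement, held unchanged while the
step is below 0.1 mm (at 30 fps that is 3 mm/s, well under walking speed),
so stationary jitter does not scramble the heading.  *Speed* is centroid
displacement × fps.  *Angular change* is the absolute wrapped heading
difference per frame, in [0, π]; a signed variant is available.
*cos(upwind)* is the dot product of the unit heading with the unit radial
outward vector, undefined within 0.5 mm of the centre (the suction hole).
*Cumulative turning* sums the absolute angular change over a trailing
window of five inter-frame changes (~167 ms at 30 fps); the window length
is a parameter.  Five *changes* rather than five *frames* keeps the
definition consistent with per-frame differencing; the distinction is one
frame and does not change any comparison in the package.

All of these are invariant under global rotation and translation of the
coordinate frame (verified to 1e-9 in the tests).

## Event metrics

For the activation assay, ON windows are the first 2 s of each 10 s LED
period and OFF windows the 2 s immediately after offset; parameter values
pool all flies, frames and trials.  `delta_dist_center` is the mean
distance-from-centre over the LED period minus the distance at the onset
frame, per fly and trial, then averaged; flies untracked at the onset
frame are excluded and counted.  The full-period window is the default
(the first-2 s variant is a flag), since the averaging window is otherwise
unspecified and the full period uses all the data.

The *return detector* anchors at the LED-offset position P0 (the position
the fly occupied when the stimulus ended): within the 15 s after offset
the fly must first be ≥ 10 mm from P0 and later ≤ 3 mm from it.  The
implementation is a linear scan over the running maximum of the distance
from P0; the test suite proves it equivalent to a brute-force scan over
all (t1, t2) pairs on 3000 simulated fly-trials.  Fly-trials whose track
covers less than 90% of the horizon (or that are untracked at the offset
frame) are excluded from the denominator and counted separately, since a
missed return cannot be distinguished from a tracking loss.

Z-scores standardize each screen parameter across the *line-level means*,
control included, with the sample SD (n−1).  Standardizing across lines
(rather than across flies within a line) is what makes the screen matrix
comparable across parameters with different units; columns with fewer than
two lines or zero variance are set missing with a warning.

## Preference indices

Quadrant assignment is by angular sector with a 0.5 mm hysteresis band:
within 0.5 mm of a boundary (which includes a small disc around the
centre) a fly keeps its previous quadrant, so boundary jitter does not
flicker the counts.  The per-frame preference index is
`(N_pos − N_neg)/N_total` with `N_total` the flies *tracked in that
frame* — using the loaded count instead would deflate the index whenever
the tracker drops a fly, which is a property of the tracking, not the
behavior.  Window scores average the frame-wise index over the stated
interval (last 30 s of the test for the memory score, last 5 s of each
lit test for the light score); an interval mean is what "during the last
30 s" describes, and an endpoint count is strictly noisier.  The memory
score of a biological replicate is the unweighted mean of the two
reciprocal runs; a single-run score is computed but flagged.  The
screening filter is strict (`|score| > 0.1`): a score exactly at the
threshold is not flagged, and ties are measure-zero in continuous scores.

## Rank statistics

Kruskal–Wallis uses mid-ranks and the standard tie correction
`1 − Σ(t³−t)/(N³−N)`; when every observation is identical the correction
degenerates and the test returns H = 0, p = 1 explicitly.  Dunn's
many-to-one comparisons use the pooled-rank variance
`N(N+1)/12 − Σ(t³−t)/(12(N−1))`, two-sided normal p-values, and
Bonferroni adjustment over the number of control comparisons by default
(the adjustment is parameterized; Bonferroni is the family used by the
common commercial implementations of Dunn's test).  The post-test is not
gated on the global test: both are always computed and reported, since
gating changes the error rate in ways screen users rarely intend.
Comparisons are many-to-one against the control line, not all-pairs.  The
statistical unit for memory scores is one reciprocal experiment.

## The synthetic cohort generator

Each fly is an independent discrete-time correlated random walk.  Per
frame the heading gains wrapped-normal noise with SD
`1/sqrt(turn_concentration)` and the fly advances
`max(0, Normal(base_speed, speed_sd))/fps`.  Defaults: 20 flies, 30 fps,
50 mm radius, base speed 10 mm/s (SD 3) — mid-range for walking flies in
this kind of arena — turn concentration 8 (heading SD ≈ 0.35 rad/frame,
giving a persistence length of a few body lengths), and 2% frame dropout
to emulate tracker losses.  Start positions are uniform over the inner
90% of the arena; per-fly random streams are split from the cohort seed
with a splitmix64 mix, so cohorts are byte-reproducible and flies
independent.

Four stimulus-coupled channels, all neutral by default, mirror the
phenotype classes the assay screens for:

| channel | parameter | acts during | target metric |
|---|---|---|---|
| speed modulation | `led_speed_multiplier` (default 1) | LED on | speed_ON |
| startle turning | `onset_turn_boost` (default 0; SD × (1+boost)) | first 2 s of LED | angular_ON / cum_turn_first2s |
| upwind drive | `offset_upwind_bias` (default 0; fraction of the angular error toward radial-outward applied per frame) | 2 s after offset | cos_upwind_OFF |
| dwell bias | `quadrant_bias` (default 0; in (−1, 1)) | test epochs | memory / light PI |

The dwell bias is a crossing-probability asymmetry: a step that would
carry the fly out of a favoured quadrant is rejected with probability
|bias|, the boundary acting as a semi-permeable wall that reflects the
heading.  At bias b the equilibrium density ratio between favoured and
unfavoured quadrants is ≈ 1/(1−b), so b = 0.5 produces PI ≈ 0.33 — the
scale of a strong conditioned preference in this assay — which is the
value the validation scenarios impose.  The demonstration effect sizes for
the other channels are `led_speed_multiplier` 0.5 (halved stimulus-period
speed), `onset_turn_boost` 2 (tripled onset heading noise) and
`offset_upwind_bias` 0.1 (an O(1 s) alignment time constant toward
upwind, giving post-offset cos(upwind) ≈ 0.5).

**Boundary handling.**  Wall crossings are resolved by *tangential
sliding*: the offending step is converted into an arc at the fly's
current radius, in the tangential direction matching its heading, and the
heading aligns with the slide.  This was a deliberate choice over a
specular bounce.  A specular reflection injects heading jumps of ~1.5 rad
at a rate proportional to walking speed, which couples the speed channel
to the measured turning metrics (a −1% shift in angular_ON under halved
LED speed, detectable at the replicate numbers used here); sliding
preserves the step length exactly and injects only noise-scale heading
changes, keeping the effect channels statistically orthogonal at their
target metrics.  Trajectories therefore remain strictly inside the arena
at all times.

**Residual couplings.**  Confined movement couples everything weakly:
e.g. slower flies meet the wall less often, which perturbs wall-adjacent
heading statistics and the distance-from-centre drift; the upwind pull
steers, so it raises angular_OFF as a side effect of its mechanism.
Channel specificity is therefore asserted on the four canonical target
metrics above (each channel moves its own and leaves the other three
within sampling error), not on every derived composite.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: odor plume structure within a quadrant,
fly–fly interactions (collisions, social aggregation), thigmotactic wall
preference, identity swaps between flies (dropout is independent per
frame), body-posture kinematics, and slow behavioral drift across the
session.  The generator validates the *measurement* pipeline, not fly
behavior.

## Validation problem sizes

The end-to-end suite uses: 500 simulated flies × 6 trials for the
return-detector oracle equivalence; 1000 null replicates (k = 5 groups of
10) for Kruskal–Wallis calibration; 200 seeded reciprocal-pair replicates
for the null memory-score centring and 100 for sign recovery under the
imposed bias; and 8 replicate cohorts of 20 flies per genotype for screen
phenotype recovery.  The memory-score replicates simulate the 60 s test
epoch directly (the score depends on no other epoch), which keeps the
calibration runs compact.  `scripts/acceptance.py` recomputes the same
quantities from scratch at these sizes.

## Numerical details

Angles wrap to (−π, π]; the absolute wrapped difference is ≤ π by
construction.  Epoch membership uses `t_start ≤ t < t_end` on exact frame
times `n/fps`.  The onset frame of an epoch is `floor(t_start·fps)` with a
1e-9 s guard against float rounding.  Degenerate inputs are handled
explicitly: zero-duration epochs slice to empty tables with a warning,
all-identical samples give H = 0/p = 1, constant z-score columns go
missing with a warning, empty Dunn groups are dropped with a warning, and
a frame with zero tracked flies has no preference index.  Headings are
preferred from the tracker; the displacement fallback makes the simulator
and minimal CSV fixtures analyzable without an orientation column.
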