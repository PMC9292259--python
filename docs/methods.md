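# Methods

## The modelling problem

A blindfolded navigator explores a real-sized invisible maze inside an
8 × 9 m room, receiving only discrete auditory feedback: a *hand beep*
when the reaching hand comes within 5 cm of a virtual wall, and a *head
beep* when the body itself does. Movement is summarized at 2 Hz by a
motion vector per 500 ms — a step size *d* (m) and a turning angle *θ*
(rad) of the torso centre of mass. Three models of this behaviour are
compared:

* **FB (feedback-only)** — the navigator is predicted to treat a wall as
  "ahead" exactly when the previous step produced a hand beep with the arm
  within ±45° of the previous heading, or a head beep.
* **MBr (map-resetting)** and **MBu (map-updating)** — the navigator
  maintains a probabilistic mental map and judges "wall ahead" from it;
  MBr starts every trial with a blank map, MBu inherits the map across the
  three repeated trials of a maze. On trial 1 the two are the same
  computation.

Each model partitions the steps of a trial into *wall* and *no-wall*
classes. Within each class, step sizes are modelled as Gamma(α, β) and
turning angles as von Mises(μ, κ) — eight free parameters per model,
estimated per participant × trial by maximum likelihood. Model fit is the
log-likelihood of the observed (d, θ) under the fitted parameters,
normalized by the number of steps so trials of different lengths are
comparable.

### Position uncertainty and the mental map

The navigator cannot see, so all models replace the measured motion
vector V\* with a noisy estimate V = V\* + |V\*| ε, ε ~ N(0, Σ) with
Σ = [[0.002, 0.0005], [0.0005, 0.002]] (m² per unit step length, applied
to the Cartesian displacement components). Position is dead-reckoned by
summing the estimates from the measured start, so the positional error is
a planar random walk whose variance grows linearly with step count. The
estimated hand position adds the measured hand–body offset to the
estimated body position.

The mental map is a pair of unnormalized evidence fields over the room,
each a uniform base (1/area) plus isotropic Gaussian components with
covariance 0.002·I m² (1-D marginal FWHM 2√(2 ln 2 · 0.002) ≈ 10.5 cm).
Per step: a hand beep appends a component at the estimated hand position
to the *wall* field; a silent step appends one at the estimated body
position to the *no-wall* field; a head-beep-only step changes nothing.
Because every criterion compares densities of the same field at different
locations, normalization cancels and the accumulation form is kept.

### Wall-ahead criteria

FB: hand beep with |bearing| ≤ 45° of the previous heading, or head beep,
evaluated on the feedback received before the step.

MBr/MBu: densities are probed every 2.5 cm along the previous heading over
5–20 cm ahead and at ±90° over 5–30 cm laterally. Wall is predicted ahead
iff (a) the maximum wall density over the ahead probes strictly exceeds
the wall density at the current estimated position *and* the maximum
no-wall density ahead is strictly below the no-wall density here, and (b)
on at least one lateral side the maximum no-wall density strictly exceeds
the no-wall density here *and* the maximum wall density there is strictly
below the wall density here. Strict inequalities make a never-updated
(uniform) map yield "no wall" everywhere. Whether (b) must hold on one or
both sides is genuinely ambiguous; both are implemented
(`lateral_rule="either_side"` default, `"both_sides"` available). A
dead-reckoned position that has drifted out of the room yields "no wall"
(no in-room evidence to compare).

Labels are predictive: the label of step *t* uses only information
available before the step. The first step of a trial, which has no
previous heading, is labelled no-wall.

### Parameter estimation

* Gamma MLE: Newton iterations on the profile score
  log α − ψ(α) = log x̄ − mean(log x), Minka-initialized; scale = x̄/α.
  Identical samples have no finite MLE and raise.
* von Mises MLE: location = circular mean; concentration from the Bessel
  ratio A(κ) = I₁(κ)/I₀(κ) = R̄, inverted by bisection on [10⁻⁸, 10⁸]
  (the ratio is computed with exponentially scaled Bessels, so it is
  stable at both ends). The spread is reported as a dispersion σ = 1/κ,
  keeping σ variance-like. Vanishing resultant (uniform) and unit
  resultant (identical angles) are flagged rather than fitted.
* Steps shorter than 0.1 mm are excluded from step-size fits and
  likelihoods: a wall-blocked walker can be exactly stationary and the
  Gamma support is d > 0. Turning-angle fits can optionally use |θ|
  (`abs_turn`, default off); the signedness of the published turning
  angles is not stated, so signed wrapped heading changes are the default.

### Model comparison

Per trial × metric (step, turn), participants provide paired scores for
the three models. A Friedman test (within-participant mid-ranks,
tie-corrected chi-square with 2 df; an exact rank-permutation null is used
for ≤ 8 units or on request) gates two-sided Wilcoxon signed-rank
post-hocs on the three model pairs, Bonferroni-corrected with family
size 3. The Wilcoxon null is exact for n ≤ 25 without ties, otherwise the
normal approximation with tie and continuity corrections. The MBr–MBu
contrast is skipped in trial 1 ("identical by definition"). The
navigator-style analysis repeats the whole block within the egocentric
and allocentric subgroups.

## The synthetic cohort generator

No recordings ship with this package; the generator is a first-class
component producing cohorts with known ground truth. Its defaults are the
study conditions: 16 participants split 8/8 into allocentric
(`map_update` policy) and egocentric (`map_reset`) navigators, up to four
catalogue mazes (straight/L/Z/U corridors, ≥ 0.8 m wide, in the 8 × 9 m
room), three trials per maze, 2 Hz stepping, and a 600-step cap (5 min of
task time); trials also end on crossing the exit segment.

The walker's kinematic ground truth uses Gamma(2.0, 0.033) walking steps
(mean 6.6 cm — the slow, careful pace reported for blind navigation) and
Gamma(1.5, 0.015) wall-examination steps (mean 2.25 cm), with von
Mises(0, 4) course-correction turns while walking and broad von
Mises(±0.4, 1.5) wobble while examining.

Behaviourally the walker alternates between **walking bouts** — ballistic
segments held on an internal course (vestibular stabilization), with
exploratory full-arm reaches on 35% of steps sweeping σ = 1.2 rad around
the walking direction — and **wall examinations**: on noticing a wall (a
beep it reacts to, or its own map criterion firing) it walks up to the
wall, then dwells there for a geometric number of steps (mean 8),
wobbling in place and patting the surface in reach–withdraw cycles (30%
of dwell steps touch). After a dwell it departs on the candidate course
with the most mapped open space (or a random one when the map is
uninformative) and does not re-engage for 10 steps. Reaction to beeps is
probabilistic — allocentric cohort members act on 45% of touches (they
trust their world-centred map), egocentric members on 85%.

Crucially, the walker is subject to the same epistemic limits as the
models: it dead-reckons with the stated noise law and builds its own
mental map in estimated coordinates. Its map policy is its navigator
style: `map_update` walkers keep the map across the trials of a maze,
`map_reset` walkers start blank each trial, `feedback_reactive` walkers
have no map at all.

Physical constraints: body steps are clipped 1 cm before wall contact and
a blocked walking step triggers a course change; the reaching hand stops
at the first wall along the arm; beeps are emitted from true geometry
(hand or torso within 5 cm of a wall). Ground-truth regime labels and all
generator parameters are recorded with each cohort for recovery tests.

An optional upsampler re-expands 2 Hz records into jittered 480 Hz marker
frames (several torso markers at zero-sum offsets, linear interpolation,
white jitter) solely to exercise the preprocessing chain (five-point
moving average, decimation with OR-reduced feedback flags, torso centre
of mass as the marker mean).

### What the generator does and does not emulate

It reproduces the paradigm's observable structure — corridor geometry,
sparse touch events, dwell-and-walk exploration, regime-dependent
kinematics, map-carrying across trials — with known parameters, so
estimator recovery and the qualitative model ordering can be tested
end-to-end. It does not emulate: 3-D kinematics or biomechanics, marker
dropout, purposive route planning beyond one-step map queries, fatigue or
memory decay, or individual parameter variation (all walkers share one
kinematic ground truth). Trials at default conditions are duration-limited
(the step cap binds; exits are rare), as in fixed-length exploration
studies, so the across-trial *speed-up* reported in related work is not
reproduced: on a short test corridor where exits do occur, map-carrying
walkers finish faster and more often than map-resetting walkers, but mean
duration is flat across trials. Passing tests therefore certify the
pipeline's correctness and the direction of the model contrasts on this
synthetic world, not quantitative agreement with human recordings.

## Numerical and reproducibility choices

* All lengths in metres, angles in radians, times in seconds internally;
  percentages/centimetres only at report boundaries.
* RNG streams derive from one master seed via `numpy` `SeedSequence`
  spawn keys per (participant, maze, trial). The three models share the
  trial's stream so that MBr and MBu are bit-identical on trial 1; a
  per-model stream would break that exact identity.
* Sub-millimetre steps inherit the previous heading (atan2 of a
  near-zero displacement is noise); turning angles are wrapped to
  (−π, π].
* The Gaussian-mixture density loop is numba-JIT compiled with a numpy
  fallback; geometry queries (point–segment distance, ray–segment
  intersection) are vectorized numpy validated against shapely in tests.
* Evaluation scale: the replicate battery uses 16-walker cohorts on the
  Z maze with 400-step trials and 50 replicates; recovery studies use
  n = 10⁴ samples × 100 seeds; Monte Carlo drift checks use 500 walks of
  100 steps. These sizes keep a full evaluation within minutes on one
  core while leaving the directional effects well resolved.

## Known limitations

* The map criterion is a conjunction of four strict density inequalities
  evaluated at a drifting estimated pose; its per-step output is
  sensitive to kernel-scale (≈ 5 cm) position differences. Consequently
  per-participant MBu−MBr likelihood differences on a single maze are
  small relative to their variability, and the Bonferroni-corrected
  Wilcoxon at n = 8 rarely resolves the allocentric-subgroup contrast
  that the full study (which pooled four mazes per participant) reported;
  the corresponding acceptance check documents this honestly rather than
  relaxing the test.
* Wall-label fractions of the map models on synthetic cohorts (~10–12%)
  sit far below the ~70% reported for human data, though the direction of
  the FB vs map-model contrast is reproduced. Matching the magnitude
  would require dwell behaviour far more extreme than the generator's
  defaults.
* The Friedman exact null enumerates within-unit rank permutations by
  column-sum convolution; it assumes exchangeability within units, as the
  test itself does.
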