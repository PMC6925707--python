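# Methods

This note documents the models implemented in `neuroarm`, the defaults they
ship with, the numerical choices behind them, and what the synthetic data
do and do not establish.

## Conformal geometric algebra kernel (`neuroarm.cga`)

Multivectors are dense vectors of 32 coefficients over the null blade basis
generated by (e0, e1, e2, e3, e∞), ordered by bitmask with e0 = bit 0 and
e∞ = bit 4.  The metric is e1² = e2² = e3² = 1, e0² = e∞² = 0,
e0·e∞ = −1.  Product tables are derived once at import from the diagonal
basis (e1, e2, e3, e+, e−) with signature (+,+,+,+,−), using
e0 = (e− − e+)/2 and e∞ = e− + e+; the geometric-product tensor is then
conjugated into the null basis, and the inner/outer products are its
grade-|r−s| / grade-(r+s) restrictions blade pair by blade pair.  This
makes the kernel exact up to floating point for arbitrary multivectors,
with each product a single 32×32×32 `einsum` (microseconds).

**Representations.**  Entities carry a `standard`/`dual` tag.  Standard
(inner-product null space) forms: spheres and planes are grade 1, circles
and lines grade 2, point pairs grade 3; a point X lies on entity A iff
X⌋A = 0.  Dual (outer-product) forms are wedges of embedded points (a line
additionally wedges e∞); containment is X∧A = 0.  Duality multiplies by
the inverse pseudoscalar Ic⁻¹ = e0∧e3∧e2∧e1∧e∞; dual∘dual = −identity on
every blade (verified by enumeration, not assumed).  The **meet** of two
standard-form entities is simply their wedge — algebraically identical to
the dual-of-wedge-of-duals formulation, without the two extra dual calls.

**Point-pair extraction** uses P± = (Pp ± √(Pp²)) / (−e∞⌋Pp) on the dual
(grade-2) pair.  The two roots are returned ordered: larger z coefficient
first, ties broken by larger x.  This fixed order is what makes the elbow
branch choice deterministic downstream.

**Numerical conventions.**  Entities are kept unnormalized (all the
constructions are scale-covariant); comparisons normalize by the
largest-magnitude coefficient.  A meet whose squared radius is below
−1e−10 × (entity scale)² is flagged imaginary; the band around zero covers
tangency.  `plane_normal` uses (π∧e∞)⌋e0 on the standard form with the
overall sign fixed so the base plane e0∧e1∧e2∧e∞ has normal +e3; this one
constant anchors every downstream angle sign.  `oriented_angle` computes
atan2(−⟨(α∧β)N̂⟩₀, α·β), which is the four-quadrant angle from α to β
counter-clockwise with respect to the unit orientation bivector N̂;
reversing N̂ negates the angle.

## Inverse kinematics (`neuroarm.kinematics`)

The arm is modeled by its first three placement joints: base rotation J0
(at the origin), shoulder J2 and elbow J3; the wrist joints do not affect
effector position and are out of scope.  J1 is fixed at (0, 0, 36) mm.
The construction, entirely by meets:

1. effector plane π_e = e0∧e3∧X_e∧e∞ (fails with a "singular azimuth"
   error when the target sits on the z-axis);
2. x_h: the sphere of radius La about the origin ∧ π_e → circle, ∧ base
   plane → point pair; the branch on the target's side is taken;
3. J2: sphere(x1, L2) ∧ sphere(x_h, Lb) → circle, ∧ π_e → point pair;
   the **upper** (higher-z) point is always taken;
4. J3: sphere(J2, L3) ∧ sphere(x_e, L4) ∧ π_e; the `branch` flag picks the
   higher-z (elbow-up, default) or lower-z member.

θ0 is the oriented angle from e2 to the π_e normal in the e1∧e2 plane
(equal to the target's azimuth from +x); θ2 and θ3 are oriented angles
between consecutive link directions in the bivector û∧e3 (û = horizontal
unit vector toward the target), so flexion below the shoulder line is
negative.  The tangent (straight-arm) elbow case is handled directly,
since the meet degenerates there.

**Default geometry.**  Only three dimensions of the physical arm are
published: the J1 height (36 mm), the base height above the table (49 mm)
and the home position [0, 155.5, 284.3] mm.  The shipped defaults —
La = 30, Lb = 150, L3 = 185, L4 = 180 mm, with L2 = √(La² + (Lb−z1)²)
derived so that (La, Lb) are exactly the horizontal/vertical components of
the constant J0→J2 offset — are a documented desk-scale approximation
chosen once so that the home position and the table-plane pick-and-place
zone (z = −49 mm, y up to ≈ 310 mm) are reachable.  Every dimension is
configuration, not a constant.

**Forward kinematics** is deliberately *not* CGA: it reconstructs the chain
by 2-D rotations in the vertical plane at azimuth θ0, using the same fixed
in-plane shoulder position and angle conventions.  It exists as the
independent oracle; FK∘IK agrees to ≤ 1e−6 mm over the working envelope
(both elbow branches).  FK assumes the upper shoulder solution, matching
the solver.

## Vision (`neuroarm.vision`)

Color segmentation is HSV windowing (hue window, wrap-around supported for
red, minimum saturation/value), connected components via scikit-image,
minimum blob area 50 px, centroid = value-weighted first moment of the
largest component.  The homography is a Hartley-normalized DLT solved by
SVD — exact on 4 correspondences; for the minimal 4-point case any 3
collinear points (source or destination) are rejected outright, matching
the stated precondition.  The marker world coordinates are the four fixed
centroids {15,385}² mm of a 400×400 mm plane.

Table→robot frame: the composition (translate by (−200, −400), rotate π,
flip x) collapses to (x, y) → (x − 200, 400 − y), the unique order placing
the robot at the origin with x ∈ [−200, 200] and y ∈ [0, 400] mm.  It is an
isometry, so millimeter errors are preserved.

Raw image pixels are mapped directly to table millimeters by one
homography (no intermediate warped image); the warped view exists only for
display.  K, R, t are never individually estimated.

## EEG pipeline (`neuroarm.bci`)

Conditioning: surface Laplacian (channel minus the mean of its montage
neighbors; the 19-channel neighbor table ships as configuration), 60-Hz
notch, 4th-order Butterworth band-pass — all zero-phase
(forward-backward), so stimulus-locked latencies are not shifted.

Features: per-epoch band powers in 2-Hz bins over 1–69 Hz, estimated by
Welch periodograms (1-s segments).  The r² map is the squared
point-biserial correlation between per-epoch bin power and the binary
condition label; feature selection takes the top-k cells of the
element-wise max over the three pairwise maps (k = 4 by default, matching
the 3–5 features per session typical of such systems), merging adjacent
selected bins on a channel into one band, ties broken by channel order
then frequency.

Classification: three pairwise LDAs (left-vs-right imagery, each vs rest)
with closed-form weights w = Σ_pooled⁻¹(µ₁−µ₀), midpoint threshold, and a
trace-scaled ridge when the pooled covariance is ill-conditioned
(condition number > 1e8).  Discriminants are trained on subepoch samples.
A 4-s epoch is split into floor((4−2)/0.0625)+1 = 33 overlapping 2-s
subepochs (0.0625-s stride); each pairwise model takes the mode over its
subepoch decisions (ties to the pair's first-listed class); the epoch
label is the class named by ≥ 2 of the 3 models, otherwise `reject`.
Controllers treat `reject` as rest — a self-paced controller must act, and
rest is the safe action.  The subepoch *count is derived*, never
hard-coded: window and stride are the protocol's parameters, and any
stated count inconsistent with them is ignored by construction.  Band
power enters LDA untransformed (no log), a documented choice.

Session scoring: cued and uncued goal-selection performance is percent
agreement between instructed/intended and classified stimulus types;
uncued process-control performance is the percent of stimuli whose
resulting action reduced the effector–target distance *or* completed an
axis change at a moment when no move on the current axis could reduce it
(the disjunctive reading of the protocol's success wording; configurable
via the step-outcome records).

Reported training accuracy is leave-one-trial-out cross-validated with the
feature selection nested inside each fold; selecting features on the full
session before cross-validation inflates null-data accuracy well above
chance (selection leakage), which the nested procedure avoids.

## Task controllers (`neuroarm.control`)

Process control holds a (position, axis, pending-rest) state: ±10 mm per
left/right-imagery classification on the active axis, rest holds, two
consecutive rests cycle y→z→x→y.  Any movement or completed axis change
clears the pending-rest latch (prevents runaway cycling on rest streaks).
Moves leaving the reachable workspace are refused with a flag, position
unchanged.  Goal selection maps right-hand imagery to the target with the
greater robot-frame x, left to the smaller (ties: first in detection
order), rest to hold; the planner emits hover → grasp → lift → hover →
release → home with 50 mm hover clearance and grasp height at the disk top
(table − 49 mm + 6 mm), running full IK on every waypoint and failing
loudly with the first infeasible waypoint's name.

## P300 statistics (`neuroarm.p300`)

Per trial: 1-s epochs (−200 to +800 ms around each stimulus) averaged,
baseline-corrected by the prestimulus mean (switchable), band-passed
1–10 Hz zero-phase, then amplitude = the *window maximum* (most positive
value, not a local-peak search — robust at low SNR) in 200–500 ms and
latency = its time.  A flat signal reports amplitude 0 at the first window
sample by convention; the window is inclusive at 500 ms.  ANOVA: classical
balanced fixed-effects decompositions (one-way and two-way with
interaction), p from the exact F distribution, no multiple-comparison
correction.  The two-way layout is 5 trial repetitions × 3 channels
(O1, O2, Pz) × 3 session replicates.

## Synthetic data (`neuroarm.synth`)

The generators are pure functions of (spec, params, seed) and define the
study conditions:

- **Protocols**: 15-s baseline; 2-s prestimulus cue (3 s for the
  goal-selection protocols, whose cue includes a 1-s tone); 4-s stimuli;
  interstimulus gaps uniform in 2–4 s (27–29 s for goal selection, during
  which the manipulation runs).  Counts: training 30 stimuli (10 per
  class), cued 15 (5 per class), uncued process control 20, uncued goal
  selection 15.  Class order is a seeded shuffle with exact counts.
- **EEG**: pink (1/f-amplitude) background noise, RMS 5 µV per channel;
  a 10-Hz mu rhythm of 10 µV at C3 and C4 whose amplitude is scaled by
  √(1−erd_depth) at the channel contralateral to the imagined hand
  (right→C3, left→C4) for the full 4-s stimulus with 250-ms raised-cosine
  ramps (the ramps avoid filter edge artifacts); erd_depth defaults to
  0.5.  No occipital alpha or artifact processes are simulated.
- **P300**: a positive deflection of 60-ms FWHM at O1/O2/Pz after every
  stimulus onset, amplitude and latency linear in the trial-repetition
  index.  The deflection is band-limited to 1–10 Hz and normalized so
  that the standard ERP band-pass applied at extraction reproduces the
  stated peak amplitude — i.e. the amplitude parameter is defined on the
  measurement scale, which is the only self-consistent convention when
  the extraction pipeline itself filters.
- **Scenes**: the 400×400 mm plane rendered through a fixed ground-truth
  projective camera (oblique view tilted ≈ 35° from vertical, placed far
  enough that the perspective bias of large sticker centroids stays below
  half a pixel), by inverse-mapping every pixel; additive Gaussian pixel
  noise on the 0–1 scale; ground truth records every centroid in image,
  table and robot coordinates.

For online (uncued) simulation, where each intent is decided only after
the previous stimulus was classified, recordings are assembled block by
block (`gen_stimulus_block`); pink-noise continuity across block
boundaries is not preserved, which affects nothing stimulus-locked.

**What passing tests show — and do not.**  The synthetic EEG is stationary,
artifact-free and has a single planted effect per mechanism, so classifier
accuracies here bound the pipeline's correctness, not its performance on
human EEG (where non-stationarity, eye/muscle artifacts and feature drift
dominate — real sessions in this paradigm sit at 56–78 % training
accuracy, far from the 100 % the clean generator allows).  Likewise the
camera model has no lens distortion, motion blur or lighting variation.

## Session drivers (`neuroarm.app`)

A scripted greedy policy stands in for the volunteer in process control
(intend the command that most reduces target distance, rest when the
active axis cannot); goal-selection intents are seeded random.  Each
intent is synthesized, classified with a previously trained consensus
classifier, and executed by the controller; P300 features are extracted
per trial repetition and pooled across sessions into the ANOVA layout.
Reports are reproducible JSON given (params, seed).

## Problem sizes

The shipped tests and the acceptance script use: 500 IK targets × 2
branches; 1000 random sphere pairs; full 5-repetition training sessions
(150 epochs) for the planted-effect accuracy; 20 seeds × 2-repetition
sessions for the null-accuracy check; 1000 null datasets for two-way ANOVA
calibration; 3-repetition uncued sessions.  These sizes are the package's
documented desk-scale defaults; all are parameters.

## Known limitations

- FK is undefined for the lower shoulder branch (the solver never emits it).
- The workspace check inside the process controller runs a full IK solve
  per step; fine at ±10 mm step rates, wasteful for trajectory streaming.
- The r² feature selector is univariate; correlated features (e.g. C3/Cz
  after the Laplacian) can enter together.
- No EDF/BDF reader: recordings are delimited matrices + JSON sidecars.
- Serialization of classifiers keeps raw weights; retraining is cheap and
  preferred over versioning them.
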