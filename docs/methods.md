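# Methods

## Scope and data model

All session data live on a 50 Hz master clock (the sacrum IMU). Streams are
stored with explicit timestamps; EMG devices record raw signals at ≥ 500 Hz
(simulator default 1000 Hz) on their own clock and are shifted onto the
master clock by the tap-marker synchronization. Units are SI throughout
(m, kg, s, rad, N·m); EMG amplitudes are in arbitrary units because the
estimator standardizes its inputs, so channel gain cancels. Streams must be
gap-free — a dropped sample is a validation error, mirroring the exclusion
of trials with acquisition errors in field practice.

## Linked-segment model

The upper body is a rigid chain rooted at the L5/S1 joint center: trunk,
head+neck (rigidly attached to the trunk — the sensor layout has no head
sensor), two upper arms and two forearm+hand segments. Segment parameters
scale linearly with stature and body mass from a standard adult
anthropometric table (mass fractions 0.497 / 0.081 / 0.028×2 / 0.022×2,
totalling 0.678 of body mass; lengths 0.288 / 0.182 / 0.186 / 0.254 of
stature; COM and radius-of-gyration fractions alongside, all named
constants in `lumbarload.lsm.ANTHROPOMETRY` and overridable by constructing
a custom `BodyModel`).

The net moment transmitted at L5/S1 follows from the Newton–Euler balance
about the joint:

    M = Σᵢ rᵢ × mᵢ(aᵢ − g) + R Iᵢ Rᵀ αᵢ + ωᵢ × (R Iᵢ Rᵀ ωᵢ)  (+ load term)

Segment positions are reconstructed from the calibrated orientations and
segment lengths; COM accelerations are transferred from each sensor's
specific-force channel across its rigid body (`a_com = a_s + α×r + ω×(ω×r)`).
Angular accelerations come from central differences of the angular velocity
after the same zero-phase 3 Hz smoothing used for EMG envelopes, which
suppresses differentiation noise. The handheld load is a point mass at a
trunk-frame offset from mid-hands, with kinematics derived from the hand
(forearm) chain. With `use_linacc=False` (for uncontrolled environments
where accelerometry is unreliable) all acceleration terms are dropped,
leaving the quasi-static gravitational moment.

**Sign convention.** Reported components use the clinical per-axis
convention — Mx positive for lateroflexion to the left, My positive for
forward flexion, Mz positive for rotation to the left — expressed in the
trunk anatomical frame. These positive directions do not form a
right-handed triple; internally the moment is computed in a right-handed
frame (x anterior, y left, z cranial) and the mediolateral component is
negated for reporting. The expression frame (trunk vs global) is a
convention choice; the moment norm is frame-invariant.

## Sensor-to-segment calibration

Gravity during quiet neutral stance (samples with near-1 g specific force
and rates below 0.3 rad/s; this also rejects the tap transient) gives the
segment longitudinal axis in sensor coordinates. The first principal
direction of the angular-velocity samples above 0.3 rad/s during the
sagittal functional movement (trunk bending for sternum/sacrum, shoulder
flexion for the arm sensors) gives the mediolateral axis, signed by the
initial movement direction; Gram–Schmidt completes the triad keeping the
gravity axis exact. All five repetitions are pooled rather than averaged
per repetition — more robust at realistic noise. A principal rotation axis
within 15° of gravity (e.g. a pure twist offered as the sagittal movement)
is rejected as degenerate. Recovery accuracy at default noise: mounting
rotations up to 20° are recovered within 2° (verified over 20 seeds); the
45° lateroflexion/rotation trials are accepted as input but unused.

## EMG amplitude and synchronization

Envelopes are full-wave rectified raw signals, low-pass filtered with a
2nd-order zero-phase Butterworth at 3 Hz (a conventional envelope bandwidth
for trunk-load work; configurable, must stay below the 25 Hz Nyquist of the
50 Hz grid), then linearly interpolated onto the master grid — the envelope
is band-limited far below the grid Nyquist, so linear interpolation is
adequate. Tap markers are detected fully automatically as the
highest-prominence transient in the pre-trial window, with the prominence
ratio to the runner-up as a confidence score (must exceed 1); a manual
cursor step would not be testable. The offset is the median EMG marker time
minus the sacrum accelerometer marker time; envelopes are re-gridded after
shifting. Synchronization error at default noise stays well below 0.05 s
for injected offsets up to ±2 s.

## ANN estimator

Inputs (16): four EMG envelopes plus 3D angular velocity and 3D specific
force from the sternum and sacrum sensors only. Orientation quaternions are
excluded: inclination is already in the accelerometer channels, and
magnetometer-aided headings are unreliable indoors. Architecture is fixed:
one hidden layer of 31 sigmoid units, linear 3-unit output. Training is
per subject and per session, full-batch L-BFGS on standardized features and
targets (standardization is needed to control sigmoid saturation; the
optimizer and initialization are free choices since only the architecture
and stopping rule are fixed). The run stops as soon as the summed per-axis
training RMSE drops below 10 Nm (checked every 200 epochs) or at
`max_epochs` (default 2000); up to 3 seeded restarts keep the best model if
the criterion is missed. The stopping RMSE is computed on the training set —
the method trains to a fit criterion, not with a validation split. Phase-2
evaluation trains on the 0 and 10 kg trials and scores the held-out 6 kg
trials; the work-task network is trained afresh on all three loads.

## Statistics

Pearson r bands: weak < 0.5 ≤ moderate < 0.7 ≤ good < 0.9 ≤ very good.
Task descriptives are the mean, peak (max) and within-trial sample SD
(n − 1) of ‖M‖. Paired contrasts (heavy − light, dynamic − static) are
gated by a Shapiro–Wilk test on the paired differences: normal
(p > 0.05) → paired t-test, otherwise Wilcoxon signed-rank; the gate
p-value is recorded so either reading can be audited. Relative differences
are reported both as the mean of per-subject percentage differences and as
100·MD/mean(reference), which differ in general. Direction splits partition
samples by the sign of the chosen component (exact zeros belong to neither
side; an empty side is reported absent, not zero); the nonnegative norm
channel is split by the sign of the per-sample dominant component, or by an
explicitly chosen axis. Task selection: light/heavy are the extreme
checklist ranks (ties broken by Borg, then trial order); a task is static
when ≥ 4 s windows of unchanged lumbar inclination (< 5° excursion) cover
at least half the trial, and dynamic when it is a large-excursion (≥ 30°)
lifting task.

## Simulator

The simulator emulates the three-phase protocol: phase 1, the functional
calibration set (five repetitions per movement, raised-cosine angle
profiles with 4 s periods, preceded by a 5 s neutral window containing the
tap at 2.5 s and followed by 3 s of stance); phase 2, bending /
lateroflexion / rotation under 0, 6 and 10 kg (3 repetitions × 4 s — the
0+10 kg training set is 6000 samples, the scale at which the estimator is
meant to operate); phase 3, work-task archetypes — a light continuous sway
(12°), a static 30° hold (12 s), and a combined heavy-and-dynamic lift
cycle (55°, 8 kg) reflecting how heavy and dynamic tasks coincide in field
checklists (splittable via separate `MotionSpec`s). Work tasks carry
checklist ranks (light 1, static 3–4, heavy/dynamic 5) and Borg CR-10
scores drawn from N(0.9, 0.8), N(3.8, 1.6) and N(6.0, 2.0) truncated to
[0, 10].

Kinematics: single-axis raised-cosine lumbar profiles with a lumbo-pelvic
rhythm (the pelvis takes 0.2–0.33 of the movement, so the sacrum sensor
moves realistically); arms hang gravity-aligned except in the shoulder
movements; angular velocities are analytic derivatives of the orientation
tracks and specific forces are consistent with the sensor-site trajectories
plus gravity (g = 9.81 m/s², IMU specific-force convention). Ground-truth
moments use the same mechanics as the supervised targets, applied to the
noise-free, perfectly calibrated streams.

Sensors: fixed per-session mounting rotations (drawn up to 10° by default),
additive Gaussian gyro (0.01 rad/s) and accelerometer (0.05 m/s²) noise.
EMG is an amplitude-modulated zero-mean Gaussian carrier whose
rectified-smoothed envelope recovers the modulation; the noise-free
envelope is linear in the moment with half-wave rectification,
`gain·max(0, a·My + b·Mx + c·Mz) + baseline`, with side-signed (b, c)
encoding the bilateral asymmetry of the trunk extensors for lateroflexion
and twist, plus cross-talk mixing (5%) and additive noise (SNR ≈ 10
against a typical envelope). The EMG device clock offset defaults to a
U(−0.5, 0.5) s draw per session.

**What the simulator does not model** — and hence what passing tests do not
show about real data: muscle physiology (activation dynamics,
force–length/velocity, fatigue), co-contraction (axial moments during the
rotation trials are therefore only a few Nm, which makes the rotation-axis
correlation the weakest of the three, as it also was in field data),
soft-tissue artifact, magnetic disturbance, ECG contamination, and
inter-subject variability in EMG–moment gains beyond the configurable
coefficients.

## Numerical choices and degenerate inputs

Quaternions are scalar-first, canonicalized to w ≥ 0 on output; vector
channels re-expressed by rotation preserve norms to 1e−9. Double
differentiation of positions uses `np.gradient` (second-order interior);
profiles start and end at rest so boundary effects vanish. Zero-variance
channels make Pearson r undefined — reported as NaN, never 0. Zero-variance
paired differences give p = 1 with an exact MD. Session CSVs are written
with 17 significant digits so write → read → write is byte-identical.

## Problem sizes

Defaults were chosen as the realistic session scale for this protocol:
full sessions of 18 trials (≈ 6.5 min of 50 Hz data, ≈ 400 k raw EMG
samples), 6000-sample training sets, 20-seed recovery suites and 50-seed
synchronization sweeps. The acceptance script runs the full chain at these
sizes.

## Known limitations

* The EMG forward model is the minimal linear-plus-noise structure under
  which a memoryless network can recover moments; real EMG–moment mappings
  are nonlinear and history-dependent, so simulator agreement values are
  optimistic upper bounds.
* Work-task archetypes are parameterized from qualitative task
  descriptions, not reconstructions of specific jobs; cohort-level
  magnitudes (e.g. task means) are not calibrated to any recorded cohort.
* The L5/S1 expression frame (trunk-fixed) is a convention; published
  field values may use a different frame, which affects per-axis values
  but not ‖M‖.
* Head-trunk rigidity and straight elbows are simplifications; they bias
  static moments by at most a few Nm at the modeled postures.
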