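# lumbarload

Ambulatory estimation of the lumbar load — the 3D net moment about the
L5/S1 intervertebral joint — for physically active workers, from wearable
sensors only: six inertial measurement units (sternum, sacrum, both upper
and lower arms) and four bipolar trunk sEMG channels (longissimus thoracis
at L1 and iliocostalis lumborum at L2–L3, bilaterally). It is aimed at
biomechanists and ergonomists who need objective lumbar-load exposure
measures during real work, where force plates and optical motion capture
are unavailable.

## Method

The package implements a per-session supervised chain:

1. **Sensor-to-segment calibration.** Functional movements (90° trunk
   bending, 45° lateroflexion, 45° rotation, 45° shoulder flexion, 90°
   abduction, five repetitions each, plus neutral stance) identify the fixed
   rotation from each sensor casing to its body-segment anatomical frame:
   gravity during quiet stance gives the longitudinal axis, the principal
   angular-velocity direction of the sagittal movement gives the
   mediolateral axis.
2. **Signal conditioning.** EMG amplitude envelopes by full-wave
   rectification and zero-phase low-pass smoothing (3 Hz), interpolated to
   the common 50 Hz grid; EMG and IMU clocks aligned from tap markers
   recorded before the measurement.
3. **Linked-segment model (LSM).** A top-down Newton–Euler balance over
   trunk, head+neck, arms and the known handheld load, scaled to the
   subject's stature and body mass, yields the net moment at L5/S1:
   `M = Σᵢ rᵢ × mᵢ(aᵢ − g) + Iᵢαᵢ + ωᵢ × Iᵢωᵢ`. Components follow the
   clinical sign convention: Mx + for lateroflexion to the left, My + for
   forward flexion, Mz + for rotation to the left.
4. **ANN estimator.** A feed-forward network with 16 inputs (4 EMG
   envelopes + sternum and sacrum angular velocity and linear acceleration
   — orientations deliberately excluded), 31 sigmoid hidden units and 3
   linear outputs is trained per subject and session against LSM targets
   from known-load trials (0 and 10 kg), to the fixed criterion
   `RMSE Mx + RMSE My + RMSE Mz < 10 Nm`, and evaluated on held-out 6 kg
   trials.
5. **Discriminant validity.** Task descriptives (mean/peak/SD of ‖M‖),
   light-vs-heavy and static-vs-dynamic paired contrasts with a
   Shapiro–Wilk-gated paired t-test / Wilcoxon choice, and direction-split
   (sign-partitioned) per-axis analyses, reported as CSV tables.

No recordings ship with the package; a forward simulator
(`lumbarload.simulate`) generates complete three-phase sessions —
ground-truth moments, IMU streams with mounting misalignment and noise,
amplitude-modulated EMG, tap markers, Borg CR-10 ratings — so the entire
chain is testable end to end.

## Worked example

```python
from lumbarload import MomentEstimator, compare_curves
from lumbarload.simulate import simulate_session
from lumbarload.pipeline import prepare_session
from lumbarload.lsm import scale_body_model, lsm_net_moment, LoadSpec
from lumbarload.ann import build_feature_matrix

session = prepare_session(simulate_session(seed=1))   # sync + calibrate
body = scale_body_model(session.subject)
train_ids = [t.id for t in session.load_trials((0.0, 10.0))]
results = MomentEstimator.from_session(session, train_ids, body).fit(seed=42)
print(results.summary())

trial = next(t for t in session.load_trials((6.0,)) if t.movement == "bending")
features = build_feature_matrix(session, [trial.id])
agreement = compare_curves(results.predict(features),
                           lsm_net_moment(trial.immu, body, LoadSpec(mass=6.0)))
print(f"hold-out 6 kg bending: r(My) = {agreement.r['y']:.3f}")
```

prints

```
L5/S1 net-moment ANN estimator
==============================================
architecture      16 -> 31 (sigmoid) -> 3 (linear)
training samples  6000
epochs            200
seed              42
converged         True (summed RMSE 4.78 Nm, criterion < 10 Nm)
----------------------------------------------
axis       RMSE [Nm]        r
Mx           1.44        0.999
My           3.03        0.998
Mz           0.30        0.979

hold-out 6 kg bending: r(My) = 0.997
```

The summed training RMSE of 4.78 Nm meets the < 10 Nm acceptance rule, and
the network trained only on 0 and 10 kg loads generalizes to the unseen
6 kg bending trial with a very good correlation on the flexion axis.
`results.plot()` draws the three-axis curves against the LSM targets.

A command-line interface covers the same chain stage by stage:

```sh
lumbarload simulate --seed 1 --out session/
lumbarload sync --session session/
lumbarload calibrate --session session/
lumbarload train --session session/ --masses 0,10 --out model.json
lumbarload report --subjects 3 --seed 0 --out report/
```

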