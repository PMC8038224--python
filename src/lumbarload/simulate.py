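"""Forward simulator for full measurement sessions.

Generates physiologically plausible upper-body kinematics (raised-cosine
joint-angle profiles, so start and stop are acceleration-free), ground-truth
L5/S1 net moments via the same linked-segment mechanics used for supervised
targets, and the raw sensor signals a session would record: six IMMU streams
(with fixed, unknown mounting rotations and additive gyro/accelerometer
noise), four sEMG channels (an amplitude-modulated zero-mean carrier whose
rectified-smoothed envelope recovers the modulation), and the tap markers
used for clock synchronization.

The default session scenario mirrors a three-phase protocol: functional
calibration movements (five repetitions each), known-load trials
(bending / lateroflexion / rotation under 0, 6 and 10 kg), and work-task
archetypes (light, static, combined heavy+dynamic) with checklist ranks and
Borg CR-10 ratings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .types import (
    GRAVITY,
    SAMPLE_RATE,
    EMG_CHANNELS,
    EmgStream,
    ImmuStream,
    NetMomentSeries,
    Session,
    SubjectInfo,
    Trial,
    ValidationError,
)
from .lsm import BodyModel, LoadSpec, lsm_net_moment, scale_body_model

#: raw EMG sample rate emitted by the simulator, Hz
EMG_RAW_RATE = 1000.0

#: linear EMG forward model: channel amplitude is
#: gain * max(0, a*My + b*Mx + c*Mz) + baseline. Side-signed (b, c) encode
#: the bilateral asymmetry of the trunk extensors for lateroflexion and
#: axial twist; left/right channels fire for opposite signs.
EMG_COEFFICIENTS = {
    "longissimus_L1_L": (1.0, 0.4, 0.5),
    "longissimus_L1_R": (1.0, -0.4, -0.5),
    "iliocostalis_L23_L": (0.6, 0.9, -0.3),
    "iliocostalis_L23_R": (0.6, -0.9, 0.3),
}

#: resting-tone envelope level, arbitrary units
EMG_BASELINE = 0.02

#: share of the lumbar movement taken up by the pelvis (lumbo-pelvic rhythm)
PELVIS_FRACTION = {
    "bending": 0.33,
    "lateroflexion": 0.20,
    "rotation": 0.30,
    "lift_cycle": 0.33,
    "hold_posture": 0.33,
}

_MOTION_MOVEMENTS = (
    "bending",
    "lateroflexion",
    "rotation",
    "shoulder_flexion",
    "shoulder_abduction",
    "neutral",
    "lift_cycle",
    "hold_posture",
)


@dataclass(frozen=True)
class MotionSpec:
    """One movement block: raised-cosine angle profile, repeated."""

    movement: str
    peak_angle: float = 0.0  # rad
    period: float = 4.0  # s per repetition (hold time for hold_posture)
    repetitions: int = 1
    load_mass: float = 0.0  # kg
    load_offset: np.ndarray = field(default_factory=lambda: np.array([0.15, 0.0, 0.0]))
    pre_duration: float = 5.0  # s of neutral stance before the movement (tap window)
    post_duration: float = 3.0  # s of neutral stance after

    def __post_init__(self):
        if self.movement not in _MOTION_MOVEMENTS:
            raise ValidationError(f"unknown movement {self.movement!r}")
        if not 0.0 <= self.peak_angle <= np.pi / 2 + 1e-9:
            raise ValidationError(f"peak angle {self.peak_angle} outside [0, pi/2]")
        if self.period <= 0.2:
            raise ValidationError(f"period {self.period} s must exceed 0.2 s")
        if self.repetitions < 1:
            raise ValidationError("repetitions must be >= 1")
        object.__setattr__(self, "load_offset", np.asarray(self.load_offset, dtype=float))


@dataclass(frozen=True)
class SensorNoiseSpec:
    """Sensor imperfection model standing in for the hardware."""

    gyro_sd: float = 0.01  # rad/s
    acc_sd: float = 0.05  # m/s^2
    #: fixed casing-to-segment misalignment per site, rotation vector (rad);
    #: empty dict = perfectly aligned mounting
    mount_rotations: dict = field(default_factory=dict)
    #: magnitude bound used when mounting rotations are drawn randomly, deg
    mount_rotation_deg: float = 10.0
    emg_gain: float = 0.01  # units/Nm
    emg_noise_sd: float = 0.05  # units
    emg_crosstalk: float = 0.05  # dimensionless
    tap_offset: float = 0.0  # s, EMG clock minus IMMU clock
    tap_time: float = 2.5  # s, physical tap instant within the pre-trial window

    def __post_init__(self):
        for name in ("gyro_sd", "acc_sd", "emg_noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0.0 <= self.emg_crosstalk <= 0.3:
            raise ValidationError("emg_crosstalk outside [0, 0.3]")
        for site, rv in self.mount_rotations.items():
            if np.linalg.norm(rv) > np.radians(30.0) + 1e-9:
                raise ValidationError(f"mount rotation for {site} exceeds 30 deg")


@dataclass
class KinematicsTrack:
    """Noise-free segment kinematics sampled at the sensor sites."""

    t: np.ndarray
    streams: dict[str, ImmuStream]
    lumbar_angle: np.ndarray  # rad, trunk movement angle profile
    spec: MotionSpec
    subject: SubjectInfo


def _raised_cosine(spec: MotionSpec, fs: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Timeline, angle and analytic angle rate for one movement block."""
    n_pre = round(spec.pre_duration * fs)
    n_post = round(spec.post_duration * fs)
    if spec.movement == "neutral":
        n_move = round(spec.period * fs)
        theta = np.zeros(n_pre + n_move + n_post)
        dtheta = np.zeros_like(theta)
    elif spec.movement == "hold_posture":
        ramp = 2.0
        n_ramp = round(ramp * fs)
        n_hold = round(spec.period * fs)
        u = np.arange(n_ramp) / n_ramp
        up = spec.peak_angle * 0.5 * (1.0 - np.cos(np.pi * u))
        dup = spec.peak_angle * np.pi / (2.0 * ramp) * np.sin(np.pi * u)
        theta = np.concatenate(
            [
                np.zeros(n_pre),
                up,
                np.full(n_hold, spec.peak_angle),
                spec.peak_angle - up,
                np.zeros(n_post),
            ]
        )
        dtheta = np.concatenate(
            [np.zeros(n_pre), dup, np.zeros(n_hold), -dup, np.zeros(n_post)]
        )
    else:
        n_rep = round(spec.period * fs)
        u = np.arange(n_rep) / n_rep
        rep = spec.peak_angle * 0.5 * (1.0 - np.cos(2.0 * np.pi * u))
        drep = spec.peak_angle * np.pi / spec.period * np.sin(2.0 * np.pi * u)
        theta = np.concatenate(
            [np.zeros(n_pre)] + [rep] * spec.repetitions + [np.zeros(n_post)]
        )
        dtheta = np.concatenate(
            [np.zeros(n_pre)] + [drep] * spec.repetitions + [np.zeros(n_post)]
        )
    t = np.arange(len(theta)) / fs
    return t, theta, dtheta


def _second_derivative(p: np.ndarray, fs: float) -> np.ndarray:
    v = np.gradient(p, 1.0 / fs, axis=0)
    return np.gradient(v, 1.0 / fs, axis=0)


def simulate_kinematics(
    spec: MotionSpec, subject: SubjectInfo, seed: int = 0
) -> KinematicsTrack:
    """Generate noise-free segment kinematics for one movement block.

    Joint angles follow raised-cosine profiles (C¹-smooth, start and end at
    rest); emitted angular velocities are the analytic derivatives of the
    orientation tracks. The arms hang vertically (gravity-aligned) except in
    the shoulder calibration movements. Sensor-site specific forces are
    consistent with the site trajectory plus gravity.
    """
    del seed  # the kinematic track is deterministic
    body = scale_body_model(subject)
    fs = SAMPLE_RATE
    t, theta, dtheta = _raised_cosine(spec, fs)
    n = len(t)
    g_vec = np.array([0.0, 0.0, -GRAVITY])
    zeros = np.zeros((n, 3))

    trunk_axis = {
        "bending": np.array([0.0, 1.0, 0.0]),
        "lift_cycle": np.array([0.0, 1.0, 0.0]),
        "hold_posture": np.array([0.0, 1.0, 0.0]),
        "lateroflexion": np.array([-1.0, 0.0, 0.0]),
        "rotation": np.array([0.0, 0.0, 1.0]),
    }.get(spec.movement)

    # segment rotations and world angular velocities
    if trunk_axis is not None:
        pf = PELVIS_FRACTION[spec.movement]
        R_trunk = Rotation.from_rotvec(np.outer(theta, trunk_axis))
        w_trunk = np.outer(dtheta, trunk_axis)
        R_pelvis = Rotation.from_rotvec(np.outer(pf * theta, trunk_axis))
        w_pelvis = np.outer(pf * dtheta, trunk_axis)
    else:
        R_trunk = Rotation.identity(n)
        w_trunk = zeros
        R_pelvis = Rotation.identity(n)
        w_pelvis = zeros

    arm_R: dict[str, Rotation] = {}
    arm_w: dict[str, np.ndarray] = {}
    for side in ("L", "R"):
        if spec.movement == "shoulder_flexion":
            axis = np.array([0.0, -1.0, 0.0])  # distal end moves anterior
        elif spec.movement == "shoulder_abduction":
            axis = np.array([1.0 if side == "L" else -1.0, 0.0, 0.0])
        else:
            axis = None
        if axis is None:
            arm_R[side] = Rotation.identity(n)
            arm_w[side] = zeros
        else:
            arm_R[side] = Rotation.from_rotvec(np.outer(theta, axis))
            arm_w[side] = np.outer(dtheta, axis)

    lt = body.segments["trunk"].length
    lu = body.segments["upper_arm_L"].length

    def stream(site: str, R: Rotation, w_global: np.ndarray, origin: np.ndarray) -> ImmuStream:
        offset = body.sensor_offsets[site]
        p = origin + R.apply(np.tile(np.asarray(offset, dtype=float), (n, 1)))
        acc = _second_derivative(p, fs)
        quat = R.as_quat()[:, [3, 0, 1, 2]]
        quat = np.where(quat[:, :1] < 0, -quat, quat)
        return ImmuStream(
            site=site,
            t=t,
            quat=quat,
            angvel=R.apply(w_global, inverse=True),
            linacc=R.apply(acc - g_vec, inverse=True),
        )

    streams: dict[str, ImmuStream] = {}
    origin0 = np.zeros((n, 3))
    streams["sternum"] = stream("sternum", R_trunk, w_trunk, origin0)
    streams["sacrum"] = stream("sacrum", R_pelvis, w_pelvis, origin0)
    for side, sign in (("L", 1.0), ("R", -1.0)):
        shoulder = R_trunk.apply(
            np.tile(np.asarray([0.0, sign * body.shoulder_halfwidth, lt], dtype=float), (n, 1))
        )
        streams[f"upper_arm_{side}"] = stream(
            f"upper_arm_{side}", arm_R[side], arm_w[side], shoulder
        )
        elbow = shoulder + arm_R[side].apply(np.tile(np.asarray([0.0, 0.0, -lu], dtype=float), (n, 1)))
        streams[f"lower_arm_{side}"] = stream(
            f"lower_arm_{side}", arm_R[side], arm_w[side], elbow
        )

    return KinematicsTrack(t=t, streams=streams, lumbar_angle=theta, spec=spec, subject=subject)


def simulate_truth_moment(
    kinematics: KinematicsTrack,
    body_model: BodyModel,
    load_mass: float | None = None,
    load_offset: np.ndarray | None = None,
) -> NetMomentSeries:
    """Ground-truth L5/S1 net moment from the noise-free kinematics.

    Uses the same linked-segment mechanics as the supervised-target
    computation, applied to the noise-free, perfectly calibrated streams.
    """
    spec = kinematics.spec
    load = LoadSpec(
        mass=spec.load_mass if load_mass is None else load_mass,
        position=spec.load_offset if load_offset is None else np.asarray(load_offset),
    )
    return lsm_net_moment(kinematics.streams, body_model, load, use_linacc=True)


def _mount_rotation(noise: SensorNoiseSpec, site: str) -> Rotation:
    rv = noise.mount_rotations.get(site)
    if rv is None:
        return Rotation.identity()
    return Rotation.from_rotvec(np.asarray(rv, dtype=float))


def _tap_pulse(t: np.ndarray, center: float, width: float, amplitude: float) -> np.ndarray:
    return amplitude * np.exp(-0.5 * ((t - center) / (width / 3.0)) ** 2)


def simulate_sensors(
    kinematics: KinematicsTrack,
    truth: NetMomentSeries,
    noise: SensorNoiseSpec = SensorNoiseSpec(),
    seed: int = 0,
) -> tuple[dict[str, ImmuStream], dict[str, EmgStream]]:
    """Degrade segment kinematics into sensor streams and synthesize sEMG.

    IMMU casings are pre-rotated by their fixed mounting rotations and carry
    additive Gaussian gyro/accelerometer noise; the sacrum accelerometer and
    every raw EMG channel carry the synchronization tap pulse. The EMG time
    axis is shifted by ``tap_offset`` (the EMG device clock error).
    """
    rng = np.random.default_rng(seed)
    t = kinematics.t
    n = len(t)

    immu: dict[str, ImmuStream] = {}
    for site, seg_stream in kinematics.streams.items():
        R_m = _mount_rotation(noise, site)
        R_seg = Rotation.from_quat(seg_stream.quat[:, [1, 2, 3, 0]])
        quat = (R_seg * R_m).as_quat()[:, [3, 0, 1, 2]]
        quat = np.where(quat[:, :1] < 0, -quat, quat)
        angvel = R_m.apply(seg_stream.angvel, inverse=True)
        linacc = R_m.apply(seg_stream.linacc, inverse=True)
        if noise.gyro_sd > 0:
            angvel = angvel + rng.normal(0.0, noise.gyro_sd, (n, 3))
        if noise.acc_sd > 0:
            linacc = linacc + rng.normal(0.0, noise.acc_sd, (n, 3))
        if site == "sacrum":
            linacc = linacc + _tap_pulse(t, noise.tap_time, 0.06, 30.0)[:, None] * np.array(
                [[0.3, 0.3, 1.0]]
            )
        immu[site] = ImmuStream(site=site, t=t, quat=quat, angvel=angvel, linacc=linacc)

    # EMG: linear-in-moment envelopes, half-wave rectified
    envelopes: dict[str, np.ndarray] = {}
    for ch in EMG_CHANNELS:
        a, b, c = EMG_COEFFICIENTS[ch]
        drive = a * truth.My + b * truth.Mx + c * truth.Mz
        envelopes[ch] = noise.emg_gain * np.maximum(0.0, drive) + EMG_BASELINE
    if noise.emg_crosstalk > 0:
        mixed = {}
        for ch in EMG_CHANNELS:
            others = np.mean([envelopes[o] for o in EMG_CHANNELS if o != ch], axis=0)
            mixed[ch] = (1.0 - noise.emg_crosstalk) * envelopes[ch] + noise.emg_crosstalk * others
        envelopes = mixed

    n_raw = int(round((t[-1] - t[0]) * EMG_RAW_RATE)) + 1
    t_raw = t[0] + np.arange(n_raw) / EMG_RAW_RATE
    carrier_scale = np.sqrt(np.pi / 2.0)  # so E|env * carrier| = env
    tap = _tap_pulse(t_raw, noise.tap_time, 0.03, 1.0)
    emg: dict[str, EmgStream] = {}
    for ch in EMG_CHANNELS:
        env_up = np.interp(t_raw, t, envelopes[ch])
        raw = env_up * carrier_scale * rng.standard_normal(n_raw)
        if noise.emg_noise_sd > 0:
            raw = raw + noise.emg_noise_sd * carrier_scale * rng.standard_normal(n_raw)
        tap_amp = 25.0 * max(float(np.max(env_up)), noise.emg_noise_sd, EMG_BASELINE)
        raw = raw + tap_amp * tap
        emg[ch] = EmgStream(channel=ch, t_raw=t_raw + noise.tap_offset, raw=raw)
    return immu, emg


# ---------------------------------------------------------------------------
# session scenarios

#: Borg CR-10 rating distributions per task perception (mean, SD), truncated
#: to the 0–10 scale
BORG_DISTRIBUTIONS = {
    "light": (0.9, 0.8),
    "static": (3.8, 1.6),
    "heavy_dynamic": (6.0, 2.0),
}

_CALIBRATION_PLAN = [
    ("cal_neutral", MotionSpec("neutral", 0.0, period=4.0)),
    ("cal_bending", MotionSpec("bending", np.radians(90), 4.0, 5)),
    ("cal_lateroflexion", MotionSpec("lateroflexion", np.radians(45), 4.0, 5)),
    ("cal_rotation", MotionSpec("rotation", np.radians(45), 4.0, 5)),
    ("cal_shoulder_flexion", MotionSpec("shoulder_flexion", np.radians(45), 4.0, 5)),
    ("cal_shoulder_abduction", MotionSpec("shoulder_abduction", np.radians(90), 4.0, 5)),
]

_LOAD_PEAKS = {"bending": np.radians(50), "lateroflexion": np.radians(30), "rotation": np.radians(30)}

_TASK_PLAN = [
    (
        "task_light",
        "light",
        MotionSpec("bending", np.radians(12), period=8.0, repetitions=3),
    ),
    (
        "task_static",
        "static",
        MotionSpec("hold_posture", np.radians(30), period=12.0),
    ),
    (
        "task_heavy_dynamic",
        "heavy_dynamic",
        MotionSpec("lift_cycle", np.radians(55), period=3.0, repetitions=6, load_mass=8.0),
    ),
]


def _truncated_normal(rng: np.random.Generator, mu: float, sd: float, lo: float, hi: float) -> float:
    for _ in range(100):
        x = rng.normal(mu, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mu, lo, hi))


def _draw_mounts(rng: np.random.Generator, max_deg: float) -> dict[str, np.ndarray]:
    mounts = {}
    for site in ("sternum", "sacrum", "upper_arm_L", "upper_arm_R", "lower_arm_L", "lower_arm_R"):
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        mounts[site] = np.radians(rng.uniform(0.0, max_deg)) * axis
    return mounts


def simulate_session(
    subject: SubjectInfo | None = None,
    scenario: str = "field_default",
    seed: int = 0,
    noise: SensorNoiseSpec | None = None,
    tap_offset: float | None = None,
) -> Session:
    """Simulate a complete three-phase session.

    ``scenario='field_default'`` emits the full protocol; ``'sync_only'``
    emits a single short neutral trial (enough to exercise marker detection
    and synchronization). Mounting rotations are drawn once per session (the
    sensors stay strapped on); the EMG clock offset defaults to a draw from
    U(−0.5, 0.5) s when not given.
    """
    rng = np.random.default_rng(seed)
    if subject is None:
        subject = SubjectInfo(id=f"sim{seed:04d}", height=1.85, mass=93.0)
    body = scale_body_model(subject)
    base = noise or SensorNoiseSpec()
    if not base.mount_rotations:
        base = replace(base, mount_rotations=_draw_mounts(rng, base.mount_rotation_deg))
    if tap_offset is None:
        tap_offset = float(rng.uniform(-0.5, 0.5))
    base = replace(base, tap_offset=tap_offset)

    def make_trial(trial_id, kind, movement, spec, **extra) -> Trial:
        kin = simulate_kinematics(spec, subject)
        truth = simulate_truth_moment(kin, body)
        immu, emg = simulate_sensors(kin, truth, base, seed=int(rng.integers(2**31)))
        return Trial(
            id=trial_id,
            kind=kind,
            movement=movement,
            load_mass=spec.load_mass,
            immu=immu,
            emg=emg,
            truth_moment=truth,
            **extra,
        )

    trials: list[Trial] = []
    if scenario == "sync_only":
        trials.append(
            make_trial("cal_neutral", "segment_calibration", "neutral", MotionSpec("neutral", 0.0, period=2.0))
        )
        return Session(subject=subject, trials=trials)
    if scenario != "field_default":
        raise ValidationError(f"unknown scenario {scenario!r}")

    for trial_id, spec in _CALIBRATION_PLAN:
        trials.append(make_trial(trial_id, "segment_calibration", spec.movement, spec))

    for movement in ("bending", "lateroflexion", "rotation"):
        for mass in (0.0, 6.0, 10.0):
            spec = MotionSpec(movement, _LOAD_PEAKS[movement], 4.0, 3, load_mass=mass)
            trials.append(
                make_trial(f"load_{movement}_{int(mass)}", "load_trial", movement, spec)
            )

    ranks = {"light": 1, "static": int(rng.choice([3, 4])), "heavy_dynamic": 5}
    for trial_id, label, spec in _TASK_PLAN:
        mu, sd = BORG_DISTRIBUTIONS[label]
        trials.append(
            make_trial(
                trial_id,
                "work_task",
                "task",
                spec,
                task_label=label,
                checklist_rank=ranks[label],
                borg=_truncated_normal(rng, mu, sd, 0.0, 10.0),
            )
        )
    return Session(subject=subject, trials=trials)


__all__ = [
    "EMG_RAW_RATE",
    "EMG_COEFFICIENTS",
    "EMG_BASELINE",
    "BORG_DISTRIBUTIONS",
    "PELVIS_FRACTION",
    "MotionSpec",
    "SensorNoiseSpec",
    "KinematicsTrack",
    "simulate_kinematics",
    "simulate_truth_moment",
    "simulate_sensors",
    "simulate_session",
]
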