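"""Top-down linked-segment model (LSM) of the L5/S1 net moment.

The upper body is modeled as a chain of rigid segments — trunk, head+neck
(rigidly attached to the trunk; the sensor layout has no head sensor), both
upper arms, and both forearm+hand segments — rooted at the L5/S1 joint
center. The net moment the joint transmits to the upper body follows from
the Newton–Euler balance about L5/S1:

    M = sum_i [ r_i x m_i (a_i - g) + I_i alpha_i + w_i x I_i w_i ] + load term

with r_i the segment COM relative to L5/S1, a_i its linear acceleration, and
the handheld load treated as a point mass at a known position relative to the
hands. Segment positions are reconstructed from the calibrated IMMU
orientations and the anthropometrically scaled segment lengths; COM
accelerations are transferred from the IMMU specific-force channels across
each rigid body when ``use_linacc`` is enabled (accelerations are otherwise
dropped, leaving the quasi-static gravitational moment).

Reported components use the clinical sign convention: Mx positive for
lateroflexion to the left, My positive for forward flexion, Mz positive for
rotation to the left, expressed in the trunk anatomical frame (x anterior,
y left, z cranial).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .types import GRAVITY, ImmuStream, NetMomentSeries, SubjectInfo, ValidationError
from .signals import lowpass_filtfilt

#: Segment parameter fractions (adult anthropometry, adapted from the
#: standard cadaver-based tables): mass as fraction of body mass, length as
#: fraction of stature, COM position as fraction of segment length from the
#: proximal end, transverse radius of gyration as fraction of segment length.
#: The modeled upper body totals 0.678 of body mass.
ANTHROPOMETRY = {
    "trunk": dict(mass_frac=0.497, length_frac=0.288, com_frac=0.50, gyration_frac=0.35),
    "head_neck": dict(mass_frac=0.081, length_frac=0.182, com_frac=0.40, gyration_frac=0.30),
    "upper_arm": dict(mass_frac=0.028, length_frac=0.186, com_frac=0.436, gyration_frac=0.322),
    "forearm_hand": dict(mass_frac=0.022, length_frac=0.254, com_frac=0.43, gyration_frac=0.34),
}

UPPER_BODY_MASS_FRACTION = 0.678

#: biacromial half-width as fraction of stature
SHOULDER_HALFWIDTH_FRAC = 0.129
#: hand center along the forearm+hand segment, fraction of its length
HAND_CENTER_FRAC = 0.78

SEGMENTS = ("trunk", "head_neck", "upper_arm_L", "upper_arm_R", "forearm_hand_L", "forearm_hand_R")

#: IMMU site serving each instrumented segment
SITE_OF_SEGMENT = {
    "trunk": "sternum",
    "upper_arm_L": "upper_arm_L",
    "upper_arm_R": "upper_arm_R",
    "forearm_hand_L": "lower_arm_L",
    "forearm_hand_R": "lower_arm_R",
}


@dataclass(frozen=True)
class SegmentParams:
    mass: float  # kg
    length: float  # m
    com_frac: float  # fraction of length from proximal end
    inertia: tuple[float, float, float]  # principal, kg m^2 (x, y transverse; z longitudinal)


@dataclass(frozen=True)
class BodyModel:
    """Anthropometrically scaled segment parameters for one subject."""

    subject: SubjectInfo
    segments: dict[str, SegmentParams]
    shoulder_halfwidth: float  # m
    hand_center_frac: float = HAND_CENTER_FRAC
    #: sensor mounting points in segment frames (m); shared with the simulator
    sensor_offsets: dict[str, np.ndarray] = field(default_factory=dict)
    #: L5/S1 center in the trunk frame — the chain root, by construction the origin
    L5S1_offset: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        total = sum(
            p.mass for name, p in self.segments.items() if name != "pelvis"
        )
        expected = UPPER_BODY_MASS_FRACTION * self.subject.mass
        if abs(total - expected) > 0.01 * self.subject.mass:
            raise ValidationError(
                f"upper-body segment masses sum to {total:.2f} kg, expected "
                f"{expected:.2f} kg (0.678 of body mass)"
            )
        for name, p in self.segments.items():
            if p.mass <= 0:
                raise ValidationError(f"{name}: non-positive mass")
            if not 0.0 < p.com_frac < 1.0:
                raise ValidationError(f"{name}: COM fraction {p.com_frac} outside (0,1)")


@dataclass(frozen=True)
class LoadSpec:
    """Handheld load: point mass at a trunk-frame offset from mid-hands."""

    mass: float = 0.0  # kg
    position: np.ndarray = field(default_factory=lambda: np.array([0.15, 0.0, 0.0]))
    known: bool = True

    def __post_init__(self):
        if self.mass < 0:
            raise ValidationError(f"load mass {self.mass} < 0")
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))


def _segment_params(kind: str, subject: SubjectInfo) -> SegmentParams:
    tab = ANTHROPOMETRY[kind]
    m = tab["mass_frac"] * subject.mass
    length = tab["length_frac"] * subject.height
    k = tab["gyration_frac"] * length
    it = m * k**2
    return SegmentParams(m, length, tab["com_frac"], (it, it, m * (0.5 * k) ** 2))


def scale_body_model(subject: SubjectInfo) -> BodyModel:
    """Scale the anthropometric table by subject stature and body mass."""
    segs = {
        "trunk": _segment_params("trunk", subject),
        "head_neck": _segment_params("head_neck", subject),
    }
    for side in ("L", "R"):
        segs[f"upper_arm_{side}"] = _segment_params("upper_arm", subject)
        segs[f"forearm_hand_{side}"] = _segment_params("forearm_hand", subject)
    lt = segs["trunk"].length
    lu = segs["upper_arm_L"].length
    lf = segs["forearm_hand_L"].length
    offsets = {
        "sternum": np.array([0.07, 0.0, 0.70 * lt]),
        "sacrum": np.array([-0.08, 0.0, -0.05]),
        "upper_arm_L": np.array([0.0, 0.03, -0.45 * lu]),
        "upper_arm_R": np.array([0.0, -0.03, -0.45 * lu]),
        "lower_arm_L": np.array([0.0, 0.02, -0.35 * lf]),
        "lower_arm_R": np.array([0.0, -0.02, -0.35 * lf]),
    }
    return BodyModel(
        subject=subject,
        segments=segs,
        shoulder_halfwidth=SHOULDER_HALFWIDTH_FRAC * subject.height,
        sensor_offsets=offsets,
    )


def moment_norm(series: NetMomentSeries) -> np.ndarray:
    """Per-sample Euclidean norm of (Mx, My, Mz), in Nm."""
    return series.norm


# ---------------------------------------------------------------------------
# chain reconstruction


def _rot(quat: np.ndarray) -> Rotation:
    """Scalar-first (w,x,y,z) quaternion array -> Rotation."""
    return Rotation.from_quat(np.asarray(quat)[:, [1, 2, 3, 0]])


@dataclass
class _SegState:
    """Per-segment world-frame state along the chain."""

    R: Rotation
    com: np.ndarray  # (N, 3) COM position relative to L5/S1
    omega: np.ndarray  # (N, 3) angular velocity, world frame
    a_ref: np.ndarray | None  # (N, 3) acceleration of a known point (sensor), world
    p_ref: np.ndarray | None  # (N, 3) that point's position


def _chain_states(
    streams: dict[str, ImmuStream],
    body: BodyModel,
) -> tuple[np.ndarray, dict[str, _SegState], np.ndarray]:
    """Reconstruct world-frame segment states from calibrated streams.

    Returns (t, states keyed by segment, mid-hands position).
    """
    missing = [
        site for site in SITE_OF_SEGMENT.values() if site not in streams
    ]
    if missing:
        raise ValidationError(f"missing segment stream(s): {', '.join(sorted(missing))}")
    t = streams["sternum"].t
    n = len(t)
    g_vec = np.array([0.0, 0.0, -GRAVITY])

    def world(stream: ImmuStream) -> tuple[Rotation, np.ndarray, np.ndarray]:
        R = _rot(stream.quat)
        omega = R.apply(stream.angvel)
        acc_world = R.apply(stream.linacc) + g_vec  # specific force -> coordinate accel
        return R, omega, acc_world

    states: dict[str, _SegState] = {}

    # trunk (sternum sensor); head+neck rigid with it
    R_t, w_t, a_sens_t = world(streams["sternum"])
    p_sens_t = R_t.apply(np.tile(np.asarray(body.sensor_offsets["sternum"], dtype=float), (n, 1)))
    lt = body.segments["trunk"].length
    trunk_com = R_t.apply(np.tile(np.asarray([0.0, 0.0, body.segments["trunk"].com_frac * lt], dtype=float), (n, 1)))
    states["trunk"] = _SegState(R_t, trunk_com, w_t, a_sens_t, p_sens_t)

    hn = body.segments["head_neck"]
    head_com = R_t.apply(np.tile(np.asarray([0.0, 0.0, lt + hn.com_frac * hn.length], dtype=float), (n, 1)))
    states["head_neck"] = _SegState(R_t, head_com, w_t, a_sens_t, p_sens_t)

    hands = {}
    for side, sign in (("L", 1.0), ("R", -1.0)):
        shoulder = R_t.apply(np.tile(np.asarray([0.0, sign * body.shoulder_halfwidth, lt], dtype=float), (n, 1)))
        ua = body.segments[f"upper_arm_{side}"]
        R_u, w_u, a_su = world(streams[f"upper_arm_{side}"])
        ua_axis = R_u.apply(np.tile(np.asarray([0.0, 0.0, -1.0], dtype=float), (n, 1)))
        ua_com = shoulder + ua.com_frac * ua.length * ua_axis
        p_su = shoulder + R_u.apply(
            np.tile(np.asarray(body.sensor_offsets[f"upper_arm_{side}"], dtype=float), (n, 1))
        )
        states[f"upper_arm_{side}"] = _SegState(R_u, ua_com, w_u, a_su, p_su)

        elbow = shoulder + ua.length * ua_axis
        fh = body.segments[f"forearm_hand_{side}"]
        R_f, w_f, a_sf = world(streams[f"lower_arm_{side}"])
        fh_axis = R_f.apply(np.tile(np.asarray([0.0, 0.0, -1.0], dtype=float), (n, 1)))
        fh_com = elbow + fh.com_frac * fh.length * fh_axis
        p_sf = elbow + R_f.apply(
            np.tile(np.asarray(body.sensor_offsets[f"lower_arm_{side}"], dtype=float), (n, 1))
        )
        states[f"forearm_hand_{side}"] = _SegState(R_f, fh_com, w_f, a_sf, p_sf)
        hands[side] = elbow + body.hand_center_frac * fh.length * fh_axis

    mid_hands = 0.5 * (hands["L"] + hands["R"])
    return t, states, mid_hands


def _smooth_gradient(x: np.ndarray, fs: float, cutoff: float) -> np.ndarray:
    """Central-difference derivative with zero-phase low-pass smoothing."""
    if len(x) >= 15:
        x = lowpass_filtfilt(x, cutoff, fs)
    return np.gradient(x, 1.0 / fs, axis=0)


def lsm_net_moment(
    streams: dict[str, ImmuStream],
    body: BodyModel,
    load: LoadSpec = LoadSpec(),
    use_linacc: bool = True,
    smoothing_cutoff: float = 3.0,
) -> NetMomentSeries:
    """Compute the 3D net moment at L5/S1 from calibrated segment streams.

    ``streams`` maps IMMU sites to segment-frame streams (sternum, sacrum and
    the four arm sensors). With ``use_linacc`` disabled, only the
    gravitational (quasi-static) terms are kept, for use outside controlled
    environments where the accelerometer channels are unreliable.
    """
    fs = 1.0 / float(np.median(np.diff(streams["sternum"].t)))
    t, states, mid_hands = _chain_states(streams, body)
    n = len(t)
    g_vec = np.array([0.0, 0.0, -GRAVITY])
    M = np.zeros((n, 3))

    for name in SEGMENTS:
        st = states[name]
        p = body.segments[name]
        if use_linacc:
            # transfer the sensor-point acceleration to the COM across the rigid body
            r_rel = st.com - st.p_ref
            alpha = _smooth_gradient(st.omega, fs, smoothing_cutoff)
            a_com = (
                st.a_ref
                + np.cross(alpha, r_rel)
                + np.cross(st.omega, np.cross(st.omega, r_rel))
            )
            I_body = np.diag(p.inertia)
            Rm = st.R.as_matrix()
            Iw = np.einsum("nij,jk,nlk->nil", Rm, I_body, Rm)
            ang = np.einsum("nij,nj->ni", Iw, alpha) + np.cross(
                st.omega, np.einsum("nij,nj->ni", Iw, st.omega)
            )
        else:
            a_com = np.zeros((n, 3))
            ang = np.zeros((n, 3))
        M += np.cross(st.com, p.mass * (a_com - g_vec)) + ang

    if load.mass > 0:
        R_t = states["trunk"].R
        p_load = mid_hands + R_t.apply(np.tile(np.asarray(load.position, dtype=float), (n, 1)))
        if use_linacc:
            v = _smooth_gradient(p_load, fs, smoothing_cutoff)
            a_load = _smooth_gradient(v, fs, smoothing_cutoff)
        else:
            a_load = np.zeros((n, 3))
        M += np.cross(p_load, load.mass * (a_load - g_vec))

    # express in the trunk anatomical frame; clinical sign convention flips My
    M_trunk = states["trunk"].R.apply(M, inverse=True)
    return NetMomentSeries(t=t, Mx=M_trunk[:, 0], My=-M_trunk[:, 1], Mz=M_trunk[:, 2])


__all__ = [
    "ANTHROPOMETRY",
    "UPPER_BODY_MASS_FRACTION",
    "SEGMENTS",
    "SITE_OF_SEGMENT",
    "SegmentParams",
    "BodyModel",
    "LoadSpec",
    "scale_body_model",
    "moment_norm",
    "lsm_net_moment",
]
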