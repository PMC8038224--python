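import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from lumbarload import DT, GRAVITY, NetMomentSeries, SubjectInfo, ValidationError
from lumbarload.lsm import (
    ANTHROPOMETRY,
    UPPER_BODY_MASS_FRACTION,
    LoadSpec,
    lsm_net_moment,
    moment_norm,
    scale_body_model,
)
from lumbarload.simulate import MotionSpec, simulate_kinematics, simulate_truth_moment


def static_flexion_oracle(body, theta, load_mass=0.0, load_offset=(0.0, 0.0, 0.0)):
    """Independent point-mass gravitational sum for a static trunk flexion.

    Positions are re-derived from the posture geometry (arms hanging
    vertically below the shoulders), not taken from the chain code.
    """
    s = body.segments
    lt = s["trunk"].length
    d_trunk = np.sin(theta) * s["trunk"].com_frac * lt
    d_head = np.sin(theta) * (lt + s["head_neck"].com_frac * s["head_neck"].length)
    d_arm = np.sin(theta) * lt  # hanging arm COM is below the shoulder
    my = GRAVITY * (
        s["trunk"].mass * d_trunk
        + s["head_neck"].mass * d_head
        + 2 * (s["upper_arm_L"].mass + s["forearm_hand_L"].mass) * d_arm
    )
    if load_mass:
        ox, _, oz = load_offset
        d_load = np.sin(theta) * lt + ox * np.cos(theta) + oz * np.sin(theta)
        my += GRAVITY * load_mass * d_load
    return my


def test_segment_masses_sum_to_upper_body_fraction(subject, body):
    total = sum(p.mass for p in body.segments.values())
    assert abs(total - UPPER_BODY_MASS_FRACTION * subject.mass) < 0.5
    assert sum(v["mass_frac"] for v in ANTHROPOMETRY.values()) + ANTHROPOMETRY["upper_arm"][
        "mass_frac"
    ] + ANTHROPOMETRY["forearm_hand"]["mass_frac"] == pytest.approx(UPPER_BODY_MASS_FRACTION)


def test_mass_scaling_is_linear(subject):
    double = SubjectInfo(id="d", height=subject.height, mass=2 * subject.mass)
    a = scale_body_model(subject)
    b = scale_body_model(double)
    for name in a.segments:
        assert b.segments[name].mass == pytest.approx(2 * a.segments[name].mass)
        assert b.segments[name].length == pytest.approx(a.segments[name].length)


def test_zero_height_rejected():
    with pytest.raises(ValidationError):
        SubjectInfo(id="z", height=0.0, mass=80.0)


def test_neutral_stance_moment_near_zero(subject, body):
    kin = simulate_kinematics(MotionSpec("neutral", 0.0, period=4.0), subject)
    m = lsm_net_moment(kin.streams, body, LoadSpec(0.0))
    assert np.linalg.norm(m.as_array().mean(axis=0)) <= 5.0


def test_static_flexion_matches_gravitational_oracle(subject, body):
    kin = simulate_kinematics(MotionSpec("hold_posture", np.pi / 2, period=6.0), subject)
    m = lsm_net_moment(kin.streams, body, LoadSpec(0.0))
    i = len(m) // 2  # mid-hold sample
    assert abs(m.My[i] - static_flexion_oracle(body, np.pi / 2)) < 1.0
    assert abs(m.Mx[i]) < 1e-6 and abs(m.Mz[i]) < 1e-6


def test_static_limit_equals_oracle_to_1e6(subject, body):
    # noise-free static hold: inertial terms vanish, gravitational sum exact
    for theta in (0.3, 0.8, np.pi / 2):
        kin = simulate_kinematics(MotionSpec("hold_posture", theta, period=6.0), subject)
        m = lsm_net_moment(kin.streams, body, LoadSpec(0.0))
        i = len(m) // 2
        assert abs(m.My[i] - static_flexion_oracle(body, theta)) < 1e-6


def test_known_load_at_040m_adds_closed_form_moment(subject, body):
    # choose the hold angle so the hands sit 0.40 m anterior of L5/S1
    lt = body.segments["trunk"].length
    theta = np.arcsin(0.40 / lt)
    kin = simulate_kinematics(MotionSpec("hold_posture", theta, period=6.0), subject)
    m0 = lsm_net_moment(kin.streams, body, LoadSpec(0.0))
    m10 = lsm_net_moment(kin.streams, body, LoadSpec(10.0, position=[0.0, 0.0, 0.0]))
    i = len(m0) // 2
    assert m10.My[i] - m0.My[i] == pytest.approx(10 * GRAVITY * 0.40, abs=0.1)


def test_load_linearity(subject, body):
    kin = simulate_kinematics(MotionSpec("bending", np.radians(50), 4.0, 2), subject)
    m0 = lsm_net_moment(kin.streams, body, LoadSpec(0.0)).as_array()
    m4 = lsm_net_moment(kin.streams, body, LoadSpec(4.0, position=[0.1, 0, 0])).as_array()
    m8 = lsm_net_moment(kin.streams, body, LoadSpec(8.0, position=[0.1, 0, 0])).as_array()
    assert np.allclose(m8 - m0, 2.0 * (m4 - m0), atol=1e-8)


def test_missing_segment_stream_names_segment(subject, body):
    kin = simulate_kinematics(MotionSpec("neutral", 0.0, period=2.0), subject)
    streams = dict(kin.streams)
    del streams["upper_arm_L"]
    with pytest.raises(ValidationError, match="upper_arm_L"):
        lsm_net_moment(streams, body)


def test_moment_norm_basic_and_rotation_invariant(rng):
    t = DT * np.arange(3)
    m = NetMomentSeries(t=t, Mx=np.array([0.0, 3.0, 1.0]), My=np.array([0.0, 4.0, 2.0]),
                        Mz=np.array([0.0, 0.0, 2.0]))
    assert moment_norm(m)[0] == 0.0
    assert moment_norm(m)[1] == pytest.approx(5.0)
    # norm is invariant under any proper rotation of the component triple
    R = Rotation.random(rng=np.random.default_rng(4)).as_matrix()
    v = m.as_array() @ R.T
    rotated = NetMomentSeries(t=t, Mx=v[:, 0], My=v[:, 1], Mz=v[:, 2])
    assert np.allclose(moment_norm(rotated), moment_norm(m), atol=1e-12)


def test_truth_moment_uses_same_mechanics(subject, body):
    kin = simulate_kinematics(MotionSpec("bending", np.radians(60), 4.0, 2, load_mass=6.0), subject)
    truth = simulate_truth_moment(kin, body)
    direct = lsm_net_moment(kin.streams, body, LoadSpec(6.0, position=kin.spec.load_offset))
    assert np.allclose(truth.as_array(), direct.as_array(), atol=1e-12)
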