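"""Sensor-to-segment calibration from functional calibration movements.

Each IMMU is strapped to its segment in an unknown, fixed orientation. The
phase-1 movement set identifies that rotation per site:

* the segment longitudinal axis (z, cranial) is the mean accelerometer
  direction during quiet neutral stance — gravity seen in the sensor frame;
* the mediolateral axis (y, pointing left) is the dominant angular-velocity
  direction during the sagittal calibration movement (trunk bending for the
  trunk and pelvis sensors, shoulder flexion for the arm sensors), taken as
  the first principal direction of the rate samples above a movement
  threshold, signed by the initial movement direction;
* the anterior axis completes the right-handed triad; Gram–Schmidt
  orthogonalization keeps the gravity axis exact.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from .types import ImmuStream, SegmentCalibration, Trial, ValidationError

#: rate threshold separating "moving" from quiet samples, rad/s
RATE_THRESHOLD = 0.3
#: principal rotation axis closer than this to gravity is unusable
DEGENERACY_ANGLE_DEG = 15.0

#: functional movement providing the rotation axis per site, and the sign of
#: the segment +y (left) axis relative to the initial movement direction:
#: trunk flexion is a positive rotation about +y, arm flexion a negative one.
_SITE_MOVEMENT = {
    "sternum": ("bending", +1.0),
    "sacrum": ("bending", +1.0),
    "upper_arm_L": ("shoulder_flexion", -1.0),
    "upper_arm_R": ("shoulder_flexion", -1.0),
    "lower_arm_L": ("shoulder_flexion", -1.0),
    "lower_arm_R": ("shoulder_flexion", -1.0),
}


class CalibrationError(RuntimeError):
    """Segment calibration could not be computed."""


def _principal_direction(samples: np.ndarray) -> np.ndarray:
    """First principal direction of a cloud of 3-vectors (not centered)."""
    _, _, vt = np.linalg.svd(samples, full_matrices=False)
    return vt[0]


def _site_rotation(
    site: str, neutral: list[ImmuStream], moving: list[ImmuStream], sign: float
) -> tuple[np.ndarray, float]:
    acc = np.concatenate([s.linacc for s in neutral], axis=0)
    gyr = np.concatenate([s.angvel for s in neutral], axis=0)
    # quiet samples only: near-1g specific force, below the rate threshold
    # (rejects the tap transient and any residual motion)
    quiet = (np.abs(np.linalg.norm(acc, axis=1) - 9.81) < 1.0) & (
        np.linalg.norm(gyr, axis=1) < RATE_THRESHOLD
    )
    if quiet.sum() < 10:
        raise CalibrationError(f"{site}: too few quiet neutral-stance samples")
    acc = acc[quiet]
    z_axis = acc.mean(axis=0)
    z_axis /= np.linalg.norm(z_axis)

    gyro = np.concatenate([s.angvel for s in moving], axis=0)
    rates = np.linalg.norm(gyro, axis=1)
    active = gyro[rates > RATE_THRESHOLD]
    if len(active) < 5:
        raise CalibrationError(
            f"{site}: too few moving samples in calibration movement "
            f"(rate threshold {RATE_THRESHOLD} rad/s)"
        )
    e = _principal_direction(active)
    angle_to_z = np.degrees(np.arccos(np.clip(abs(np.dot(e, z_axis)), -1.0, 1.0)))
    if angle_to_z < DEGENERACY_ANGLE_DEG:
        raise CalibrationError(
            f"{site}: rotation axis within {angle_to_z:.1f} deg of gravity — "
            "degenerate geometry (movement is a pure longitudinal rotation?)"
        )
    first = active[: min(10, len(active))].mean(axis=0)
    if np.dot(e, first) < 0:
        e = -e
    y_axis = sign * e

    x_axis = np.cross(y_axis, z_axis)
    x_axis /= np.linalg.norm(x_axis)
    y_axis = np.cross(z_axis, x_axis)

    # columns = segment axes in sensor coordinates = R_{sensor<-segment}
    C = np.column_stack([x_axis, y_axis, z_axis])
    R_mount = C.T  # sensor -> segment
    q = Rotation.from_matrix(R_mount).as_quat()  # x,y,z,w
    quat = np.array([q[3], q[0], q[1], q[2]])

    # residual: angular scatter of the gravity samples about the z estimate
    unit_acc = acc / np.linalg.norm(acc, axis=1, keepdims=True)
    ang = np.arccos(np.clip(unit_acc @ z_axis, -1.0, 1.0))
    residual = float(np.degrees(np.sqrt(np.mean(ang**2))))
    return quat, residual


def estimate_segment_frames(calib_trials: list[Trial]) -> SegmentCalibration:
    """Estimate sensor→segment rotations from phase-1 calibration trials."""
    if not calib_trials:
        raise CalibrationError("no calibration trials supplied")
    by_movement: dict[str, list[Trial]] = {}
    for tr in calib_trials:
        by_movement.setdefault(tr.movement, []).append(tr)
    if "neutral" not in by_movement:
        raise CalibrationError("missing neutral-stance calibration trial")

    sites = set()
    for tr in calib_trials:
        sites.update(tr.immu.keys())

    rotations: dict[str, np.ndarray] = {}
    residuals: dict[str, float] = {}
    for site in sorted(sites):
        movement, sign = _SITE_MOVEMENT[site]
        if movement not in by_movement:
            raise CalibrationError(f"{site}: missing {movement} calibration trial")
        neutral = [tr.immu[site] for tr in by_movement["neutral"] if site in tr.immu]
        moving = [tr.immu[site] for tr in by_movement[movement] if site in tr.immu]
        if not neutral or not moving:
            raise CalibrationError(f"{site}: site absent from required calibration trials")
        rotations[site], residuals[site] = _site_rotation(site, neutral, moving, sign)

    return SegmentCalibration(
        rotations=rotations,
        residual_deg=residuals,
        source_trials=[tr.id for tr in calib_trials],
    )


def apply_calibration(stream: ImmuStream, calib: SegmentCalibration) -> ImmuStream:
    """Re-express a casing-frame stream in its body-segment frame.

    Orientation becomes the segment orientation; angular velocity and
    specific force are rotated into the segment frame. Per-sample vector
    norms are unchanged (pure rotation).
    """
    if stream.site not in calib.rotations:
        raise ValidationError(f"no calibration for site {stream.site!r}")
    q = calib.rotations[stream.site]
    R_m = Rotation.from_quat([q[1], q[2], q[3], q[0]])  # sensor -> segment
    R_s = Rotation.from_quat(stream.quat[:, [1, 2, 3, 0]])  # global <- sensor
    R_seg = R_s * R_m.inv()  # global <- segment
    q_out = R_seg.as_quat()[:, [3, 0, 1, 2]]
    # canonical sign (w >= 0) for reproducible round-trips
    q_out = np.where(q_out[:, :1] < 0, -q_out, q_out)
    return ImmuStream(
        site=stream.site,
        t=stream.t.copy(),
        quat=q_out,
        angvel=R_m.apply(stream.angvel),
        linacc=R_m.apply(stream.linacc),
    )


def geodesic_angle_deg(q1: np.ndarray, q2: np.ndarray) -> float:
    """Angle (deg) of the relative rotation between two scalar-first quaternions."""
    r1 = Rotation.from_quat([q1[1], q1[2], q1[3], q1[0]])
    r2 = Rotation.from_quat([q2[1], q2[2], q2[3], q2[0]])
    return float(np.degrees((r1.inv() * r2).magnitude()))


__all__ = [
    "RATE_THRESHOLD",
    "DEGENERACY_ANGLE_DEG",
    "CalibrationError",
    "estimate_segment_frames",
    "apply_calibration",
    "geodesic_angle_deg",
]
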