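"""Core domain types for ambulatory lumbar-load sessions.

All streams live on a common 50 Hz session clock once synchronized; units are
SI throughout (m, kg, s, rad, N·m) except EMG, which is in arbitrary units —
the downstream estimator normalizes its inputs, so the EMG scale cancels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SAMPLE_RATE = 50.0  #: session grid rate, Hz
DT = 1.0 / SAMPLE_RATE
GRAVITY = 9.81  #: m/s^2

#: IMMU mounting sites (six-sensor layout: sternum, sacrum and both arms).
IMMU_SITES = (
    "sternum",
    "sacrum",
    "upper_arm_L",
    "upper_arm_R",
    "lower_arm_L",
    "lower_arm_R",
)

#: Bipolar sEMG channels: longissimus thoracis at L1 and iliocostalis
#: lumborum at L2–L3, bilaterally.
EMG_CHANNELS = (
    "longissimus_L1_L",
    "longissimus_L1_R",
    "iliocostalis_L23_L",
    "iliocostalis_L23_R",
)

MOVEMENTS = (
    "bending",
    "lateroflexion",
    "rotation",
    "shoulder_flexion",
    "shoulder_abduction",
    "neutral",
    "task",
)

TRIAL_KINDS = ("segment_calibration", "load_trial", "work_task")
TASK_LABELS = ("light", "heavy", "static", "dynamic", "heavy_dynamic", "none")


class ValidationError(ValueError):
    """A domain invariant was violated."""


class LoadError(IOError):
    """A session could not be read from disk."""


def _as_float_array(x, name: str, shape_tail: tuple = ()) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if shape_tail and arr.shape[1:] != shape_tail:
        raise ValidationError(f"{name}: expected trailing shape {shape_tail}, got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        bad = int(np.argwhere(~np.isfinite(arr))[0][0])
        raise ValidationError(f"{name}: non-finite value at sample {bad}")
    return arr


def _check_uniform(t: np.ndarray, dt: float, name: str, tol: float = 1e-9) -> None:
    if len(t) > 1:
        dts = np.diff(t)
        bad = np.nonzero(np.abs(dts - dt) > tol)[0]
        if bad.size:
            raise ValidationError(
                f"{name}: sample spacing {dts[bad[0]]:.6g} s at index {int(bad[0])} "
                f"(expected {dt:.6g} s); streams must be gap-free"
            )


@dataclass(frozen=True)
class SubjectInfo:
    """Subject descriptives used to scale the body model."""

    id: str
    height: float  # m
    mass: float  # kg
    handedness: str = "right"

    def __post_init__(self):
        if not 1.0 < self.height < 2.5:
            raise ValidationError(f"height {self.height} m outside (1.0, 2.5)")
        if not 30.0 < self.mass < 200.0:
            raise ValidationError(f"mass {self.mass} kg outside (30, 200)")
        if self.handedness not in ("left", "right"):
            raise ValidationError(f"handedness {self.handedness!r}")


@dataclass
class ImmuStream:
    """One IMMU's kinematics at 50 Hz.

    ``quat`` is the casing (or, after calibration, segment) orientation as a
    unit quaternion (w, x, y, z) mapping sensor-frame vectors to the global
    frame; ``angvel`` (rad/s) and ``linacc`` (specific force, m/s²) are
    expressed in the sensor frame.
    """

    site: str
    t: np.ndarray
    quat: np.ndarray  # (N, 4) scalar-first
    angvel: np.ndarray  # (N, 3)
    linacc: np.ndarray  # (N, 3)

    def __post_init__(self):
        if self.site not in IMMU_SITES:
            raise ValidationError(f"unknown IMMU site {self.site!r}")
        self.t = _as_float_array(self.t, f"{self.site}.t")
        self.quat = _as_float_array(self.quat, f"{self.site}.quat", (4,))
        self.angvel = _as_float_array(self.angvel, f"{self.site}.angvel", (3,))
        self.linacc = _as_float_array(self.linacc, f"{self.site}.linacc", (3,))
        n = len(self.t)
        for name in ("quat", "angvel", "linacc"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"{self.site}.{name}: length mismatch with t")
        _check_uniform(self.t, DT, f"{self.site}.t")
        norms = np.linalg.norm(self.quat, axis=1)
        bad = np.nonzero(np.abs(norms - 1.0) > 1e-6)[0]
        if bad.size:
            raise ValidationError(
                f"{self.site}.quat: norm {norms[bad[0]]:.8f} at sample {int(bad[0])}"
            )

    def __len__(self) -> int:
        return len(self.t)

    def copy(self) -> "ImmuStream":
        return ImmuStream(
            self.site, self.t.copy(), self.quat.copy(), self.angvel.copy(), self.linacc.copy()
        )


@dataclass
class EmgStream:
    """One bipolar sEMG channel: raw signal plus 50 Hz amplitude envelope."""

    channel: str
    t_raw: np.ndarray
    raw: np.ndarray
    t_env: np.ndarray | None = None
    envelope: np.ndarray | None = None

    def __post_init__(self):
        if self.channel not in EMG_CHANNELS:
            raise ValidationError(f"unknown EMG channel {self.channel!r}")
        self.t_raw = _as_float_array(self.t_raw, f"{self.channel}.t_raw")
        self.raw = _as_float_array(self.raw, f"{self.channel}.raw")
        if len(self.t_raw) != len(self.raw):
            raise ValidationError(f"{self.channel}: t_raw/raw length mismatch")
        if len(self.t_raw) > 1:
            dt = float(np.median(np.diff(self.t_raw)))
            if dt <= 0 or 1.0 / dt < 500.0 - 1e-6:
                raise ValidationError(
                    f"{self.channel}: raw rate {1.0 / dt if dt > 0 else 0:.1f} Hz < 500 Hz"
                )
        if self.envelope is not None:
            self.t_env = _as_float_array(self.t_env, f"{self.channel}.t_env")
            self.envelope = _as_float_array(self.envelope, f"{self.channel}.envelope")
            if np.any(self.envelope < 0):
                bad = int(np.argmax(self.envelope < 0))
                raise ValidationError(f"{self.channel}.envelope negative at sample {bad}")

    @property
    def raw_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t_raw)))

    def copy(self) -> "EmgStream":
        return EmgStream(
            self.channel,
            self.t_raw.copy(),
            self.raw.copy(),
            None if self.t_env is None else self.t_env.copy(),
            None if self.envelope is None else self.envelope.copy(),
        )


@dataclass
class NetMomentSeries:
    """3D net moment at L5/S1 on the 50 Hz grid.

    Sign conventions: Mx positive = lateroflexion to the left, My positive =
    forward flexion, Mz positive = rotation to the left. ``norm`` is the
    per-sample Euclidean norm of (Mx, My, Mz).
    """

    t: np.ndarray
    Mx: np.ndarray
    My: np.ndarray
    Mz: np.ndarray

    def __post_init__(self):
        self.t = _as_float_array(self.t, "moment.t")
        self.Mx = _as_float_array(self.Mx, "moment.Mx")
        self.My = _as_float_array(self.My, "moment.My")
        self.Mz = _as_float_array(self.Mz, "moment.Mz")
        n = len(self.t)
        if not (len(self.Mx) == len(self.My) == len(self.Mz) == n):
            raise ValidationError("moment: component length mismatch")

    @property
    def norm(self) -> np.ndarray:
        return np.sqrt(self.Mx**2 + self.My**2 + self.Mz**2)

    def as_array(self) -> np.ndarray:
        """(N, 3) array of (Mx, My, Mz)."""
        return np.column_stack([self.Mx, self.My, self.Mz])

    def component(self, axis: str) -> np.ndarray:
        return {"x": self.Mx, "y": self.My, "z": self.Mz, "norm": self.norm}[axis]

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class Trial:
    """One recorded trial with its sensor streams.

    ``truth_moment`` is only ever present on simulator output, where the
    noise-free ground-truth L5/S1 moment is known.
    """

    id: str
    kind: str
    movement: str
    load_mass: float = 0.0
    task_label: str = "none"
    checklist_rank: int | None = None
    borg: float | None = None
    immu: dict[str, ImmuStream] = field(default_factory=dict)
    emg: dict[str, EmgStream] = field(default_factory=dict)
    truth_moment: NetMomentSeries | None = None

    def __post_init__(self):
        if self.kind not in TRIAL_KINDS:
            raise ValidationError(f"trial {self.id}: unknown kind {self.kind!r}")
        if self.movement not in MOVEMENTS:
            raise ValidationError(f"trial {self.id}: unknown movement {self.movement!r}")
        if self.task_label not in TASK_LABELS:
            raise ValidationError(f"trial {self.id}: unknown task label {self.task_label!r}")
        if self.kind == "load_trial" and self.load_mass not in (0.0, 6.0, 10.0):
            raise ValidationError(
                f"trial {self.id}: load trial mass {self.load_mass} not in {{0, 6, 10}} kg"
            )
        if self.borg is not None and not 0.0 <= self.borg <= 10.0:
            raise ValidationError(f"trial {self.id}: Borg {self.borg} outside [0, 10]")
        if self.checklist_rank is not None and not 1 <= int(self.checklist_rank) <= 5:
            raise ValidationError(f"trial {self.id}: checklist rank {self.checklist_rank}")


@dataclass
class SegmentCalibration:
    """Fixed sensor-casing → body-segment rotations from phase-1 movements."""

    rotations: dict[str, np.ndarray]  # site -> unit quaternion (w,x,y,z), sensor->segment
    residual_deg: dict[str, float]
    source_trials: list[str] = field(default_factory=list)

    def __post_init__(self):
        for site, q in self.rotations.items():
            q = np.asarray(q, dtype=float)
            if q.shape != (4,) or abs(np.linalg.norm(q) - 1.0) > 1e-6:
                raise ValidationError(f"calibration for {site}: not a unit quaternion")
            self.rotations[site] = q
        for site, r in self.residual_deg.items():
            if r < 0:
                raise ValidationError(f"calibration residual for {site} negative")


@dataclass
class Session:
    """A full measurement session: subject, ordered trials, derived state."""

    subject: SubjectInfo
    trials: list[Trial] = field(default_factory=list)
    sync_offsets: dict[str, float] = field(default_factory=dict)
    calibration: SegmentCalibration | None = None

    def __post_init__(self):
        n_cal_blocks = sum(1 for tr in self.trials if tr.kind == "segment_calibration")
        # one calibration *block*: calibration trials must be contiguous and lead
        kinds = [tr.kind for tr in self.trials]
        if n_cal_blocks:
            first = kinds.index("segment_calibration")
            last = len(kinds) - 1 - kinds[::-1].index("segment_calibration")
            if any(k != "segment_calibration" for k in kinds[first : last + 1]):
                raise ValidationError("segment-calibration trials must form one block")
        for off in self.sync_offsets.values():
            if not np.isfinite(off):
                raise ValidationError("non-finite sync offset")
        ids = [tr.id for tr in self.trials]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate trial ids")

    def trial(self, trial_id: str) -> Trial:
        for tr in self.trials:
            if tr.id == trial_id:
                return tr
        raise KeyError(trial_id)

    def trials_of_kind(self, kind: str) -> list[Trial]:
        return [tr for tr in self.trials if tr.kind == kind]

    def load_trials(self, masses: tuple[float, ...] | None = None) -> list[Trial]:
        out = self.trials_of_kind("load_trial")
        if masses is not None:
            out = [tr for tr in out if tr.load_mass in masses]
        return out


__all__ = [
    "SAMPLE_RATE",
    "DT",
    "GRAVITY",
    "IMMU_SITES",
    "EMG_CHANNELS",
    "MOVEMENTS",
    "ValidationError",
    "LoadError",
    "SubjectInfo",
    "ImmuStream",
    "EmgStream",
    "NetMomentSeries",
    "Trial",
    "SegmentCalibration",
    "Session",
]
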