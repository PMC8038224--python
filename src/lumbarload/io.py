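"""On-disk session format: YAML manifest plus one CSV per stream.

Human-inspectable, diff-able layout:

* ``session.yaml`` — subject block, sync offsets, optional calibration,
  trial list with per-trial stream file names.
* IMMU streams — ``t,qw,qx,qy,qz,wx,wy,wz,ax,ay,az``
* raw EMG — ``t,value`` (envelope, when present, in a separate ``t,value``
  file on the 50 Hz grid)
* moments — ``t,Mx,My,Mz``

Floats are written with 17 significant digits, so write → read → write is
byte-identical and float64 values round-trip exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .types import (
    EmgStream,
    ImmuStream,
    LoadError,
    NetMomentSeries,
    SegmentCalibration,
    Session,
    SubjectInfo,
    Trial,
)

_FMT = "%.17g"


def _write_csv(path: Path, header: str, columns: list[np.ndarray]) -> None:
    data = np.column_stack(columns)
    np.savetxt(path, data, fmt=_FMT, delimiter=",", header=header, comments="")


def _read_csv(path: Path, n_cols: int, what: str) -> np.ndarray:
    if not path.exists():
        raise LoadError(f"missing stream file for {what}: {path.name}")
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if data.shape[1] != n_cols:
        raise LoadError(f"{path.name}: expected {n_cols} columns, found {data.shape[1]}")
    return data


def write_session(session: Session, path) -> None:
    """Write a session directory (manifest + stream CSVs)."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "subject": {
            "id": session.subject.id,
            "height": session.subject.height,
            "mass": session.subject.mass,
            "handedness": session.subject.handedness,
        },
        "sync_offsets": {k: float(v) for k, v in session.sync_offsets.items()},
        "trials": [],
    }
    if session.calibration is not None:
        manifest["calibration"] = {
            "rotations": {
                site: [float(x) for x in q] for site, q in session.calibration.rotations.items()
            },
            "residual_deg": {
                site: float(r) for site, r in session.calibration.residual_deg.items()
            },
            "source_trials": list(session.calibration.source_trials),
        }
    for trial in session.trials:
        entry: dict = {
            "id": trial.id,
            "kind": trial.kind,
            "movement": trial.movement,
            "load_mass": float(trial.load_mass),
            "task_label": trial.task_label,
            "checklist_rank": trial.checklist_rank,
            "borg": None if trial.borg is None else float(trial.borg),
            "immu": {},
            "emg": {},
            "emg_env": {},
            "truth": None,
        }
        for site, s in trial.immu.items():
            fname = f"{trial.id}__immu_{site}.csv"
            _write_csv(
                root / fname,
                "t,qw,qx,qy,qz,wx,wy,wz,ax,ay,az",
                [s.t, s.quat, s.angvel, s.linacc],
            )
            entry["immu"][site] = fname
        for ch, s in trial.emg.items():
            fname = f"{trial.id}__emg_{ch}.csv"
            _write_csv(root / fname, "t,value", [s.t_raw, s.raw])
            entry["emg"][ch] = fname
            if s.envelope is not None:
                ename = f"{trial.id}__env_{ch}.csv"
                _write_csv(root / ename, "t,value", [s.t_env, s.envelope])
                entry["emg_env"][ch] = ename
        if trial.truth_moment is not None:
            fname = f"{trial.id}__truth.csv"
            m = trial.truth_moment
            _write_csv(root / fname, "t,Mx,My,Mz", [m.t, m.Mx, m.My, m.Mz])
            entry["truth"] = fname
        manifest["trials"].append(entry)
    with open(root / "session.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def read_session(path) -> Session:
    """Read and fully validate a session directory."""
    root = Path(path)
    manifest_path = root / "session.yaml"
    if not manifest_path.exists():
        raise LoadError(f"no session.yaml in {root}")
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)

    sub = manifest["subject"]
    subject = SubjectInfo(
        id=str(sub["id"]),
        height=float(sub["height"]),
        mass=float(sub["mass"]),
        handedness=sub.get("handedness", "right"),
    )
    trials = []
    for entry in manifest.get("trials", []):
        tid = entry["id"]
        immu = {}
        for site, fname in (entry.get("immu") or {}).items():
            data = _read_csv(root / fname, 11, f"trial {tid} IMMU {site}")
            immu[site] = ImmuStream(
                site=site,
                t=data[:, 0],
                quat=data[:, 1:5],
                angvel=data[:, 5:8],
                linacc=data[:, 8:11],
            )
        emg = {}
        for ch, fname in (entry.get("emg") or {}).items():
            data = _read_csv(root / fname, 2, f"trial {tid} EMG {ch}")
            t_env = envelope = None
            ename = (entry.get("emg_env") or {}).get(ch)
            if ename:
                env = _read_csv(root / ename, 2, f"trial {tid} EMG envelope {ch}")
                t_env, envelope = env[:, 0], env[:, 1]
            emg[ch] = EmgStream(
                channel=ch, t_raw=data[:, 0], raw=data[:, 1], t_env=t_env, envelope=envelope
            )
        truth = None
        if entry.get("truth"):
            data = _read_csv(root / entry["truth"], 4, f"trial {tid} truth moment")
            truth = NetMomentSeries(t=data[:, 0], Mx=data[:, 1], My=data[:, 2], Mz=data[:, 3])
        trials.append(
            Trial(
                id=tid,
                kind=entry["kind"],
                movement=entry["movement"],
                load_mass=float(entry.get("load_mass") or 0.0),
                task_label=entry.get("task_label") or "none",
                checklist_rank=entry.get("checklist_rank"),
                borg=entry.get("borg"),
                immu=immu,
                emg=emg,
                truth_moment=truth,
            )
        )
    calibration = None
    if "calibration" in manifest:
        cal = manifest["calibration"]
        calibration = SegmentCalibration(
            rotations={site: np.asarray(q, dtype=float) for site, q in cal["rotations"].items()},
            residual_deg={site: float(r) for site, r in cal["residual_deg"].items()},
            source_trials=list(cal.get("source_trials", [])),
        )
    return Session(
        subject=subject,
        trials=trials,
        sync_offsets={k: float(v) for k, v in (manifest.get("sync_offsets") or {}).items()},
        calibration=calibration,
    )


def sessions_equal(a: Session, b: Session) -> bool:
    """Exact equality of two sessions (streams compared bitwise)."""
    if a.subject != b.subject or len(a.trials) != len(b.trials):
        return False
    if a.sync_offsets != b.sync_offsets:
        return False
    for ta, tb in zip(a.trials, b.trials):
        if (ta.id, ta.kind, ta.movement, ta.load_mass, ta.task_label) != (
            tb.id,
            tb.kind,
            tb.movement,
            tb.load_mass,
            tb.task_label,
        ):
            return False
        if ta.checklist_rank != tb.checklist_rank or ta.borg != tb.borg:
            return False
        if set(ta.immu) != set(tb.immu) or set(ta.emg) != set(tb.emg):
            return False
        for site in ta.immu:
            sa, sb = ta.immu[site], tb.immu[site]
            if not all(
                np.array_equal(getattr(sa, f), getattr(sb, f))
                for f in ("t", "quat", "angvel", "linacc")
            ):
                return False
        for ch in ta.emg:
            sa, sb = ta.emg[ch], tb.emg[ch]
            if not (np.array_equal(sa.t_raw, sb.t_raw) and np.array_equal(sa.raw, sb.raw)):
                return False
        if (ta.truth_moment is None) != (tb.truth_moment is None):
            return False
        if ta.truth_moment is not None:
            ma, mb = ta.truth_moment, tb.truth_moment
            if not all(
                np.array_equal(getattr(ma, f), getattr(mb, f)) for f in ("t", "Mx", "My", "Mz")
            ):
                return False
    return True


__all__ = ["write_session", "read_session", "sessions_equal"]
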