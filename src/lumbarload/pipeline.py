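"""End-to-end pipeline: calibrate → synchronize → envelopes → LSM targets →
ANN training → estimation → discriminant-validity report.

The pipeline runs per subject: the phase-1 movements calibrate the
sensor-to-segment rotations; phase-2 known-load trials provide supervised
targets (training on the 0 and 10 kg trials, evaluation on the held-out
6 kg trials; the phase-3 network retrains on all three loads); phase-3 work
tasks are scored with the trained network and summarized with the paired
task contrasts and direction-split tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .types import Session, SubjectInfo, ValidationError
from .io import read_session
from .signals import EnvelopeParams, synchronize
from .calibration import apply_calibration, estimate_segment_frames
from .lsm import LoadSpec, lsm_net_moment, scale_body_model
from .ann import MomentEstimator, build_feature_matrix, predict_moments
from .simulate import simulate_session
from .stats import (
    SubjectResults,
    ValidityReport,
    build_report,
    compare_curves,
    direction_split,
    select_tasks,
    task_descriptives,
)

logger = logging.getLogger("lumbarload")

_MOVEMENTS_PHASE2 = ("bending", "lateroflexion", "rotation")


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    Either ``session_paths`` (directories in the documented on-disk format)
    or simulator settings (``n_subjects`` sessions from ``seed``) name the
    session source.
    """

    session_paths: list[str] = field(default_factory=list)
    n_subjects: int = 1
    seed: int = 0
    subject_height: float = 1.85
    subject_mass: float = 93.0
    output_dir: str | None = None
    use_linacc: bool = True
    envelope: EnvelopeParams = field(default_factory=EnvelopeParams)
    train_masses: tuple[float, ...] = (0.0, 10.0)
    eval_mass: float = 6.0
    phase3_masses: tuple[float, ...] = (0.0, 6.0, 10.0)
    max_epochs: int = 2000
    restarts: int = 3


def prepare_session(
    session: Session, envelope: EnvelopeParams = EnvelopeParams()
) -> Session:
    """Synchronize, calibrate and express all streams in segment frames.

    Mutates and returns the session: EMG envelopes land on the IMMU 50 Hz
    grid, ``sync_offsets`` and ``calibration`` are filled in, and IMMU
    streams are replaced by their segment-frame versions.
    """
    synchronize(session, envelope)
    cal_trials = session.trials_of_kind("segment_calibration")
    if not cal_trials:
        raise ValidationError("session has no segment-calibration trials")
    calib = estimate_segment_frames(cal_trials)
    session.calibration = calib
    for trial in session.trials:
        trial.immu = {
            site: apply_calibration(stream, calib) for site, stream in trial.immu.items()
        }
    return session


def analyze_session(session: Session, config: PipelineConfig, seed: int) -> SubjectResults:
    """Run calibration, training and validity analysis for one session."""
    body = scale_body_model(session.subject)
    load_trials = session.load_trials()
    if not any(tr.load_mass in config.train_masses for tr in load_trials):
        raise ValidationError("ANN training requires load trials")
    prepare_session(session, config.envelope)

    train_ids = [tr.id for tr in load_trials if tr.load_mass in config.train_masses]
    logger.info("training on %s", train_ids)
    est = MomentEstimator.from_session(
        session, train_ids, body, use_linacc=config.use_linacc
    ).fit(seed=seed, max_epochs=config.max_epochs, restarts=config.restarts)

    sr = SubjectResults(subject_id=session.subject.id)
    for trial in load_trials:
        if trial.load_mass != config.eval_mass:
            continue
        feats = build_feature_matrix(session, [trial.id])
        predicted = predict_moments(est.ann, feats)
        target = lsm_net_moment(
            trial.immu, body, LoadSpec(mass=trial.load_mass), use_linacc=config.use_linacc
        )
        n = min(len(predicted), len(target))
        predicted.Mx, predicted.My, predicted.Mz = (
            predicted.Mx[:n],
            predicted.My[:n],
            predicted.Mz[:n],
        )
        target.Mx, target.My, target.Mz = target.Mx[:n], target.My[:n], target.Mz[:n]
        predicted.t, target.t = predicted.t[:n], target.t[:n]
        sr.agreement[trial.movement] = compare_curves(predicted, target)
        logger.info(
            "trial %s movement-axis agreement: %s", trial.id, sr.agreement[trial.movement].r
        )

    work = session.trials_of_kind("work_task")
    if work:
        phase3_ids = [tr.id for tr in load_trials if tr.load_mass in config.phase3_masses]
        est3 = MomentEstimator.from_session(
            session, phase3_ids, body, use_linacc=config.use_linacc
        ).fit(seed=seed + 1, max_epochs=config.max_epochs, restarts=config.restarts)
        roles = select_tasks(session.trials)
        for role, tid in roles.items():
            trial = session.trial(tid)
            feats = build_feature_matrix(session, [tid])
            moments = predict_moments(est3.ann, feats)
            sr.tasks[role] = task_descriptives(trial, moments)
            sr.direction[role] = {
                axis: direction_split(moments, axis) for axis in ("norm", "x", "y", "z")
            }
    return sr


def run_pipeline(config: PipelineConfig) -> ValidityReport:
    """Execute the full chain and build the report tables.

    Any stage failure propagates annotated with the subject and stage.
    """
    results = []
    if config.session_paths:
        sources = [("load", p) for p in config.session_paths]
    else:
        sources = [("simulate", i) for i in range(config.n_subjects)]
    for idx, (kind, src) in enumerate(sources):
        if kind == "load":
            session = read_session(src)
        else:
            session = simulate_session(
                subject=SubjectInfo(
                    id=f"sim{config.seed + src:04d}",
                    height=config.subject_height,
                    mass=config.subject_mass,
                ),
                seed=config.seed + src,
            )
        logger.info("analyzing session %s", session.subject.id)
        try:
            results.append(analyze_session(session, config, seed=config.seed + 1000 + idx))
        except Exception as exc:
            raise type(exc)(f"[subject {session.subject.id}] {exc}") from exc
    report = build_report(results)
    if config.output_dir:
        report.save(Path(config.output_dir))
    return report


__all__ = ["PipelineConfig", "prepare_session", "analyze_session", "run_pipeline"]
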