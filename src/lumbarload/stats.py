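"""Discriminant-validity statistics for estimated lumbar moments.

Curve agreement (per-axis RMSE, Pearson r/r² with the conventional
qualitative bands), task descriptives (mean, peak and within-trial SD of the
moment norm), direction-split analysis (sign-partitioned component
descriptives exposing asymmetric loading), normality-gated paired testing
(Shapiro–Wilk deciding between the paired t-test and the Wilcoxon
signed-rank test), task selection from checklist ranks and posture
variability, and the cohort report tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst
from scipy.spatial.transform import Rotation

from .types import NetMomentSeries, Trial, ValidationError

#: Pearson-r qualitative cutpoints: weak < 0.5 <= moderate < 0.7 <= good
#: < 0.9 <= very_good
R_BANDS = ((0.9, "very_good"), (0.7, "good"), (0.5, "moderate"), (-np.inf, "weak"))

#: static-task criterion: lumbar posture unchanged for at least this long
STATIC_WINDOW_S = 4.0
#: posture excursion regarded as "unchanged", deg
STATIC_EXCURSION_DEG = 5.0
#: minimum overall excursion for a lifting (dynamic) task, deg
DYNAMIC_EXCURSION_DEG = 30.0


def r_band(r: float) -> str | None:
    if not np.isfinite(r):
        return None
    for cut, name in R_BANDS:
        if r > cut:
            return name
    return "weak"


@dataclass
class AgreementResult:
    """Curve agreement between estimated and target moments."""

    rmse: dict[str, float]  # per axis + 'norm', Nm
    r: dict[str, float]  # per axis; NaN where undefined
    r2: dict[str, float]
    band: dict[str, str | None]


def compare_curves(estimated: NetMomentSeries, target: NetMomentSeries) -> AgreementResult:
    """RMSE and Pearson r/r² per axis plus norm-channel RMSE.

    A zero-variance channel has undefined correlation and is reported as NaN
    (band ``None``), never coerced to 0.
    """
    if len(estimated) != len(target):
        raise ValidationError("estimated and target series differ in length")
    rmse, r, r2, band = {}, {}, {}, {}
    for axis in ("x", "y", "z"):
        e, g = estimated.component(axis), target.component(axis)
        rmse[axis] = float(np.sqrt(np.mean((e - g) ** 2)))
        if np.std(e) == 0 or np.std(g) == 0:
            r[axis] = float("nan")
        else:
            r[axis] = float(sst.pearsonr(e, g).statistic)
        r2[axis] = r[axis] ** 2
        band[axis] = r_band(r[axis])
    rmse["norm"] = float(np.sqrt(np.mean((estimated.norm - target.norm) ** 2)))
    return AgreementResult(rmse=rmse, r=r, r2=r2, band=band)


@dataclass
class TaskDescriptives:
    """Mean, peak (max) and variance (within-trial SD) of the moment norm."""

    mean: float
    peak: float
    variance: float  # sample SD (n-1) of ||M|| within the trial, Nm
    borg: float | None = None
    checklist_rank: int | None = None


def task_descriptives(trial: Trial, moments: NetMomentSeries) -> TaskDescriptives:
    if len(moments) == 0:
        raise ValidationError(f"trial {trial.id}: empty moment series")
    norm = moments.norm
    return TaskDescriptives(
        mean=float(np.mean(norm)),
        peak=float(np.max(norm)),
        variance=float(np.std(norm, ddof=1)) if len(norm) > 1 else 0.0,
        borg=trial.borg,
        checklist_rank=trial.checklist_rank,
    )


@dataclass
class DirectionSplit:
    """Sign-partitioned descriptives of one moment channel.

    Samples are assigned by the sign of the split component; exact zeros
    belong to neither segment. An empty segment's descriptives are ``None``
    (absent), never zero.
    """

    axis: str
    positive: TaskDescriptives | None
    negative: TaskDescriptives | None
    n_positive: int
    n_negative: int


def _segment_descriptives(values: np.ndarray) -> TaskDescriptives | None:
    if values.size == 0:
        return None
    peak = values[np.argmax(np.abs(values))]
    return TaskDescriptives(
        mean=float(np.mean(values)),
        peak=float(peak),
        variance=float(np.std(values, ddof=1)) if values.size > 1 else 0.0,
    )


def direction_split(
    moments: NetMomentSeries, axis: str, split_axis: str | None = None
) -> DirectionSplit:
    """Partition a channel by movement direction and describe each side.

    For the signed axes x/y/z the channel's own sign defines the partition.
    The norm is nonnegative, so for ``axis='norm'`` the sign of ``split_axis``
    is used — or, when none is given, the sign of the per-sample dominant
    component (the axis with the largest magnitude at that sample).
    """
    if axis not in ("x", "y", "z", "norm"):
        raise ValidationError(f"axis {axis!r} not in x/y/z/norm")
    values = moments.component(axis)
    if axis == "norm":
        if split_axis is not None:
            signs = np.sign(moments.component(split_axis))
        else:
            comps = moments.as_array()
            dominant = np.argmax(np.abs(comps), axis=1)
            signs = np.sign(comps[np.arange(len(comps)), dominant])
    else:
        signs = np.sign(values)
    pos = values[signs > 0]
    neg = values[signs < 0]
    return DirectionSplit(
        axis=axis,
        positive=_segment_descriptives(pos),
        negative=_segment_descriptives(neg),
        n_positive=int(pos.size),
        n_negative=int(neg.size),
    )


@dataclass
class PairedComparison:
    """Paired difference summary: MD ± SDD, CI, normality-gated test."""

    MD: float
    SDD: float
    CI95: tuple[float, float]
    p: float
    test_used: str  # 'paired_t' or 'wilcoxon'
    normality_p: float
    n: int
    #: mean of per-subject percentage differences (relative to values_A)
    MD_rel: float = float("nan")
    SDD_rel: float = float("nan")
    CI95_rel: tuple[float, float] = (float("nan"), float("nan"))
    #: 100 * MD / mean(values_A) — the alternative relative summary
    MD_rel_of_means: float = float("nan")


def _ci_mean(d: np.ndarray, alpha: float) -> tuple[float, float]:
    n = len(d)
    md, sd = float(np.mean(d)), float(np.std(d, ddof=1))
    if sd == 0:
        return (md, md)
    half = sst.t.ppf(1 - alpha / 2, n - 1) * sd / np.sqrt(n)
    return (md - half, md + half)


def paired_comparison(
    values_A: np.ndarray, values_B: np.ndarray, alpha: float = 0.05
) -> PairedComparison:
    """Compare paired per-subject values; MD is ``mean(B − A)``.

    The Shapiro–Wilk test on the paired differences gates the test choice:
    normal (p > 0.05) → paired t-test, otherwise Wilcoxon signed-rank. The
    gate p-value is recorded so either reading can be audited.
    """
    a = np.asarray(values_A, dtype=float)
    b = np.asarray(values_B, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("paired vectors must be 1-D and equal length")
    n = len(a)
    if n < 3:
        raise ValidationError(f"paired comparison needs n >= 3, got {n}")
    d = b - a
    md, sdd = float(np.mean(d)), float(np.std(d, ddof=1))
    ci = _ci_mean(d, alpha)

    if np.all(d == d[0]):  # zero-variance differences
        norm_p = float("nan")
        p = 1.0 if sdd == 0 else 0.0
        test = "paired_t"
    else:
        norm_p = float(sst.shapiro(d).pvalue)
        if norm_p > 0.05:
            test = "paired_t"
            p = float(sst.ttest_rel(b, a).pvalue)
        else:
            test = "wilcoxon"
            p = float(sst.wilcoxon(b, a).pvalue)

    with np.errstate(divide="ignore", invalid="ignore"):
        rel = 100.0 * d / a
    rel = rel[np.isfinite(rel)]
    if rel.size >= 2:
        md_rel, sdd_rel = float(np.mean(rel)), float(np.std(rel, ddof=1))
        ci_rel = _ci_mean(rel, alpha)
    else:
        md_rel = sdd_rel = float("nan")
        ci_rel = (float("nan"), float("nan"))
    mean_a = float(np.mean(a))
    rel_of_means = 100.0 * md / mean_a if mean_a != 0 else float("nan")
    return PairedComparison(
        MD=md,
        SDD=sdd,
        CI95=ci,
        p=p,
        test_used=test,
        normality_p=norm_p,
        n=n,
        MD_rel=md_rel,
        SDD_rel=sdd_rel,
        CI95_rel=ci_rel,
        MD_rel_of_means=rel_of_means,
    )


# ---------------------------------------------------------------------------
# task selection


def _inclination_deg(trial: Trial) -> np.ndarray:
    """Lumbar inclination proxy: angle of the sternum z-axis from vertical."""
    if "sternum" not in trial.immu:
        raise ValidationError(f"trial {trial.id}: no sternum stream for posture analysis")
    q = trial.immu["sternum"].quat
    R = Rotation.from_quat(q[:, [1, 2, 3, 0]])
    z_world = R.apply(np.tile([0.0, 0.0, 1.0], (len(q), 1)))
    return np.degrees(np.arccos(np.clip(z_world[:, 2], -1.0, 1.0)))


def _posture_class(trial: Trial) -> str:
    """'static' (≥ 4 s unchanged posture for most of the trial), 'dynamic'
    (large-excursion lifting), or 'varied'."""
    ang = _inclination_deg(trial)
    fs = 1.0 / float(np.median(np.diff(trial.immu["sternum"].t)))
    w = int(round(STATIC_WINDOW_S * fs))
    covered = np.zeros(len(ang), dtype=bool)
    if len(ang) >= w:
        windows = np.lib.stride_tricks.sliding_window_view(ang, w)
        still = windows.max(axis=1) - windows.min(axis=1) < STATIC_EXCURSION_DEG
        for i in np.nonzero(still)[0]:
            covered[i : i + w] = True
    if covered.mean() >= 0.5:
        return "static"
    if np.ptp(ang) >= DYNAMIC_EXCURSION_DEG:
        return "dynamic"
    return "varied"


def select_tasks(trials: list[Trial]) -> dict[str, str]:
    """Select light/heavy/static/dynamic tasks from the work-task trials.

    Light/heavy are the lowest/highest checklist rank (ties broken by Borg,
    then trial order); static/dynamic come from the posture-variability
    criterion. A combined heavy-and-dynamic trial may serve as both heavy
    and dynamic.
    """
    work = [tr for tr in trials if tr.kind == "work_task"]
    if not work:
        raise ValidationError("no work tasks in session")
    ranked = [tr for tr in work if tr.checklist_rank is not None]
    if not ranked:
        raise ValidationError("work tasks carry no checklist ranks")

    def keyfun(reverse: bool):
        def key(item):
            i, tr = item
            borg = tr.borg if tr.borg is not None else 0.0
            return (tr.checklist_rank, -borg if reverse else borg, i)

        return key

    indexed = list(enumerate(ranked))
    light = min(indexed, key=keyfun(reverse=False))[1]
    heavy = max(indexed, key=lambda it: (it[1].checklist_rank, it[1].borg or 0.0, -it[0]))[1]

    static = dynamic = None
    for tr in work:
        cls = _posture_class(tr)
        if cls == "static" and static is None:
            static = tr
        elif cls == "dynamic" and dynamic is None:
            dynamic = tr
    if static is None:
        raise ValidationError("no static task (no trial holds its lumbar posture >= 4 s)")
    if dynamic is None:
        raise ValidationError("no dynamic task (no lifting trial with varying posture)")
    return {"light": light.id, "heavy": heavy.id, "static": static.id, "dynamic": dynamic.id}


# ---------------------------------------------------------------------------
# report tables


@dataclass
class SubjectResults:
    """Per-subject ingredients for the cohort report."""

    subject_id: str
    #: movement -> AgreementResult on the 6 kg evaluation trial
    agreement: dict[str, AgreementResult] = field(default_factory=dict)
    #: task label -> TaskDescriptives of the ANN-estimated moments
    tasks: dict[str, TaskDescriptives] = field(default_factory=dict)
    #: task label -> {axis -> DirectionSplit}
    direction: dict[str, dict[str, DirectionSplit]] = field(default_factory=dict)


@dataclass
class ValidityReport:
    """Report tables of the full analysis chain."""

    tables: dict[str, pd.DataFrame]
    provenance: list[str] = field(default_factory=list)

    def save(self, directory) -> None:
        from pathlib import Path

        out = Path(directory)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(out / f"{name}.csv")


_MOVEMENT_AXIS = {"bending": "y", "lateroflexion": "x", "rotation": "z"}


def _paired_rows(
    results: list[SubjectResults],
    task_a: str,
    task_b: str,
    getter,
    params=("mean", "peak", "variance"),
) -> pd.DataFrame:
    rows = {}
    for param in params:
        a, b = [], []
        for sr in results:
            da, db = getter(sr, task_a), getter(sr, task_b)
            if da is None or db is None:
                continue
            va, vb = getattr(da, param, None), getattr(db, param, None)
            if va is None or vb is None:
                continue
            a.append(va)
            b.append(vb)
        if len(a) >= 3:
            pc = paired_comparison(np.array(a), np.array(b))
            rows[param] = {
                "MD": pc.MD,
                "SDD": pc.SDD,
                "CI_low": pc.CI95[0],
                "CI_high": pc.CI95[1],
                "MD_rel_pct": pc.MD_rel,
                "SDD_rel_pct": pc.SDD_rel,
                "CI_rel_low": pc.CI95_rel[0],
                "CI_rel_high": pc.CI95_rel[1],
                "p": pc.p,
                "test": pc.test_used,
                "n": pc.n,
            }
        elif a:
            d = np.array(b) - np.array(a)
            rows[param] = {
                "MD": float(np.mean(d)),
                "SDD": float(np.std(d, ddof=1)) if len(d) > 1 else 0.0,
                "CI_low": np.nan,
                "CI_high": np.nan,
                "MD_rel_pct": np.nan,
                "SDD_rel_pct": np.nan,
                "CI_rel_low": np.nan,
                "CI_rel_high": np.nan,
                "p": np.nan,
                "test": "none (n < 3)",
                "n": len(a),
            }
    return pd.DataFrame(rows).T


def build_report(results: list[SubjectResults]) -> ValidityReport:
    """Assemble the cohort report tables from per-subject results.

    Mean columns are the plain means of the per-subject cells; paired
    contrasts (light vs heavy, static vs dynamic, direction splits) use the
    normality-gated paired tests when at least three subjects contribute.
    """
    if not results:
        raise ValidationError("no subject results")
    subjects = [sr.subject_id for sr in results]
    provenance = []

    # agreement (movement-axis r and r2 per subject)
    rows = {}
    for movement, axis in _MOVEMENT_AXIS.items():
        for metric in ("r", "r2"):
            vals = []
            for sr in results:
                ag = sr.agreement.get(movement)
                vals.append(getattr(ag, metric)[axis] if ag else np.nan)
            arr = np.asarray(vals, dtype=float)
            ok = arr[np.isfinite(arr)]
            rows[(movement, axis, metric)] = dict(zip(subjects, vals)) | {
                "Mean": float(np.mean(ok)) if ok.size else np.nan,
                "SDD": float(np.std(ok, ddof=1)) if ok.size > 1 else np.nan,
            }
    agreement = pd.DataFrame(rows).T
    agreement.index.names = ["movement", "axis", "metric"]
    provenance.append("agreement_by_subject: movement-axis r/r2 on 6 kg evaluation trials")

    rows = {}
    for movement in _MOVEMENT_AXIS:
        for axis in ("x", "y", "z"):
            vals = []
            for sr in results:
                ag = sr.agreement.get(movement)
                vals.append(ag.rmse[axis] if ag else np.nan)
            arr = np.asarray(vals, dtype=float)
            ok = arr[np.isfinite(arr)]
            rows[(movement, axis)] = dict(zip(subjects, vals)) | {
                "Mean": float(np.mean(ok)) if ok.size else np.nan,
                "SDD": float(np.std(ok, ddof=1)) if ok.size > 1 else np.nan,
            }
    rmse_table = pd.DataFrame(rows).T
    rmse_table.index.names = ["movement", "axis"]
    provenance.append("rmse_by_movement_axis: per-axis RMSE (Nm) on 6 kg evaluation trials")

    # task descriptives
    task_labels = sorted({lbl for sr in results for lbl in sr.tasks})
    rows = {}
    for lbl in task_labels:
        row = {}
        for param in ("mean", "peak", "variance", "checklist_rank", "borg"):
            vals = [
                getattr(sr.tasks[lbl], param)
                for sr in results
                if lbl in sr.tasks and getattr(sr.tasks[lbl], param) is not None
            ]
            row[param] = float(np.mean(vals)) if vals else np.nan
            row[f"{param}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan
        rows[lbl] = row
    task_table = pd.DataFrame(rows).T
    provenance.append("task_descriptives: ||M|| mean/peak/SD per task over subjects")

    def task_getter(sr: SubjectResults, label: str):
        return sr.tasks.get(label)

    light_heavy = _paired_rows(results, "light", "heavy", task_getter)
    lh_borg = _paired_rows(results, "light", "heavy", task_getter, params=("borg",))
    if not lh_borg.empty:
        light_heavy = pd.concat([light_heavy, lh_borg])
    static_dynamic = _paired_rows(results, "static", "dynamic", task_getter)
    sd_borg = _paired_rows(results, "static", "dynamic", task_getter, params=("borg",))
    if not sd_borg.empty:
        static_dynamic = pd.concat([static_dynamic, sd_borg])
    provenance.append("light_vs_heavy / static_vs_dynamic: MD = second minus first task")

    def split_frame(task_a: str, task_b: str) -> pd.DataFrame:
        frames = {}
        for direction in ("positive", "negative"):
            for axis in ("norm", "x", "y", "z"):
                def getter(sr: SubjectResults, label: str, _d=direction, _a=axis):
                    splits = sr.direction.get(label)
                    if not splits or _a not in splits:
                        return None
                    return getattr(splits[_a], _d)

                df = _paired_rows(
                    results, task_a, task_b,
                    lambda sr, lbl, _g=getter: _g(sr, lbl),
                    params=("mean", "variance"),
                )
                for param in df.index:
                    frames[(param, direction, axis)] = df.loc[param]
        out = pd.DataFrame(frames).T
        if not out.empty:
            out.index.names = ["parameter", "direction", "axis"]
        return out

    direction_lh = split_frame("light", "heavy")
    direction_sd = split_frame("static", "dynamic")
    provenance.append("direction tables: sign-partitioned component descriptives")

    return ValidityReport(
        tables={
            "agreement_by_subject": agreement,
            "rmse_by_movement_axis": rmse_table,
            "task_descriptives": task_table,
            "light_vs_heavy": light_heavy,
            "static_vs_dynamic": static_dynamic,
            "direction_light_heavy": direction_lh,
            "direction_static_dynamic": direction_sd,
        },
        provenance=provenance,
    )


__all__ = [
    "R_BANDS",
    "r_band",
    "AgreementResult",
    "TaskDescriptives",
    "DirectionSplit",
    "PairedComparison",
    "SubjectResults",
    "ValidityReport",
    "compare_curves",
    "task_descriptives",
    "direction_split",
    "paired_comparison",
    "select_tasks",
    "build_report",
]
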