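import numpy as np
import pytest
from scipy import stats as sst
from scipy.spatial.transform import Rotation

from lumbarload import DT, NetMomentSeries, Trial, ValidationError
from lumbarload.stats import (
    SubjectResults,
    build_report,
    compare_curves,
    direction_split,
    paired_comparison,
    r_band,
    select_tasks,
    task_descriptives,
)
from lumbarload.types import ImmuStream


def _series(mx, my, mz):
    n = len(mx)
    return NetMomentSeries(
        t=DT * np.arange(n),
        Mx=np.asarray(mx, dtype=float),
        My=np.asarray(my, dtype=float),
        Mz=np.asarray(mz, dtype=float),
    )


# ---------------------------------------------------------------- compare


def test_identity_agreement():
    rng = np.random.default_rng(0)
    m = _series(*rng.standard_normal((3, 200)))
    ag = compare_curves(m, m)
    assert all(v == 0 for v in ag.rmse.values())
    assert all(np.isclose(v, 1.0) for v in ag.r.values())
    assert all(b == "very_good" for b in ag.band.values())


def test_constant_offset_agreement():
    rng = np.random.default_rng(1)
    base = rng.standard_normal(300)
    target = _series(base, base, base)
    est = _series(base + 5.0, base + 5.0, base + 5.0)
    ag = compare_curves(est, target)
    for axis in ("x", "y", "z"):
        assert ag.rmse[axis] == pytest.approx(5.0)
        assert ag.r[axis] == pytest.approx(1.0)


def test_zero_variance_channel_reports_nan_not_zero():
    target = _series(np.zeros(50), np.arange(50), np.arange(50))
    est = _series(np.zeros(50), np.arange(50), np.arange(50))
    ag = compare_curves(est, target)
    assert np.isnan(ag.r["x"]) and ag.band["x"] is None


def test_compare_matches_bruteforce_oracle():
    rng = np.random.default_rng(7)
    a = _series(*rng.standard_normal((3, 64)))
    b = _series(*rng.standard_normal((3, 64)))
    ag = compare_curves(a, b)
    for axis in ("x", "y", "z"):
        e, g = a.component(axis), b.component(axis)
        rmse_bf = np.sqrt(np.sum((e - g) ** 2) / len(e))
        r_bf = np.sum((e - e.mean()) * (g - g.mean())) / np.sqrt(
            np.sum((e - e.mean()) ** 2) * np.sum((g - g.mean()) ** 2)
        )
        assert ag.rmse[axis] == pytest.approx(rmse_bf, abs=1e-12)
        assert ag.r[axis] == pytest.approx(r_bf, abs=1e-12)
        assert ag.r2[axis] == pytest.approx(r_bf**2, abs=1e-12)


def test_r_band_cutpoints():
    assert r_band(0.95) == "very_good"
    assert r_band(0.8) == "good"
    assert r_band(0.6) == "moderate"
    assert r_band(0.3) == "weak"


# ---------------------------------------------------------------- descriptives


def test_descriptives_constant_series():
    m = _series(np.full(100, 20.0), np.zeros(100), np.zeros(100))
    trial = Trial(id="t", kind="work_task", movement="task", borg=2.0, checklist_rank=1)
    d = task_descriptives(trial, m)
    assert (d.mean, d.peak, d.variance) == (20.0, 20.0, 0.0)
    assert d.borg == 2.0 and d.checklist_rank == 1


def test_descriptives_hand_arithmetic():
    m = _series([10.0, 20.0, 30.0], [0, 0, 0], [0, 0, 0])
    d = task_descriptives(Trial(id="t", kind="work_task", movement="task"), m)
    assert d.mean == pytest.approx(20.0)
    assert d.peak == pytest.approx(30.0)
    assert d.variance == pytest.approx(10.0)  # sample SD, n-1


# ---------------------------------------------------------------- direction


def test_one_sided_signal_has_absent_negative_segment():
    m = _series(np.zeros(50), np.abs(np.sin(np.arange(50))) + 0.1, np.zeros(50))
    ds = direction_split(m, "y")
    assert ds.negative is None
    assert ds.positive.mean > 0


def test_sine_positive_segment_mean():
    n = 10000
    t = np.arange(n) / n
    A = 7.0
    m = _series(np.zeros(n), A * np.sin(2 * np.pi * 5 * t), np.zeros(n))
    ds = direction_split(m, "y")
    assert ds.positive.mean == pytest.approx(2 * A / np.pi, rel=0.01)
    assert ds.negative.mean == pytest.approx(-2 * A / np.pi, rel=0.01)


def test_sign_flip_mirrors_segments():
    rng = np.random.default_rng(3)
    y = rng.standard_normal(500)
    m = _series(np.zeros(500), y, np.zeros(500))
    flipped = _series(np.zeros(500), -y, np.zeros(500))
    a = direction_split(m, "y")
    b = direction_split(flipped, "y")
    assert a.positive.mean == pytest.approx(-b.negative.mean)
    assert a.n_positive == b.n_negative


def test_partition_is_disjoint_and_exhaustive():
    rng = np.random.default_rng(4)
    y = rng.standard_normal(1000)
    y[::10] = 0.0  # exact zeros belong to neither side
    m = _series(np.zeros(1000), y, np.zeros(1000))
    ds = direction_split(m, "y")
    assert ds.n_positive + ds.n_negative == np.count_nonzero(y)
    assert ds.n_positive == np.sum(y > 0)


def test_norm_split_uses_dominant_axis_sign():
    y = np.array([5.0, -5.0, 5.0, -5.0])
    m = _series(np.ones(4), y, np.zeros(4))
    ds = direction_split(m, "norm")
    assert ds.n_positive == 2 and ds.n_negative == 2
    ds_x = direction_split(m, "norm", split_axis="x")
    assert ds_x.n_positive == 4 and ds_x.negative is None


# ---------------------------------------------------------------- paired


def test_identical_vectors_null_case():
    v = np.array([1.0, 2.0, 3.0, 4.0])
    pc = paired_comparison(v, v)
    assert pc.MD == 0.0 and pc.p == 1.0


def test_closed_form_t_statistic():
    a = np.zeros(3)
    b = np.array([1.0, 2.0, 3.0])
    pc = paired_comparison(a, b)
    assert pc.MD == pytest.approx(2.0)
    assert pc.SDD == pytest.approx(1.0)
    t = pc.MD / (pc.SDD / np.sqrt(3))
    assert t == pytest.approx(3.464, abs=0.001)
    p_closed = 2 * (1 - sst.t.cdf(t, df=2))
    assert pc.p == pytest.approx(p_closed, abs=1e-6)
    assert pc.p == pytest.approx(0.074, abs=0.001)
    assert pc.test_used == "paired_t"
    assert pc.CI95[0] <= pc.MD <= pc.CI95[1]


def test_non_normal_differences_use_wilcoxon():
    rng = np.random.default_rng(0)
    a = np.zeros(20)
    b = np.exp(rng.standard_normal(20) * 2) + 5  # heavily skewed differences
    pc = paired_comparison(a, b)
    assert pc.normality_p <= 0.05
    assert pc.test_used == "wilcoxon"
    assert pc.p == pytest.approx(float(sst.wilcoxon(b, a).pvalue), abs=1e-12)


def test_paired_needs_three_subjects():
    with pytest.raises(ValidationError, match="n >= 3"):
        paired_comparison(np.array([1.0, 2.0]), np.array([2.0, 3.0]))


def test_relative_md_both_ways():
    a = np.array([10.0, 20.0, 30.0])
    b = np.array([15.0, 30.0, 45.0])
    pc = paired_comparison(a, b)
    assert pc.MD_rel == pytest.approx(50.0)
    assert pc.MD_rel_of_means == pytest.approx(100.0 * pc.MD / a.mean())


# ---------------------------------------------------------------- selection


def _task_trial(tid, rank, borg, angle_profile):
    n = len(angle_profile)
    t = DT * np.arange(n)
    R = Rotation.from_rotvec(np.outer(angle_profile, [0.0, 1.0, 0.0]))
    quat = R.as_quat()[:, [3, 0, 1, 2]]
    quat = np.where(quat[:, :1] < 0, -quat, quat)
    stream = ImmuStream("sternum", t, quat, np.zeros((n, 3)), np.zeros((n, 3)))
    return Trial(
        id=tid,
        kind="work_task",
        movement="task",
        checklist_rank=rank,
        borg=borg,
        immu={"sternum": stream},
    )


def _hold(n, angle):
    return np.full(n, np.radians(angle))


def _sway(n, amp_deg, cycles):
    return np.radians(amp_deg) * 0.5 * (1 - np.cos(2 * np.pi * cycles * np.arange(n) / n))


def test_select_tasks_by_rank_and_posture():
    trials = [
        _task_trial("a", 1, 1.0, _sway(1500, 12, 4)),  # light, never still, small range
        _task_trial("b", 3, 4.0, _hold(1500, 30)),  # static hold
        _task_trial("c", 5, 6.0, _sway(1500, 55, 6)),  # heavy lifting
    ]
    roles = select_tasks(trials)
    assert roles == {"light": "a", "heavy": "c", "static": "b", "dynamic": "c"}


def test_heavy_tie_broken_by_borg():
    trials = [
        _task_trial("a", 1, 1.0, _sway(1500, 12, 4)),
        _task_trial("b", 5, 6.0, _hold(1500, 30)),
        _task_trial("c", 5, 8.0, _sway(1500, 55, 6)),
    ]
    roles = select_tasks(trials)
    assert roles["heavy"] == "c"


def test_all_dynamic_raises_no_static():
    trials = [
        _task_trial("a", 1, 1.0, _sway(1500, 40, 6)),
        _task_trial("c", 5, 8.0, _sway(1500, 55, 6)),
    ]
    with pytest.raises(ValidationError, match="no static task"):
        select_tasks(trials)


def test_no_work_tasks_is_an_error():
    with pytest.raises(ValidationError, match="no work tasks"):
        select_tasks([])


# ---------------------------------------------------------------- report


def _subject_results(sid, scale=1.0):
    from lumbarload.stats import AgreementResult, TaskDescriptives

    ag = AgreementResult(
        rmse={"x": 2.0 * scale, "y": 3.0 * scale, "z": 1.0 * scale, "norm": 3.0},
        r={"x": 0.9, "y": 0.95, "z": 0.7},
        r2={"x": 0.81, "y": 0.9, "z": 0.49},
        band={"x": "good", "y": "very_good", "z": "good"},
    )
    sr = SubjectResults(subject_id=sid)
    for mv in ("bending", "lateroflexion", "rotation"):
        sr.agreement[mv] = ag
    sr.tasks = {
        "light": TaskDescriptives(10.0 * scale, 50.0, 5.0, borg=1.0, checklist_rank=1),
        "heavy": TaskDescriptives(25.0 * scale, 90.0, 12.0, borg=6.0, checklist_rank=5),
        "static": TaskDescriptives(15.0 * scale, 60.0, 4.0, borg=4.0, checklist_rank=3),
        "dynamic": TaskDescriptives(26.0 * scale, 95.0, 14.0, borg=6.5, checklist_rank=5),
    }
    return sr


def test_single_subject_report_shapes():
    rep = build_report([_subject_results("s1")])
    ag = rep.tables["agreement_by_subject"]
    assert list(ag.columns) == ["s1", "Mean", "SDD"]
    assert rep.tables["rmse_by_movement_axis"].shape[0] == 9
    assert set(rep.tables["task_descriptives"].index) >= {"light", "heavy", "static", "dynamic"}


def test_report_mean_column_is_mean_of_cells():
    results = [_subject_results(f"s{i}", scale=1.0 + 0.2 * i) for i in range(4)]
    rep = build_report(results)
    rmse = rep.tables["rmse_by_movement_axis"]
    subj_cols = [c for c in rmse.columns if c not in ("Mean", "SDD")]
    assert np.allclose(rmse["Mean"], rmse[subj_cols].mean(axis=1))


def test_report_paired_contrasts_present_with_cohort():
    results = [_subject_results(f"s{i}", scale=1.0 + 0.1 * i) for i in range(5)]
    rep = build_report(results)
    lh = rep.tables["light_vs_heavy"]
    assert {"mean", "peak", "variance", "borg"} <= set(lh.index)
    row = lh.loc["mean"]
    assert row["MD"] > 0 and 0 <= row["p"] <= 1
    assert row["CI_low"] <= row["MD"] <= row["CI_high"]
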