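import numpy as np
import pytest

from lumbarload import NetMomentSeries, ValidationError
from lumbarload.ann import (
    FEATURE_NAMES,
    AnnModel,
    FeatureMatrix,
    MomentEstimator,
    build_feature_matrix,
    predict_moments,
    train_ann,
)

DT = 0.02


def _toy_features(n=600, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, 16))
    return FeatureMatrix(t=DT * np.arange(n), X=X, trial_ids=np.array(["t"] * n, dtype=object))


def _targets_from(X, t):
    # a smooth nonlinear map the 31-unit network can represent
    y1 = 20 * np.tanh(X[:, 0]) + 5 * X[:, 4]
    y2 = 10 * X[:, 1] * 0.5 + 3 * np.tanh(X[:, 7])
    y3 = 4 * np.tanh(X[:, 2] + X[:, 10])
    return NetMomentSeries(t=t, Mx=y1, My=y2, Mz=y3)


def test_feature_matrix_shape_and_16_columns(prepared_session):
    trial = prepared_session.load_trials((6.0,))[0]
    fm = build_feature_matrix(prepared_session, [trial.id])
    assert fm.X.shape == (len(trial.immu["sternum"]), 16)
    assert len(FEATURE_NAMES) == 16
    # a 20 s load trial at 50 Hz
    assert fm.X.shape[0] == 1000


def test_feature_matrix_concatenates_trials(prepared_session):
    ids = [tr.id for tr in prepared_session.load_trials((0.0, 10.0))]
    fm = build_feature_matrix(prepared_session, ids)
    assert len(fm) == sum(len(prepared_session.trial(t).immu["sternum"]) for t in ids)
    assert set(np.unique(fm.trial_ids)) == set(ids)


def test_quaternions_are_excluded_from_features(prepared_session):
    # no feature column may be a relabeled orientation channel
    ids = [tr.id for tr in prepared_session.load_trials((0.0, 10.0))]
    fm = build_feature_matrix(prepared_session, ids)
    quats = np.vstack(
        [
            np.hstack(
                [prepared_session.trial(t).immu[s].quat for s in ("sternum", "sacrum")]
            )[: np.sum(fm.trial_ids == t)]
            for t in ids
        ]
    )
    for j in range(fm.X.shape[1]):
        col = fm.X[:, j]
        if np.std(col) == 0:
            continue
        for k in range(quats.shape[1]):
            q = quats[:, k]
            if np.std(q) == 0:
                continue
            assert abs(np.corrcoef(col, q)[0, 1]) < 0.999


def test_zero_targets_converge_to_tiny_rmse():
    fm = _toy_features()
    zeros = NetMomentSeries(t=fm.t, Mx=np.zeros(len(fm)), My=np.zeros(len(fm)), Mz=np.zeros(len(fm)))
    model = train_ann(fm, zeros, seed=0, max_epochs=200, restarts=1)
    assert model.converged
    assert model.final_rmse_sum <= 0.5


def test_learnable_targets_reach_criterion_and_determinism():
    fm = _toy_features(seed=1)
    targets = _targets_from(fm.X, fm.t)
    a = train_ann(fm, targets, seed=7, max_epochs=400, restarts=1)
    b = train_ann(fm, targets, seed=7, max_epochs=400, restarts=1)
    assert np.array_equal(a.W1, b.W1) and np.array_equal(a.W2, b.W2)
    pa = predict_moments(a, fm)
    pb = predict_moments(b, fm)
    assert np.array_equal(pa.as_array(), pb.as_array())


def test_shuffled_targets_do_not_converge():
    fm = _toy_features(seed=2)
    targets = _targets_from(fm.X, fm.t)
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(fm))
    shuffled = NetMomentSeries(
        t=fm.t, Mx=targets.Mx[perm], My=targets.My[perm], Mz=targets.Mz[perm]
    )
    with pytest.warns(UserWarning, match="criterion not met"):
        model = train_ann(fm, shuffled, seed=0, max_epochs=150, restarts=1)
    assert not model.converged


def test_zero_weight_model_outputs_denormalized_bias():
    model = AnnModel(
        W1=np.zeros((16, 31)),
        b1=np.zeros(31),
        W2=np.zeros((31, 3)),
        b2=np.array([1.0, -2.0, 0.5]),
        x_mean=np.zeros(16),
        x_scale=np.ones(16),
        y_mean=np.array([10.0, 0.0, -5.0]),
        y_scale=np.array([2.0, 3.0, 4.0]),
        epochs=0,
        final_rmse_sum=0.0,
        seed=0,
        converged=True,
    )
    fm = _toy_features(n=5)
    out = predict_moments(model, fm)
    # hidden layer sits at sigmoid(0) = 0.5 everywhere, contributing nothing
    # through zero output weights: y = b2 * scale + mean
    assert np.allclose(out.as_array(), [1.0 * 2 + 10, -2.0 * 3 + 0, 0.5 * 4 - 5])


def test_wrong_feature_count_rejected():
    fm = _toy_features(n=10)
    with pytest.raises(ValidationError, match="16 columns"):
        FeatureMatrix(t=fm.t, X=fm.X[:, :12], trial_ids=fm.trial_ids)


def test_emg_gain_invariance_of_converged_predictions():
    # multiplying all EMG channels by a constant is absorbed by the
    # per-feature standardization
    fm = _toy_features(seed=4)
    targets = _targets_from(fm.X, fm.t)
    scaled = FeatureMatrix(
        t=fm.t, X=fm.X * np.r_[np.full(4, 10.0), np.ones(12)], trial_ids=fm.trial_ids
    )
    a = train_ann(fm, targets, seed=5, max_epochs=300, restarts=1)
    b = train_ann(scaled, targets, seed=5, max_epochs=300, restarts=1)
    pa = predict_moments(a, fm).as_array()
    pb = predict_moments(b, scaled).as_array()
    # standardization absorbs the gain up to float rounding, which nudges the
    # optimizer path; converged predictions must still agree closely
    for i in range(3):
        rms = np.sqrt(np.mean((pa[:, i] - pb[:, i]) ** 2))
        assert rms < 0.05 * np.std(pa[:, i])
        assert np.corrcoef(pa[:, i], pb[:, i])[0, 1] > 0.999


def test_six_kg_holdout_good_on_bending_axis(prepared_session):
    """0/10 kg training generalizes to the held-out 6 kg bending trial."""
    ids = [tr.id for tr in prepared_session.load_trials((0.0, 10.0))]
    est = MomentEstimator.from_session(prepared_session, ids).fit(seed=42)
    assert est.converged
    assert est.rmse_sum < 10.0
    bend6 = next(tr for tr in prepared_session.load_trials((6.0,)) if tr.movement == "bending")
    fm = build_feature_matrix(prepared_session, [bend6.id])
    pred = est.predict(fm)
    from lumbarload.lsm import LoadSpec, lsm_net_moment, scale_body_model

    target = lsm_net_moment(
        bend6.immu, scale_body_model(prepared_session.subject), LoadSpec(mass=6.0)
    )
    r = np.corrcoef(pred.My, target.My)[0, 1]
    assert r >= 0.9
    summary = est.summary()
    assert "16 -> 31" in summary and "converged" in summary.lower()
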