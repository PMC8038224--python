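"""Per-session ANN estimation of the L5/S1 net moment.

A feed-forward network with one hidden layer of 31 sigmoid units and a
linear 3-output layer maps 16 features per sample — the four sEMG amplitude
envelopes plus 3D angular velocity and 3D linear acceleration from the
sternum and sacrum IMMUs only — to (Mx, My, Mz). Orientation quaternions are
deliberately excluded: inclination is already present in the accelerometer
channels, and magnetometer-aided orientation is unreliable in industrial
environments.

The network is trained per subject and per session in supervised mode
against linked-segment-model targets from the known-load trials, to the
fixed criterion "RMSE Mx + RMSE My + RMSE Mz < 10 Nm" on the training set.
Exposed in the model/results idiom: :class:`MomentEstimator` is built from a
session, ``fit()`` returns :class:`MomentEstimatorResults` carrying weights,
the training record and diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.neural_network import MLPRegressor

from .types import EMG_CHANNELS, NetMomentSeries, Session, ValidationError
from .lsm import BodyModel, LoadSpec, lsm_net_moment, scale_body_model

N_FEATURES = 16
N_HIDDEN = 31
#: training stop criterion: summed per-axis RMSE on the training set, Nm
RMSE_CRITERION = 10.0

FEATURE_NAMES = tuple(
    [f"emg_{ch}" for ch in EMG_CHANNELS]
    + [f"sternum_angvel_{a}" for a in "xyz"]
    + [f"sternum_linacc_{a}" for a in "xyz"]
    + [f"sacrum_angvel_{a}" for a in "xyz"]
    + [f"sacrum_linacc_{a}" for a in "xyz"]
)


@dataclass
class FeatureMatrix:
    """ANN input features on the common 50 Hz grid."""

    t: np.ndarray
    X: np.ndarray  # (N, 16)
    trial_ids: np.ndarray  # (N,) trial id per row
    feature_names: tuple = FEATURE_NAMES

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != N_FEATURES:
            raise ValidationError(
                f"feature matrix must have {N_FEATURES} columns, got {self.X.shape}"
            )
        if not np.all(np.isfinite(self.X)):
            raise ValidationError("feature matrix contains missing/non-finite values")

    def __len__(self) -> int:
        return len(self.X)


def build_feature_matrix(session: Session, trial_ids: list[str]) -> FeatureMatrix:
    """Assemble the 16-column feature matrix for the named trials.

    Requires synchronized, calibrated trials with EMG envelopes on the 50 Hz
    grid. Rows of consecutive trials are concatenated; ``trial_ids``
    bookkeeping allows per-trial extraction afterwards.
    """
    blocks, times, ids = [], [], []
    for tid in trial_ids:
        trial = session.trial(tid)
        cols = []
        for ch in EMG_CHANNELS:
            if ch not in trial.emg or trial.emg[ch].envelope is None:
                raise ValidationError(f"trial {tid}: missing EMG envelope for {ch}")
        for site in ("sternum", "sacrum"):
            if site not in trial.immu:
                raise ValidationError(f"trial {tid}: missing IMMU stream {site}")
        n = min(
            min(len(trial.emg[ch].envelope) for ch in EMG_CHANNELS),
            min(len(trial.immu[s]) for s in ("sternum", "sacrum")),
        )
        for ch in EMG_CHANNELS:
            cols.append(trial.emg[ch].envelope[:n])
        for site in ("sternum", "sacrum"):
            cols.append(trial.immu[site].angvel[:n])
            cols.append(trial.immu[site].linacc[:n])
        X = np.column_stack(cols)
        blocks.append(X)
        times.append(trial.immu["sternum"].t[:n])
        ids.extend([tid] * n)
    if not blocks:
        raise ValidationError("no trials given")
    return FeatureMatrix(
        t=np.concatenate(times), X=np.vstack(blocks), trial_ids=np.asarray(ids, dtype=object)
    )


@dataclass
class AnnModel:
    """Trained network weights plus normalization and training metadata."""

    W1: np.ndarray  # (16, 31)
    b1: np.ndarray  # (31,)
    W2: np.ndarray  # (31, 3)
    b2: np.ndarray  # (3,)
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: np.ndarray
    y_scale: np.ndarray
    epochs: int
    final_rmse_sum: float  # Nm, summed per-axis RMSE on the training set
    seed: int
    converged: bool

    def __post_init__(self):
        if self.W1.shape != (N_FEATURES, N_HIDDEN) or self.W2.shape != (N_HIDDEN, 3):
            raise ValidationError(
                f"architecture must be {N_FEATURES}->{N_HIDDEN}->3, got "
                f"{self.W1.shape} / {self.W2.shape}"
            )

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Sigmoid-hidden, linear-output forward pass on raw features."""
        Z = (np.asarray(X, dtype=float) - self.x_mean) / self.x_scale
        H = 1.0 / (1.0 + np.exp(-(Z @ self.W1 + self.b1)))
        Y = H @ self.W2 + self.b2
        return Y * self.y_scale + self.y_mean


def _rmse_per_axis(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    return np.sqrt(np.mean((y_true - y_pred) ** 2, axis=0))


def train_ann(
    features: FeatureMatrix,
    targets: NetMomentSeries,
    seed: int = 0,
    max_epochs: int = 2000,
    restarts: int = 3,
    rmse_criterion: float = RMSE_CRITERION,
) -> AnnModel:
    """Train the 16→31→3 network against target moments.

    Full-batch quasi-Newton (L-BFGS) minimization of the mean squared error
    with per-feature/per-target standardization and small seeded random
    initialization. Training is accepted once the summed per-axis RMSE on
    the training set drops below ``rmse_criterion``; otherwise up to
    ``restarts`` re-initializations are tried and the best kept
    (``converged=False`` with a warning if the criterion is never met).
    """
    X = features.X
    Y = targets.as_array()
    if len(X) != len(Y):
        raise ValidationError(f"features ({len(X)}) and targets ({len(Y)}) misaligned")
    n_weights = N_FEATURES * N_HIDDEN + N_HIDDEN + N_HIDDEN * 3 + 3
    if len(X) < 10 * n_weights:
        warnings.warn(
            f"only {len(X)} samples for {n_weights} weights; >= {10 * n_weights} "
            "recommended",
            stacklevel=2,
        )
    x_mean, x_scale = X.mean(axis=0), X.std(axis=0)
    x_scale[x_scale == 0] = 1.0
    y_mean, y_scale = Y.mean(axis=0), Y.std(axis=0)
    y_scale[y_scale == 0] = 1.0
    Xn = (X - x_mean) / x_scale
    Yn = (Y - y_mean) / y_scale

    best: AnnModel | None = None
    chunk = 200  # epochs between checks of the stopping criterion
    for k in range(max(1, restarts)):
        net = MLPRegressor(
            hidden_layer_sizes=(N_HIDDEN,),
            activation="logistic",
            solver="lbfgs",
            alpha=1e-6,
            max_iter=chunk,
            tol=1e-8,
            random_state=seed + k,
            warm_start=True,
        )
        epochs = 0
        rmse_sum = float("inf")
        while epochs < max_epochs:
            net.max_iter = min(chunk, max_epochs - epochs)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # convergence handled via the RMSE criterion
                net.fit(Xn, Yn)
            made = int(net.n_iter_)
            epochs += made
            pred = net.predict(Xn) * y_scale + y_mean
            if not np.all(np.isfinite(pred)):
                raise ValidationError("training diverged: non-finite loss")
            rmse_sum = float(_rmse_per_axis(Y, pred).sum())
            if rmse_sum < rmse_criterion or made < net.max_iter:
                break
        model = AnnModel(
            W1=net.coefs_[0],
            b1=net.intercepts_[0],
            W2=net.coefs_[1],
            b2=net.intercepts_[1],
            x_mean=x_mean,
            x_scale=x_scale,
            y_mean=y_mean,
            y_scale=y_scale,
            epochs=epochs,
            final_rmse_sum=rmse_sum,
            seed=seed + k,
            converged=rmse_sum < rmse_criterion,
        )
        if best is None or model.final_rmse_sum < best.final_rmse_sum:
            best = model
        if model.converged:
            break
    assert best is not None
    if not best.converged:
        warnings.warn(
            f"training criterion not met: summed RMSE {best.final_rmse_sum:.2f} Nm "
            f">= {rmse_criterion} Nm after {restarts} restart(s)",
            stacklevel=2,
        )
    return best


def predict_moments(model: AnnModel, features: FeatureMatrix) -> NetMomentSeries:
    """Apply a trained network to a feature matrix."""
    if features.X.shape[1] != model.W1.shape[0]:
        raise ValidationError(
            f"feature count {features.X.shape[1]} != model input {model.W1.shape[0]}"
        )
    Y = model.forward(features.X)
    return NetMomentSeries(t=features.t, Mx=Y[:, 0], My=Y[:, 1], Mz=Y[:, 2])


# ---------------------------------------------------------------------------
# model / results interface


class MomentEstimator:
    """EMG + kinematics → L5/S1 net moment estimator for one session.

    Parameters
    ----------
    features : FeatureMatrix
        Training inputs (4 EMG envelopes + sternum/sacrum angular velocity
        and linear acceleration).
    targets : NetMomentSeries
        Supervised targets, normally linked-segment-model moments from the
        known-load trials.
    """

    def __init__(self, features: FeatureMatrix, targets: NetMomentSeries):
        if len(features) != len(targets):
            raise ValidationError("features and targets must be sample-aligned")
        self.features = features
        self.targets = targets

    @classmethod
    def from_session(
        cls,
        session: Session,
        trial_ids: list[str],
        body_model: BodyModel | None = None,
        use_linacc: bool = True,
    ) -> "MomentEstimator":
        """Build the estimator from a calibrated, synchronized session.

        Targets are computed with the linked-segment model from each named
        trial's streams and its known handheld load.
        """
        body = body_model or scale_body_model(session.subject)
        features = build_feature_matrix(session, trial_ids)
        parts = []
        for tid in trial_ids:
            trial = session.trial(tid)
            m = lsm_net_moment(
                trial.immu, body, LoadSpec(mass=trial.load_mass), use_linacc=use_linacc
            )
            n = int(np.sum(features.trial_ids == tid))
            parts.append(m.as_array()[:n])
        Y = np.vstack(parts)
        targets = NetMomentSeries(t=features.t, Mx=Y[:, 0], My=Y[:, 1], Mz=Y[:, 2])
        return cls(features, targets)

    def fit(
        self,
        seed: int = 0,
        max_epochs: int = 2000,
        restarts: int = 3,
        rmse_criterion: float = RMSE_CRITERION,
    ) -> "MomentEstimatorResults":
        model = train_ann(
            self.features,
            self.targets,
            seed=seed,
            max_epochs=max_epochs,
            restarts=restarts,
            rmse_criterion=rmse_criterion,
        )
        return MomentEstimatorResults(self, model)


class MomentEstimatorResults:
    """Fit results: trained weights, training record, diagnostics."""

    def __init__(self, model: MomentEstimator, ann: AnnModel):
        self.model = model
        self.ann = ann

    @property
    def converged(self) -> bool:
        return self.ann.converged

    @property
    def rmse_sum(self) -> float:
        return self.ann.final_rmse_sum

    def predict(self, features: FeatureMatrix | None = None) -> NetMomentSeries:
        return predict_moments(self.ann, features or self.model.features)

    def training_rmse(self) -> dict[str, float]:
        pred = self.predict().as_array()
        rmse = _rmse_per_axis(self.model.targets.as_array(), pred)
        return {"Mx": float(rmse[0]), "My": float(rmse[1]), "Mz": float(rmse[2])}

    def training_r(self) -> dict[str, float]:
        pred = self.predict().as_array()
        true = self.model.targets.as_array()
        out = {}
        for i, axis in enumerate(("Mx", "My", "Mz")):
            out[axis] = float(np.corrcoef(true[:, i], pred[:, i])[0, 1])
        return out

    def plot(self, features: FeatureMatrix | None = None, target: NetMomentSeries | None = None):
        """Plot predicted (and optionally target) moment curves."""
        from .plotting import plot_moment_comparison

        return plot_moment_comparison(
            self.predict(features), target if target is not None else self.model.targets
        )

    def summary(self) -> str:
        rmse = self.training_rmse()
        r = self.training_r()
        lines = [
            "L5/S1 net-moment ANN estimator",
            "=" * 46,
            f"architecture      16 -> {N_HIDDEN} (sigmoid) -> 3 (linear)",
            f"training samples  {len(self.model.features)}",
            f"epochs            {self.ann.epochs}",
            f"seed              {self.ann.seed}",
            f"converged         {self.ann.converged} "
            f"(summed RMSE {self.ann.final_rmse_sum:.2f} Nm, criterion < {RMSE_CRITERION:.0f} Nm)",
            "-" * 46,
            "axis       RMSE [Nm]        r",
        ]
        for axis in ("Mx", "My", "Mz"):
            lines.append(f"{axis:<6} {rmse[axis]:>10.2f} {r[axis]:>12.3f}")
        return "\n".join(lines)


__all__ = [
    "N_FEATURES",
    "N_HIDDEN",
    "RMSE_CRITERION",
    "FEATURE_NAMES",
    "FeatureMatrix",
    "AnnModel",
    "build_feature_matrix",
    "train_ann",
    "predict_moments",
    "MomentEstimator",
    "MomentEstimatorResults",
]
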