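"""Personalized multi-horizon glucose forecasting.

One model per horizon (15/30/45/60 min).  Each horizon model is a
state-gated ensemble: a gradient-boosted-trees classifier assigns the
current feature vector to one of a small number of physiological trend
states (defined during training by discretising the realised future rate of
change into falling-fast / falling / flat / rising / rising-fast), and an
RBF support-vector regressor trained exclusively on that state's examples
produces the prediction.  The regressors predict the glucose *delta* over
the horizon; anchors are current + delta, clamped to the sensor range.
In-between 5-minute points come from a natural cubic spline through the
anchor knots.

Training requires 2000 valid CGM points (about a week of continuous data)
and a seed; identical (data, seed, config) yields identical models and
predictions.  Bundles are considered stale 14 days after training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from xgboost import XGBClassifier

from .core import (
    ConfigError,
    EventRecord,
    GlucoseSeries,
    PatientProfile,
    SENSOR_MAX,
    SENSOR_MIN,
    sliding_windows,
    validate_and_clamp,
)
from .physio import (
    FeatureConfig,
    FeatureUnavailableError,
    PhysioParams,
    build_features,
    feature_matrix,
    fit_physio_params,
)

HORIZONS = (15, 30, 45, 60)
MIN_TRAINING_POINTS = 2000
RETRAIN_AFTER_DAYS = 14

#: Future rate-of-change cut points (mg/dL per minute) defining the five
#: trend states: falling fast / falling / flat / rising / rising fast.
STATE_RATE_BINS = (-0.5, -0.1, 0.1, 0.5)
N_STATES = len(STATE_RATE_BINS) + 1


class InsufficientDataError(ValueError):
    """Raised when fewer than the 2000-point training gate's worth of CGM
    samples are available."""


@dataclass
class TrainConfig:
    """Hyperparameters for the state-gated ensemble.

    Fixed, recorded values — reproducibility over tuning.
    """

    feature: FeatureConfig = field(default_factory=FeatureConfig)
    min_state_n: int = 200        # training pairs per state before merging
    max_train_pairs: int = 8000   # seeded subsample cap per horizon
    tree_depth: int = 4
    boosting_rounds: int = 200
    learning_rate: float = 0.1
    svr_c: float = 10.0
    svr_epsilon: float = 2.0      # mg/dL
    fit_physio: bool = True

    def to_dict(self) -> dict:
        return {
            "history": self.feature.history,
            "max_gap": self.feature.max_gap,
            "min_state_n": self.min_state_n,
            "max_train_pairs": self.max_train_pairs,
            "tree_depth": self.tree_depth,
            "boosting_rounds": self.boosting_rounds,
            "learning_rate": self.learning_rate,
            "svr_c": self.svr_c,
            "svr_epsilon": self.svr_epsilon,
            "fit_physio": self.fit_physio,
        }


def state_labels(deltas: np.ndarray, horizon: float) -> np.ndarray:
    """Discretise realised horizon deltas (mg/dL) into the five trend states."""
    rates = np.asarray(deltas, dtype=float) / horizon
    return np.digitize(rates, STATE_RATE_BINS)


def merge_small_states(labels: np.ndarray, min_state_n: int) -> np.ndarray:
    """Map of raw state -> merged group, folding under-populated states into
    their nearest populated neighbour by class adjacency.

    Returns an int array of length N_STATES; merged group ids are raw state
    ids of the surviving states (not yet compacted).
    """
    mapping = np.arange(N_STATES)
    counts = np.bincount(labels, minlength=N_STATES).astype(float)
    for _ in range(N_STATES):
        merged_counts = np.zeros(N_STATES)
        for s in range(N_STATES):
            merged_counts[mapping[s]] += counts[s]
        small = [
            g
            for g in np.unique(mapping)
            if 0 < merged_counts[g] < min_state_n
        ]
        if not small or len(np.unique(mapping)) == 1:
            break
        g = small[0]
        # nearest surviving neighbour by state-index distance, richer side wins ties
        others = [o for o in np.unique(mapping) if o != g and merged_counts[o] > 0]
        if not others:
            break
        target = min(others, key=lambda o: (abs(o - g), -merged_counts[o]))
        mapping[mapping == g] = target
    return mapping


@dataclass
class HorizonModel:
    """Trained artifact for one prediction horizon."""

    horizon: int
    scaler: StandardScaler
    classifier: XGBClassifier | None      # None when training collapsed to one state
    class_to_group: np.ndarray            # raw state id -> regressor group id
    regressors: dict[int, SVR]
    constant_group: int = 0               # used when classifier is None

    def __post_init__(self) -> None:
        if self.horizon not in HORIZONS:
            raise ConfigError(f"horizon must be one of {HORIZONS}")

    def classify(self, X: np.ndarray) -> np.ndarray:
        """Group id for each standardized feature row; deterministic."""
        if X.shape[1] != self.scaler.mean_.shape[0]:
            raise ValueError(
                f"feature length mismatch: got {X.shape[1]}, expected {self.scaler.mean_.shape[0]}"
            )
        if self.classifier is None:
            return np.full(len(X), self.constant_group, dtype=int)
        raw = self.classifier.predict(X).astype(int)
        return self.class_to_group[raw]

    def predict_delta(self, X: np.ndarray) -> np.ndarray:
        """Predicted horizon delta (mg/dL) for each raw feature row."""
        Xs = self.scaler.transform(X)
        groups = self.classify(Xs)
        out = np.empty(len(X))
        for g in np.unique(groups):
            mask = groups == g
            out[mask] = self.regressors[int(g)].predict(Xs[mask])
        return out


@dataclass
class ModelBundle:
    """Per-patient trained artifact: one state-gated model per horizon."""

    patient_id: str
    models: dict[int, HorizonModel]
    physio: PhysioParams
    trained_at: pd.Timestamp
    training_points: int
    seed: int
    config: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self) -> None:
        if set(self.models) != set(HORIZONS):
            raise ConfigError(f"bundle must contain exactly the horizons {HORIZONS}")
        if self.training_points < MIN_TRAINING_POINTS:
            raise ConfigError("bundle built from fewer points than the training gate allows")


@dataclass
class PredictionCurve:
    """Forecast anchored at ``t0``: four anchor predictions plus the
    5-minutely interpolated trajectory from +5 to +60 min."""

    t0: pd.Timestamp
    current: float
    anchors: dict[int, float]
    interpolated: np.ndarray
    adjusted: bool = False

    def anchor_array(self) -> np.ndarray:
        return np.array([self.anchors[h] for h in HORIZONS])


def interpolate_curve(current: float, anchors: dict[int, float]) -> np.ndarray:
    """Natural cubic spline through (0, current) and the four anchors,
    evaluated every 5 minutes from +5 to +60 (12 values)."""
    knots_t = np.array([0.0, *HORIZONS])
    knots_v = np.array([current, *(anchors[h] for h in HORIZONS)])
    if not np.all(np.isfinite(knots_v)):
        raise ValueError("non-finite anchor value")
    spline = CubicSpline(knots_t, knots_v, bc_type="natural")
    grid = np.arange(5.0, 61.0, 5.0)
    return np.clip(spline(grid), SENSOR_MIN, SENSOR_MAX)


def classify_state(model: HorizonModel, fv) -> int:
    """Group id of a single feature vector under a trained horizon model."""
    values = fv.values if hasattr(fv, "values") else np.asarray(fv, dtype=float)
    Xs = model.scaler.transform(values.reshape(1, -1))
    return int(model.classify(Xs)[0])


def _training_pairs(
    series: GlucoseSeries,
    events: Sequence[EventRecord],
    params: PhysioParams,
    horizon: int,
    config: TrainConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(X, current, target) arrays for one horizon from gap-free windows."""
    ends, targets = [], []
    for w in sliding_windows(series, config.feature.history, horizon, config.feature.max_gap):
        ends.append(w.end)
        targets.append(w.target)
    if not ends:
        return np.empty((0, 1)), np.empty(0), np.empty(0)
    ends = np.array(ends)
    targets = np.array(targets)
    X = feature_matrix(series, events, params, ends, config.feature)
    return X, series.values[ends], series.values[targets]


def _fit_horizon(
    X: np.ndarray,
    current: np.ndarray,
    target: np.ndarray,
    horizon: int,
    seed: int,
    config: TrainConfig,
) -> HorizonModel:
    rng = np.random.default_rng(seed)
    if len(X) > config.max_train_pairs:
        keep = rng.choice(len(X), size=config.max_train_pairs, replace=False)
        keep.sort()
        X, current, target = X[keep], current[keep], target[keep]
    delta = target - current
    labels = state_labels(delta, horizon)
    mapping = merge_small_states(labels, config.min_state_n)
    groups = mapping[labels]

    scaler = StandardScaler()
    # guard against zero-variance columns (constant training series)
    Xs = scaler.fit(X).transform(X)
    Xs = np.nan_to_num(Xs, nan=0.0, posinf=0.0, neginf=0.0)

    unique_groups = np.unique(groups)
    if len(unique_groups) > 1:
        # classifier learns the merged group directly; compact ids for xgboost
        compact = {g: i for i, g in enumerate(unique_groups)}
        y_cls = np.array([compact[g] for g in groups])
        clf = XGBClassifier(
            max_depth=config.tree_depth,
            n_estimators=config.boosting_rounds,
            learning_rate=config.learning_rate,
            random_state=seed,
            n_jobs=1,
            tree_method="hist",
            verbosity=0,
        )
        clf.fit(Xs, y_cls)
        class_to_group = np.array(list(unique_groups))  # predicted compact id -> group id
    else:
        clf = None
        class_to_group = np.array(list(unique_groups))

    regressors: dict[int, SVR] = {}
    for g in unique_groups:
        mask = groups == g
        svr = SVR(kernel="rbf", C=config.svr_c, epsilon=config.svr_epsilon)
        svr.fit(Xs[mask], delta[mask])
        regressors[int(g)] = svr
    return HorizonModel(
        horizon=horizon,
        scaler=scaler,
        classifier=clf,
        class_to_group=class_to_group,
        regressors=regressors,
        constant_group=int(unique_groups[0]),
    )


def train_bundle(
    series: GlucoseSeries,
    events: Sequence[EventRecord],
    profile: PatientProfile,
    seed: int,
    config: TrainConfig | None = None,
) -> ModelBundle:
    """Train the four-horizon personalized bundle.

    Raises :class:`InsufficientDataError` below the 2000-point gate.
    Deterministic given (data, seed, config).
    """
    config = config or TrainConfig()
    clean = validate_and_clamp(series)
    if len(clean) < MIN_TRAINING_POINTS:
        raise InsufficientDataError(
            f"{len(clean)} CGM points available; the personalized model requires "
            f"{MIN_TRAINING_POINTS} points (about a week of continuous data)"
        )
    if config.fit_physio:
        params = fit_physio_params(clean, list(events), profile)
    else:
        params = PhysioParams(icr=profile.icr, cf=profile.cf, personalized=False)
    models = {}
    for k, horizon in enumerate(HORIZONS):
        X, current, target = _training_pairs(clean, events, params, horizon, config)
        if len(X) == 0:
            raise InsufficientDataError(f"no gap-free training windows for horizon {horizon}")
        models[horizon] = _fit_horizon(X, current, target, horizon, seed + k, config)
    return ModelBundle(
        patient_id=profile.patient_id,
        models=models,
        physio=params,
        trained_at=pd.Timestamp(clean.times[-1]),
        training_points=len(clean),
        seed=seed,
        config=config,
    )


def predict_horizons(
    bundle: ModelBundle,
    series: GlucoseSeries,
    events: Sequence[EventRecord],
    t0,
) -> PredictionCurve:
    """Predict the next hour from the window ending at ``t0``."""
    fv = build_features(
        series, events, None, bundle.physio, t0, bundle.config.feature
    )
    i = series.index_of(t0)
    current = float(series.values[i])
    X = fv.values.reshape(1, -1)
    anchors = {}
    for h in HORIZONS:
        delta = float(bundle.models[h].predict_delta(X)[0])
        anchors[h] = float(np.clip(current + delta, SENSOR_MIN, SENSOR_MAX))
    return PredictionCurve(
        t0=pd.Timestamp(t0),
        current=current,
        anchors=anchors,
        interpolated=interpolate_curve(current, anchors),
        adjusted=False,
    )


def predict_batch(
    bundle: ModelBundle,
    series: GlucoseSeries,
    events: Sequence[EventRecord],
    end_indices: np.ndarray,
) -> dict[int, np.ndarray]:
    """Anchor predictions for many window-end indices at once (evaluation path)."""
    end_indices = np.asarray(end_indices, dtype=int)
    X = feature_matrix(series, events, bundle.physio, end_indices, bundle.config.feature)
    current = series.values[end_indices]
    out = {}
    for h in HORIZONS:
        delta = bundle.models[h].predict_delta(X)
        out[h] = np.clip(current + delta, SENSOR_MIN, SENSOR_MAX)
    return out


def needs_retrain(bundle: ModelBundle, now) -> bool:
    """True once 14 days have elapsed since training (boundary inclusive)."""
    age = pd.Timestamp(now) - pd.Timestamp(bundle.trained_at)
    return age >= pd.Timedelta(days=RETRAIN_AFTER_DAYS)


# ---------------------------------------------------------------------------
# evaluation helpers: RMSE against held-out data and the two naive baselines


def rmse(predicted: np.ndarray, reference: np.ndarray) -> float:
    predicted = np.asarray(predicted, dtype=float)
    reference = np.asarray(reference, dtype=float)
    return float(np.sqrt(np.mean((predicted - reference) ** 2)))


def evaluation_windows(
    series: GlucoseSeries, horizon: int, config: TrainConfig, stride: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """(end_indices, target_indices) of admissible evaluation points."""
    ends, targets = [], []
    for w in sliding_windows(series, config.feature.history, horizon, config.feature.max_gap):
        ends.append(w.end)
        targets.append(w.target)
    ends = np.array(ends, dtype=int)[::stride]
    targets = np.array(targets, dtype=int)[::stride]
    return ends, targets


def locf_forecast(series: GlucoseSeries, end_indices: np.ndarray) -> np.ndarray:
    """Last-observation-carried-forward baseline: the current value."""
    return series.values[np.asarray(end_indices, dtype=int)]


def linear_extrapolation_forecast(
    series: GlucoseSeries, end_indices: np.ndarray, horizon: float, window: float = 30.0
) -> np.ndarray:
    """OLS line through the trailing ``window`` minutes, read ``horizon`` min ahead."""
    mins = series.minutes()
    out = np.empty(len(end_indices))
    for k, e in enumerate(np.asarray(end_indices, dtype=int)):
        lo = int(np.searchsorted(mins, mins[e] - window - 1e-9))
        t = mins[lo : e + 1] - mins[e]
        v = series.values[lo : e + 1]
        if len(t) < 2:
            out[k] = v[-1]
            continue
        slope, intercept = np.polyfit(t, v, 1)
        out[k] = intercept + slope * horizon
    return np.clip(out, SENSOR_MIN, SENSOR_MAX)
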