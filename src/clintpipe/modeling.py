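"""Three-class stability classifiers with a resampling-based tuning protocol.

Four families are supported — random forest, AdaBoost, and SVMs with radial
and linear kernels.  Training always centres and scales the features using
training-set statistics, searches a grid of roughly ``tune_length`` values
along each tunable axis (rf: mtry; adaboost: mfinal x maxdepth x coeflearn;
radial SVM: sigma x cost; linear SVM: cost), scores each candidate by
resampling — out-of-bag for the forest, 10-fold cross-validation otherwise —
and refits the best candidate on the full training set.

The user-facing surface follows the model/results idiom:

    fit = StabilityClassifier(X, y, feature_names, config).fit()
    fit.resample_accuracy, fit.resample_kappa, fit.params
    fit.predict(X_new); fit.feature_importance(); print(fit.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.metrics import accuracy_score, cohen_kappa_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "ModelConfig",
    "StabilityClassifier",
    "StabilityFit",
    "preprocess_fit",
    "preprocess_apply",
    "tune_and_train",
    "predict_class",
    "feature_importance",
]

_ALGORITHMS = ("rf", "adaboost", "svm_radial", "svm_linear")

#: AdaBoost weight-update flavours mapped onto SAMME learning rates:
#: Breiman's half-log weights, Freund's full log weights, and Zhu's
#: multiclass-corrected (SAMME) update with an aggressive rate.
_COEFLEARN_RATE = {"Breiman": 0.5, "Freund": 1.0, "Zhu": 1.5}


@dataclass(frozen=True)
class ModelConfig:
    """Algorithm choice plus the tuning protocol.

    ``fixed_hyperparameters`` bypasses the grid search (the resampling pass
    still runs once to report honest resample metrics); the tuned values a
    fidelity run would pin (e.g. mtry, sigma, cost) go here.
    """

    algorithm: str = "rf"
    tune_length: int = 10
    seed: int = 0
    rf_trees: int = 500
    fixed_hyperparameters: Mapping[str, object] | None = None

    def __post_init__(self) -> None:
        if self.algorithm not in _ALGORITHMS:
            raise ValueError(f"algorithm must be one of {_ALGORITHMS}, got {self.algorithm!r}")
        if self.tune_length < 1:
            raise ValueError("tune_length must be >= 1")

    @property
    def validation(self) -> str:
        """Resampling scheme bound to the algorithm: OOB for rf, else 10-fold CV."""
        return "oob" if self.algorithm == "rf" else "cv10"


def preprocess_fit(X_train: np.ndarray) -> StandardScaler:
    """Fit a centring/scaling transform on the training matrix only."""
    X_train = np.asarray(X_train, dtype=float)
    sd = X_train.std(axis=0)
    if np.any(sd == 0.0):
        bad = np.flatnonzero(sd == 0.0)
        raise ValueError(f"zero-variance columns must be filtered before scaling: indices {bad.tolist()}")
    return StandardScaler().fit(X_train)


def preprocess_apply(scaler: StandardScaler, X: np.ndarray) -> np.ndarray:
    """Apply training statistics to any matrix (test means stay nonzero)."""
    return scaler.transform(np.asarray(X, dtype=float))


def _grid(config: ModelConfig, p: int, X: np.ndarray) -> list[dict[str, object]]:
    t = config.tune_length
    if config.fixed_hyperparameters is not None:
        return [dict(config.fixed_hyperparameters)]
    if config.algorithm == "rf":
        lo, hi = max(1, int(round(np.sqrt(p) / 4))), max(2, p // 2)
        vals = np.unique(np.round(np.geomspace(lo, hi, t)).astype(int))
        return [{"mtry": int(v)} for v in vals]
    if config.algorithm == "adaboost":
        mfinals = np.unique(np.linspace(50, 500, min(t, 10)).round().astype(int))
        depths = range(1, min(t, 10) + 1)
        return [
            {"mfinal": int(m), "maxdepth": int(d), "coeflearn": c}
            for m in mfinals
            for d in depths
            for c in ("Breiman", "Freund", "Zhu")
        ]
    costs = [float(2.0**k) for k in range(-2, -2 + min(t, 10))]
    if config.algorithm == "svm_linear":
        return [{"cost": c} for c in costs]
    # radial: sigma grid seeded by the median heuristic on pairwise distances
    rng = np.random.default_rng(config.seed)
    sub = X[rng.choice(X.shape[0], size=min(200, X.shape[0]), replace=False)]
    d2 = np.sum((sub[:, None, :] - sub[None, :, :]) ** 2, axis=-1)
    med = np.median(d2[np.triu_indices_from(d2, k=1)])
    sigma0 = 1.0 / (2.0 * med) if med > 0 else 1.0
    sigmas = sigma0 * np.geomspace(0.25, 4.0, min(t, 10))
    return [{"sigma": float(s), "cost": c} for s in sigmas for c in costs]


def _make_estimator(config: ModelConfig, params: Mapping[str, object], p: int):
    seed = config.seed
    if config.algorithm == "rf":
        return RandomForestClassifier(
            n_estimators=config.rf_trees,
            max_features=min(int(params["mtry"]), p),
            oob_score=True,
            random_state=seed,
            n_jobs=1,
        )
    if config.algorithm == "adaboost":
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=int(params["maxdepth"]), random_state=seed),
            n_estimators=int(params["mfinal"]),
            learning_rate=_COEFLEARN_RATE[str(params["coeflearn"])],
            random_state=seed,
        )
    if config.algorithm == "svm_radial":
        return SVC(kernel="rbf", gamma=float(params["sigma"]), C=float(params["cost"]), random_state=seed)
    return SVC(kernel="linear", C=float(params["cost"]), random_state=seed)


def _resample_metrics(
    config: ModelConfig, params: Mapping[str, object], X: np.ndarray, y: np.ndarray
) -> tuple[float, float]:
    """Held-out (accuracy, kappa): OOB predictions for rf, 10-fold CV otherwise."""
    p = X.shape[1]
    if config.validation == "oob":
        est = _make_estimator(config, params, p).fit(X, y)
        proba = est.oob_decision_function_
        pred = est.classes_[np.argmax(proba, axis=1)]
        return accuracy_score(y, pred), cohen_kappa_score(y, pred)
    classes = np.unique(y)
    if len(y) < 10 * len(classes):
        raise ValueError(f"10-fold CV needs at least {10 * len(classes)} samples, got {len(y)}")
    cv = StratifiedKFold(n_splits=10, shuffle=True, random_state=config.seed)
    pred = np.empty(len(y), dtype=y.dtype)
    for tr, te in cv.split(X, y):
        est = _make_estimator(config, params, p).fit(X[tr], y[tr])
        pred[te] = est.predict(X[te])
    return accuracy_score(y, pred), cohen_kappa_score(y, pred)


class StabilityClassifier:
    """Model object: training data plus the tuning protocol.

    Parameters
    ----------
    X : array, n x p — selected features only, unscaled.
    y : array of class labels (three-class downstream, any >= 2 accepted).
    feature_names : column names, used for name-based prediction alignment.
    config : ModelConfig.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: Sequence[str],
        feature_names: Sequence[str],
        config: ModelConfig = ModelConfig(),
    ):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y)
        self.feature_names = list(feature_names)
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length does not match matrix width")
        self.config = config

    def fit(self) -> "StabilityFit":
        """Grid search by resample accuracy, then refit on all training rows."""
        scaler = preprocess_fit(self.X)
        Xs = preprocess_apply(scaler, self.X)
        results = []
        for params in _grid(self.config, Xs.shape[1], Xs):
            acc, kap = _resample_metrics(self.config, params, Xs, self.y)
            results.append((params, acc, kap))
        best_params, best_acc, best_kappa = max(results, key=lambda r: (r[1], r[2]))
        est = _make_estimator(self.config, best_params, Xs.shape[1]).fit(Xs, self.y)
        return StabilityFit(
            model=self,
            scaler=scaler,
            estimator=est,
            params=dict(best_params),
            resample_accuracy=float(best_acc),
            resample_kappa=float(best_kappa),
            grid_results=[(dict(p), float(a), float(k)) for p, a, k in results],
        )


@dataclass
class StabilityFit:
    """Results object: fitted estimator, chosen hyperparameters, diagnostics."""

    model: StabilityClassifier
    scaler: StandardScaler
    estimator: object
    params: dict[str, object]
    resample_accuracy: float
    resample_kappa: float
    grid_results: list[tuple[dict[str, object], float, float]] = field(default_factory=list)

    def _align(self, X: np.ndarray, feature_names: Sequence[str] | None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        names = self.model.feature_names
        if feature_names is None:
            if X.ndim != 2 or (X.shape[0] and X.shape[1] != len(names)):
                raise ValueError(f"expected {len(names)} columns, got {X.shape}")
            return X
        feature_names = list(feature_names)
        missing = [n for n in names if n not in feature_names]
        if missing:
            raise ValueError(f"prediction matrix lacks trained features: {missing}")
        idx = [feature_names.index(n) for n in names]
        return X[:, idx]

    def predict(self, X: np.ndarray, feature_names: Sequence[str] | None = None) -> np.ndarray:
        """Predict class labels; columns are aligned by name when given."""
        X = self._align(X, feature_names)
        if X.shape[0] == 0:
            return np.array([], dtype=self.model.y.dtype)
        return self.estimator.predict(preprocess_apply(self.scaler, X))

    def feature_importance(self) -> dict[str, float]:
        """Importances scaled so the top feature scores 100 (rf/adaboost only)."""
        imp = getattr(self.estimator, "feature_importances_", None)
        if imp is None:
            raise ValueError(f"{self.model.config.algorithm} does not expose feature importances")
        top = imp.max()
        scaled = imp * (100.0 / top) if top > 0 else imp
        return dict(zip(self.model.feature_names, scaled.tolist()))

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Stability classifier fit",
            "========================",
            f"algorithm:          {cfg.algorithm}",
            f"validation:         {cfg.validation}",
            f"n training rows:    {self.model.X.shape[0]}",
            f"n features:         {self.model.X.shape[1]}",
            f"chosen parameters:  {self.params}",
            f"resample accuracy:  {self.resample_accuracy:.3f}",
            f"resample kappa:     {self.resample_kappa:.3f}",
        ]
        return "\n".join(lines)


def tune_and_train(
    X: np.ndarray,
    y: Sequence[str],
    feature_names: Sequence[str],
    config: ModelConfig = ModelConfig(),
) -> StabilityFit:
    """Functional wrapper over :class:`StabilityClassifier`."""
    return StabilityClassifier(X, y, feature_names, config).fit()


def predict_class(
    fit: StabilityFit, X: np.ndarray, feature_names: Sequence[str] | None = None
) -> np.ndarray:
    return fit.predict(X, feature_names)


def feature_importance(fit: StabilityFit) -> dict[str, float]:
    return fit.feature_importance()
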