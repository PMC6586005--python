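"""All-relevant feature selection against permuted shadow features.

Each iteration appends a column-wise permuted copy of the feature matrix
(the "shadows"), fits a random forest, and scores a *hit* for every real
feature whose importance exceeds the best shadow importance.  Across
iterations the hit count of an uninformative feature behaves like a
Binomial(runs, 1/2) draw is too generous — in truth beating the maximum of
all shadows is much harder — so the classical two-sided binomial test at a
Bonferroni-adjusted level is conservative for rejection and demanding for
confirmation, exactly the property wanted for an all-relevant screen.

Features that are neither confirmed nor rejected when the run budget is
exhausted remain *tentative* and are excluded from downstream models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

__all__ = ["BorutaConfig", "FeatureDecision", "shadow_augment", "boruta_run", "selected_features"]


@dataclass(frozen=True)
class BorutaConfig:
    """Settings for the shadow-feature selection loop.

    significance is the two-sided test level, Bonferroni-adjusted by the
    number of features; importance is "permutation" (robust on sparse binary
    bits, the default) or "impurity" (much faster, mildly cardinality-biased).
    """

    max_runs: int = 100
    significance: float = 0.01
    rf_trees: int = 500
    seed: int = 0
    importance: str = "permutation"
    permutation_repeats: int = 3

    def __post_init__(self) -> None:
        if self.max_runs < 10:
            raise ValueError("max_runs must be >= 10")
        if not 0.0 < self.significance < 1.0:
            raise ValueError("significance must lie in (0, 1)")
        if self.importance not in {"permutation", "impurity"}:
            raise ValueError(f"unknown importance measure {self.importance!r}")


@dataclass(frozen=True)
class FeatureDecision:
    feature_name: str
    decision: str  # confirmed | rejected | tentative
    hit_count: int
    runs: int

    def __post_init__(self) -> None:
        if self.hit_count > self.runs:
            raise ValueError("hit_count cannot exceed runs")


def shadow_augment(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Return ``[X | shadow]`` where each shadow column is a permutation of
    the corresponding real column.  X itself is left untouched."""
    X = np.asarray(X)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to permute")
    shadow = X.copy()
    for j in range(shadow.shape[1]):
        shadow[:, j] = shadow[rng.permutation(shadow.shape[0]), j]
    return np.hstack([X, shadow])


def _importances(
    X: np.ndarray, y: np.ndarray, config: BorutaConfig, seed: int
) -> np.ndarray:
    rf = RandomForestClassifier(
        n_estimators=config.rf_trees,
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(X, y)
    if config.importance == "impurity":
        return rf.feature_importances_
    r = permutation_importance(
        rf, X, y, n_repeats=config.permutation_repeats, random_state=seed, n_jobs=1
    )
    return r.importances_mean


def boruta_run(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str] | None = None,
    config: BorutaConfig = BorutaConfig(),
) -> list[FeatureDecision]:
    """Run the shadow-feature selection loop and decide every feature.

    Per iteration a feature still undecided scores a hit when its importance
    exceeds the maximum shadow importance.  After each iteration a two-sided
    binomial test (p = 1/2) at ``significance / n_features`` confirms features
    with significantly many hits and rejects those with significantly few;
    survivors at ``max_runs`` are tentative.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("class labels must contain at least 2 classes")
    n, p = X.shape
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(p)]
    if len(feature_names) != p:
        raise ValueError("feature_names length does not match matrix width")

    rng = np.random.default_rng(config.seed)
    alpha = config.significance / p  # Bonferroni over features
    status = np.full(p, "tentative", dtype=object)
    hits = np.zeros(p, dtype=int)
    runs_at_decision = np.zeros(p, dtype=int)
    runs = 0

    for it in range(config.max_runs):
        active = np.flatnonzero(status == "tentative")
        if active.size == 0:
            break
        Xa = X[:, active]
        aug = shadow_augment(Xa, rng)
        imp = _importances(aug, y, config, seed=int(rng.integers(2**31 - 1)))
        real, shadow = imp[: active.size], imp[active.size :]
        threshold = shadow.max()
        hits[active] += (real > threshold).astype(int)
        runs += 1

        for j in active:
            # two-sided: significantly more hits than chance -> confirmed,
            # significantly fewer -> rejected
            if binom.sf(hits[j] - 1, runs, 0.5) < alpha:
                status[j] = "confirmed"
                runs_at_decision[j] = runs
            elif binom.cdf(hits[j], runs, 0.5) < alpha:
                status[j] = "rejected"
                runs_at_decision[j] = runs

    runs_at_decision[status == "tentative"] = runs
    return [
        FeatureDecision(feature_names[j], str(status[j]), int(hits[j]), int(runs_at_decision[j]))
        for j in range(p)
    ]


def selected_features(decisions: list[FeatureDecision]) -> list[str]:
    """Names of confirmed features (tentative ones are excluded, strictly)."""
    return [d.feature_name for d in decisions if d.decision == "confirmed"]
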