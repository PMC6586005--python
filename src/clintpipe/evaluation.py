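"""Evaluation of three-class stability predictions.

Beyond the standard confusion matrix, accuracy, Cohen's kappa and one-vs-rest
per-class statistics, this module computes the *critical mis-prediction*
percentage: the fraction of test compounds confused between the two extreme
classes (observed unstable predicted stable, or observed stable predicted
unstable) — the two clinically worst mistakes, since they either advance a
rapidly cleared compound or discard a stable one.  Errors into or out of the
moderate class never count as critical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .pk_model import StabilityClass, round_half_up

__all__ = [
    "CLASS_ORDER",
    "ConfusionMatrix3",
    "EvaluationReport",
    "confusion",
    "accuracy",
    "kappa",
    "critical_misprediction",
    "per_class_stats",
    "evaluate",
]

CLASS_ORDER = (StabilityClass.STABLE, StabilityClass.MODERATE, StabilityClass.UNSTABLE)
_INDEX = {c: i for i, c in enumerate(CLASS_ORDER)}
_INDEX.update({c.value: i for i, c in enumerate(CLASS_ORDER)})


@dataclass(frozen=True)
class ConfusionMatrix3:
    """3x3 counts; rows are observed classes, columns predicted, in the order
    (stable, moderate, unstable)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (3, 3):
            raise ValueError("confusion matrix must be 3x3")
        if (c < 0).any() or not np.issubdtype(c.dtype, np.integer):
            raise ValueError("confusion matrix entries must be nonnegative integers")
        object.__setattr__(self, "counts", c)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_rows(cls, stable_row, moderate_row, unstable_row) -> "ConfusionMatrix3":
        return cls(np.array([stable_row, moderate_row, unstable_row], dtype=int))


def confusion(obs: Sequence, pred: Sequence) -> ConfusionMatrix3:
    """Tally observed-vs-predicted labels into a ConfusionMatrix3."""
    if len(obs) != len(pred):
        raise ValueError("obs and pred must have equal length")
    if len(obs) == 0:
        raise ValueError("cannot build a confusion matrix from empty inputs")
    counts = np.zeros((3, 3), dtype=int)
    for o, p in zip(obs, pred):
        try:
            counts[_INDEX[o], _INDEX[p]] += 1
        except KeyError as exc:
            raise ValueError(f"unknown class label {exc.args[0]!r}") from None
    return ConfusionMatrix3(counts)


def accuracy(cm: ConfusionMatrix3) -> float:
    """Fraction of correctly classified compounds: trace / n."""
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts)) / cm.n


def kappa(cm: ConfusionMatrix3) -> float:
    """Cohen's kappa: observed agreement corrected for chance agreement.

    kappa = (p_o - p_e) / (1 - p_e), with p_e the sum over classes of the
    products of row and column marginal frequencies.  When p_e = 1 (all mass
    in one cell of the marginals) chance correction is undefined and a
    ValueError is raised rather than returning NaN.
    """
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    c = cm.counts.astype(float)
    n = cm.n
    p_o = np.trace(c) / n
    p_e = float((c.sum(axis=1) / n) @ (c.sum(axis=0) / n))
    if p_e >= 1.0:
        raise ValueError("chance agreement is 1; kappa undefined")
    return float((p_o - p_e) / (1.0 - p_e))


def critical_misprediction(cm: ConfusionMatrix3) -> float:
    """Percentage of stable<->unstable confusions among all test compounds.

    100 * (counts[unstable, stable] + counts[stable, unstable]) / n.  Changes
    confined to the moderate row or column cannot affect it.
    """
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    i_s, i_u = _INDEX[StabilityClass.STABLE], _INDEX[StabilityClass.UNSTABLE]
    return 100.0 * (int(cm.counts[i_u, i_s]) + int(cm.counts[i_s, i_u])) / cm.n


def per_class_stats(cm: ConfusionMatrix3) -> dict[str, dict[str, float | None]]:
    """One-vs-rest sensitivity, specificity, PPV, NPV and balanced accuracy.

    Cells whose denominator is zero (e.g. sensitivity of a class absent from
    the observations) are reported as None rather than NaN.
    """
    out: dict[str, dict[str, float | None]] = {}
    c = cm.counts
    n = cm.n
    for cls, i in ((cl, _INDEX[cl]) for cl in CLASS_ORDER):
        tp = int(c[i, i])
        fn = int(c[i, :].sum()) - tp
        fp = int(c[:, i].sum()) - tp
        tn = n - tp - fn - fp

        def ratio(num: int, den: int) -> float | None:
            return num / den if den > 0 else None

        sens = ratio(tp, tp + fn)
        spec = ratio(tn, tn + fp)
        bal = (sens + spec) / 2.0 if sens is not None and spec is not None else None
        out[cls.value] = {
            "sensitivity": sens,
            "specificity": spec,
            "ppv": ratio(tp, tp + fp),
            "npv": ratio(tn, tn + fn),
            "balanced_accuracy": bal,
            "prevalence": ratio(tp + fn, n),
        }
    return out


@dataclass
class EvaluationReport:
    """Complete evaluation surface for one model on one test set."""

    cm: ConfusionMatrix3
    accuracy: float
    kappa: float
    critical_mispredict_pct: float
    per_class: dict[str, dict[str, float | None]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        """JSON-ready report; rates to 3 d.p., percentages to 2 d.p."""
        return {
            "confusion": self.cm.counts.tolist(),
            "n": self.cm.n,
            "accuracy": round_half_up(self.accuracy, 3),
            "kappa": round_half_up(self.kappa, 3),
            "critical_mispredict_pct": round_half_up(self.critical_mispredict_pct, 2),
            "per_class": {
                cls: {k: (None if v is None else round_half_up(v, 3)) for k, v in stats.items()}
                for cls, stats in self.per_class.items()
            },
        }


def evaluate(obs: Sequence, pred: Sequence) -> EvaluationReport:
    """Build the full report from observed and predicted label sequences."""
    cm = confusion(obs, pred)
    return EvaluationReport(
        cm=cm,
        accuracy=accuracy(cm),
        kappa=kappa(cm),
        critical_mispredict_pct=critical_misprediction(cm),
        per_class=per_class_stats(cm),
    )
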