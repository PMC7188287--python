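"""Diagnostic performance of an eGFR equation at the mGFR < 45 task.

The positive class is reduced kidney function (mGFR below the clinical
cutoff, default 45 mL/min/1.73 m**2), and lower eGFR indicates a
positive test.  AUC is computed with the rank (Mann-Whitney) formula --
for a single monotone predictor this is identical to the ROC of a
fitted logistic-regression score, because the logit is monotone in the
predictor.  Sensitivity, specificity, predictive values and likelihood
ratios are taken from the 2x2 table at the cutoff; undefined margins
yield NaN flags (or an infinite likelihood ratio for a perfect test),
never a crash.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "DiagnosticTask",
    "DiagnosticReport",
    "auc",
    "confusion_metrics",
    "plr_band",
]


@dataclass(frozen=True)
class DiagnosticTask:
    """Binary labels (1 = mGFR < cutoff) with eGFR scores.

    Lower scores indicate the positive class; ``threshold`` is the
    operating cutoff for the 2x2 table metrics.
    """

    labels: np.ndarray
    scores: np.ndarray
    threshold: float = 45.0

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=int)
        scores = np.asarray(self.scores, dtype=float)
        if labels.shape != scores.shape or labels.ndim != 1:
            raise ValueError("labels and scores must be one-dimensional and of equal length")
        if not np.all(np.isin(labels, (0, 1))):
            raise ValueError("labels must be binary (0/1)")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "scores", scores)

    @classmethod
    def from_mgfr(cls, egfr, mgfr, threshold: float = 45.0) -> "DiagnosticTask":
        mgfr = np.asarray(mgfr, dtype=float)
        return cls(labels=(mgfr < threshold).astype(int), scores=egfr, threshold=threshold)


@dataclass(frozen=True)
class DiagnosticReport:
    """AUC and 2x2-table metrics for one equation at the cutoff."""

    auc: Optional[float]
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    plr: float
    nlr: float
    n: int

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def auc(task: DiagnosticTask) -> float:
    """Probability that a random positive scores below a random negative.

    Mann-Whitney rank form with ties counted 1/2.  Not forced above 0.5:
    a predictor oriented the wrong way yields AUC < 0.5.
    """
    pos = task.labels == 1
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(task.scores)  # average ranks handle ties
    # sum of positive ranks counts pairs where positive > negative
    u_pos_greater = float(ranks[pos].sum()) - n_pos * (n_pos + 1) / 2.0
    return 1.0 - u_pos_greater / (n_pos * n_neg)


def confusion_metrics(task: DiagnosticTask, include_auc: bool = True) -> DiagnosticReport:
    """2x2-table metrics at the cutoff (positive test = eGFR < threshold).

    Empty margins give NaN for the affected metric; a perfect test
    reports PLR = +inf.
    """
    predicted_pos = task.scores < task.threshold
    actual_pos = task.labels == 1
    tp = int(np.sum(predicted_pos & actual_pos))
    fp = int(np.sum(predicted_pos & ~actual_pos))
    fn = int(np.sum(~predicted_pos & actual_pos))
    tn = int(np.sum(~predicted_pos & ~actual_pos))

    def _ratio(num: int, den: int) -> float:
        return num / den if den > 0 else math.nan

    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    ppv = _ratio(tp, tp + fp)
    npv = _ratio(tn, tn + fn)
    if math.isnan(sens) or math.isnan(spec):
        plr = nlr = math.nan
    else:
        plr = sens / (1.0 - spec) if spec < 1.0 else (math.inf if sens > 0 else math.nan)
        nlr = (1.0 - sens) / spec if spec > 0 else math.nan
    auc_value = None
    if include_auc:
        try:
            auc_value = auc(task)
        except ValueError:
            auc_value = None
    return DiagnosticReport(
        auc=auc_value,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        plr=plr,
        nlr=nlr,
        n=len(task.labels),
    )


def plr_band(plr: float) -> str:
    """Effect-size band for a positive likelihood ratio.

    >10 large; 5-10 moderate (both edges moderate); <5 small.
    """
    if not plr > 0:
        raise ValueError("positive likelihood ratio must be > 0")
    if plr > 10.0:
        return "large"
    if plr >= 5.0:
        return "moderate"
    return "small"
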