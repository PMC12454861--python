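"""Empirical ROC curves, AUC, Youden's J cutpoints, sensitivity inversion.

Conventions (isolated here so the rest of the pipeline inherits them):

* a case is called positive iff ``score >= threshold``;
* candidate thresholds are the unique observed scores, descending, preceded
  by a sentinel just above the maximum score (the sens=0, spec=1 corner);
* tied scores collapse to a single operating point — no interpolation;
* AUC is the trapezoidal area over (1 - specificity, sensitivity), which
  equals the Mann-Whitney U statistic / (n_pos * n_neg) with ties counted
  one half.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RocPoint",
    "RocCurve",
    "DegenerateCohortError",
    "roc_curve",
    "auc",
    "youden_threshold",
    "threshold_for_sensitivity",
]


class DegenerateCohortError(ValueError):
    """Raised when ROC analysis is attempted on single-class labels."""


@dataclass(frozen=True)
class RocPoint:
    """One operating point: threshold with its sensitivity and specificity."""

    threshold: float
    sensitivity: float
    specificity: float

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC curve for one reader x pathology x RFS level.

    ``thresholds`` descend from the sentinel (above the maximum score) to the
    minimum observed score; ``sensitivity`` is non-decreasing and
    ``specificity`` non-increasing along the curve.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    n_pos: int
    n_neg: int
    reader_id: str | None = None
    pathology: str | None = None
    rfs_level: str | None = None

    @property
    def points(self) -> list[RocPoint]:
        return [
            RocPoint(float(t), float(se), float(sp))
            for t, se, sp in zip(self.thresholds, self.sensitivity, self.specificity)
        ]

    @property
    def youden_j(self) -> np.ndarray:
        return self.sensitivity + self.specificity - 1.0


def roc_curve(
    scores: np.ndarray,
    labels: np.ndarray,
    *,
    reader_id: str | None = None,
    pathology: str | None = None,
    rfs_level: str | None = None,
) -> RocCurve:
    """Exact empirical ROC curve over all observed operating points.

    ``labels`` are binary reference labels; at least one positive and one
    negative are required, otherwise sensitivity or specificity is undefined
    and a :class:`DegenerateCohortError` names the missing class.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D arrays of equal length")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0:
        raise DegenerateCohortError("no positive cases under this reference standard")
    if n_neg == 0:
        raise DegenerateCohortError("no negative cases under this reference standard")

    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]

    # block boundaries: last index of each tied-score run
    distinct = np.r_[s[1:] != s[:-1], True]
    tp_cum = np.cumsum(y)[distinct]
    fp_cum = np.cumsum(~y)[distinct]
    uniq = s[distinct]

    sentinel = float(np.nextafter(s[0], np.inf))
    thresholds = np.r_[sentinel, uniq]
    sens = np.r_[0.0, tp_cum / n_pos]
    spec = np.r_[1.0, 1.0 - fp_cum / n_neg]

    return RocCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        n_pos=n_pos,
        n_neg=n_neg,
        reader_id=reader_id,
        pathology=pathology,
        rfs_level=rfs_level,
    )


def auc(curve: RocCurve) -> float:
    """Trapezoidal area under the ROC curve.

    Equals the probability that a random positive case outscores a random
    negative one, counting ties one half (the normalized Mann-Whitney U).
    Prevalence-independent: duplicating every case of one class leaves it
    unchanged.
    """
    fpr = 1.0 - curve.specificity
    return float(np.trapezoid(curve.sensitivity, fpr))


def youden_threshold(curve: RocCurve) -> tuple[float, float]:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Among equal maximizers the highest threshold is returned — the most
    specific operating point, i.e. the fewest alerts at equal J.
    """
    j = curve.youden_j
    # ties resolved within float tolerance: J computed at different operating
    # points can differ by one ulp for mathematically equal values
    best = int(np.flatnonzero(j >= j.max() - 1e-12)[0])  # thresholds descend
    return float(curve.thresholds[best]), float(j[best])


def threshold_for_sensitivity(curve: RocCurve, target_sens_pct: float) -> tuple[float, float]:
    """Largest threshold whose sensitivity reaches ``target_sens_pct``.

    The minimal sensitization achieving the target: since sensitivity only
    grows as the threshold drops, this is the first operating point (scanning
    thresholds downward) with sensitivity >= target.  Returns ``(threshold,
    realized_sensitivity_pct)`` — on a step-function curve the realized
    sensitivity may exceed the requested one.
    """
    if not 0.0 <= target_sens_pct <= 100.0:
        raise ValueError(f"target sensitivity {target_sens_pct} outside [0, 100]%")
    target = target_sens_pct / 100.0
    # sensitivity is non-decreasing along descending thresholds
    idx = int(np.argmax(curve.sensitivity >= target - 1e-12))
    return float(curve.thresholds[idx]), float(curve.sensitivity[idx] * 100.0)
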