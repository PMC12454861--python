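"""Diagnostic 2x2 metrics, Wald intervals, and summary-table reconstruction.

Provides the prevalence-dependent evaluation layer: confusion tables from an
expert sample reading at a given threshold, the standard metric battery
(sensitivity, specificity, accuracy, PPV, NPV, FNR, FPR) with 95% Wald
confidence intervals, two-proportion comparison tests, projection of
expected positive counts onto full subgroup sizes, and reconstruction of
integer 2x2 tables from published one-decimal summary percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
from scipy import stats

from .cohorts import ClinicalCohort

__all__ = [
    "ConfusionTable",
    "ConfidenceInterval",
    "MetricEstimate",
    "MetricsReport",
    "confusion",
    "metrics",
    "wald_ci",
    "compare_proportions",
    "reconstruct_table",
    "estimate_clinical_counts",
    "InconsistentSummaryError",
]

Z_95 = 1.959964  # two-sided 95% normal quantile


class InconsistentSummaryError(ValueError):
    """No integer counts reproduce the printed summary percentages."""


@dataclass(frozen=True)
class ConfusionTable:
    """Integer 2x2 contingency table of AI calls against the reference."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class ConfidenceInterval:
    lower: float
    upper: float
    level: float = 0.95


@dataclass(frozen=True)
class MetricEstimate:
    """One diagnostic metric in percent with its Wald CI.

    ``defined`` is False when the metric's denominator is zero (e.g. PPV with
    no positive calls); the value is then not meaningful and CIs are absent.
    """

    value: float | None
    ci: ConfidenceInterval | None
    numerator: int
    denominator: int

    @property
    def defined(self) -> bool:
        return self.denominator > 0


@dataclass(frozen=True)
class MetricsReport:
    sensitivity: MetricEstimate
    specificity: MetricEstimate
    accuracy: MetricEstimate
    ppv: MetricEstimate
    npv: MetricEstimate
    fnr: MetricEstimate
    fpr: MetricEstimate
    n: int
    prevalence_pct: float

    def to_dict(self) -> dict:
        out: dict = {"n": self.n, "prevalence_pct": round(self.prevalence_pct, 6)}
        for name in ("sensitivity", "specificity", "accuracy", "ppv", "npv", "fnr", "fpr"):
            est: MetricEstimate = getattr(self, name)
            if est.defined:
                out[name] = {
                    "pct": round(est.value, 6),
                    "ci_lower_pct": round(est.ci.lower, 6),
                    "ci_upper_pct": round(est.ci.upper, 6),
                    "numerator": est.numerator,
                    "denominator": est.denominator,
                }
            else:
                out[name] = {"undefined": True, "denominator": 0}
        return out


def wald_ci(successes: int, n: int, level: float = 0.95) -> ConfidenceInterval:
    """Wald normal-approximation CI for a binomial proportion, in percent.

    ``p_hat +/- z * sqrt(p_hat (1 - p_hat) / n)``, clipped to [0, 100].  The
    Wald form (rather than Wilson or Clopper-Pearson) is the package default
    because it matches the bracketed intervals of typical reader-study
    reports; degenerate cases (0 or n successes) collapse to a point.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    p = successes / n
    half = z * math.sqrt(p * (1.0 - p) / n)
    return ConfidenceInterval(
        lower=max(0.0, (p - half) * 100.0),
        upper=min(100.0, (p + half) * 100.0),
        level=level,
    )


def _estimate(numerator: int, denominator: int) -> MetricEstimate:
    if denominator == 0:
        return MetricEstimate(None, None, numerator, 0)
    return MetricEstimate(
        value=100.0 * numerator / denominator,
        ci=wald_ci(numerator, denominator),
        numerator=numerator,
        denominator=denominator,
    )


def metrics(table: ConfusionTable) -> MetricsReport:
    """Standard diagnostic metric battery with 95% Wald CIs, in percent.

    Each metric is a binomial proportion with its own numerator/denominator;
    zero-denominator metrics are flagged undefined rather than NaN.
    """
    if table.n == 0:
        raise ValueError("empty confusion table")
    return MetricsReport(
        sensitivity=_estimate(table.tp, table.positives),
        specificity=_estimate(table.tn, table.negatives),
        accuracy=_estimate(table.tp + table.tn, table.n),
        ppv=_estimate(table.tp, table.tp + table.fp),
        npv=_estimate(table.tn, table.tn + table.fn),
        fnr=_estimate(table.fn, table.positives),
        fpr=_estimate(table.fp, table.negatives),
        n=table.n,
        prevalence_pct=100.0 * table.positives / table.n,
    )


def confusion(
    clinical: ClinicalCohort,
    pathology: str,
    threshold: float,
    subgroup: str | None = None,
) -> ConfusionTable:
    """Confusion table of AI calls (score >= threshold) on the sample reading."""
    sample = clinical.labelled_sample(pathology, subgroup)
    call = sample["ai_score"].to_numpy() >= threshold
    truth = sample["reference_positive"].to_numpy().astype(bool)
    return ConfusionTable(
        tp=int((call & truth).sum()),
        fp=int((call & ~truth).sum()),
        fn=int((~call & truth).sum()),
        tn=int((~call & ~truth).sum()),
    )


def compare_proportions(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sample proportion test p-value.

    Continuity-corrected chi-square on the 2x2 table; when any expected cell
    is below 5 the test falls back to Fisher's exact test.  Used to compare
    metric proportions between thresholds on the same sample reading (an
    unpaired approximation).
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must lie within their group sizes")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    if (expected < 5).any():
        _, p = stats.fisher_exact(table)
        return float(p)
    if k1 * n2 == k2 * n1:  # identical proportions: statistic 0 by construction
        return 1.0
    _, p, _, _ = stats.chi2_contingency(table, correction=True)
    return float(p)


def _match_count(pct: float, denom: int, what: str, tol: float = 0.05) -> tuple[int, bool]:
    """Integer k in [0, denom] rendering closest to pct as 100k/denom.

    Returns ``(k, ambiguous)``; ambiguous flags a tie between adjacent counts
    (resolved toward the larger).  Raises when even the best k misses the
    printed percent by more than ``tol`` percentage points.
    """
    if denom == 0:
        if pct not in (0.0,):
            raise InconsistentSummaryError(f"{what}: percent {pct} with empty denominator")
        return 0, False
    ks = np.arange(denom + 1)
    err = np.abs(100.0 * ks / denom - pct)
    best = err.min()
    if best > tol:
        raise InconsistentSummaryError(
            f"{what}: no count /{denom} reproduces {pct}% within {tol} points"
        )
    candidates = ks[np.isclose(err, best, atol=1e-9)]
    return int(candidates.max()), len(candidates) > 1


def reconstruct_table(
    sens_pct: float, spec_pct: float, prev_pct: float, n: int
) -> ConfusionTable:
    """Recover the integer 2x2 table behind printed summary percentages.

    Given one-decimal sensitivity, specificity and prevalence for a sample of
    size ``n``: positives P = round(prev * n / 100); tp is the integer
    rendering closest to the printed sensitivity over P, tn likewise from
    specificity over n - P.  Raises :class:`InconsistentSummaryError` when no
    integer count lands within 0.05 percentage points (half a printed
    decimal) of a stated percent.
    """
    for name, pct in (("sensitivity", sens_pct), ("specificity", spec_pct), ("prevalence", prev_pct)):
        if not 0.0 <= pct <= 100.0:
            raise ValueError(f"{name} {pct}% outside [0, 100]")
    if n <= 0:
        raise ValueError("n must be positive")
    positives, _ = _match_count(prev_pct, n, "prevalence")
    negatives = n - positives
    tp, _ = _match_count(sens_pct, positives, "sensitivity")
    tn, _ = _match_count(spec_pct, negatives, "specificity")
    return ConfusionTable(tp=tp, fp=negatives - tn, fn=positives - tp, tn=tn)


def estimate_clinical_counts(prev_pct: float, subgroup_size: int) -> int:
    """Expected positive count projected onto a full subgroup.

    Ceiling of ``prev_pct/100 * subgroup_size`` — the projection rounds any
    fractional expected case up to a whole case.
    """
    if prev_pct < 0 or subgroup_size < 0:
        raise ValueError("inputs must be non-negative")
    expected = prev_pct * subgroup_size / 100.0
    return int(math.ceil(round(expected, 9)))
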