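"""Subgroup-specific optimized thresholds by the slope criterion.

The optimized threshold (OT) marks the upper limit of a maximally justifiable
sensitization: scanning the sensitivity-to-alert-rate linkage curve upward,
the target sensitivity is the first grid point at which one more percentage
point of sensitivity costs more than one percentage point of alert rate in
clinical routine (forward-difference slope > 1 on the mean reader curve).
Per-reader OTs invert each reader's ROC curve at the common target
sensitivity; the aggregate OT is their mean (median available).  Outpatient-
and inpatient-optimized variants (OPOT/IPOT) differ only in the clinical
subgroup the linkage curve is computed on.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Literal, Mapping

import numpy as np

from .cohorts import (
    ClinicalCohort,
    EnrichedCohort,
    PathologyConfig,
    build_reference_standard,
)
from .linkage import LinkageCurve, alert_rate, default_sens_grid, linkage_curve
from .roc import RocCurve, roc_curve, threshold_for_sensitivity, youden_threshold

__all__ = [
    "OptimizationResult",
    "DEFAULT_SLOPE_WINDOW_PCT",
    "linkage_slopes",
    "find_target_sensitivity",
    "derive_ot",
    "reader_roc_curves",
    "optimize",
]


@dataclass(frozen=True)
class OptimizationResult:
    """Optimized threshold for one pathology x subgroup x RFS level."""

    pathology: str
    subgroup: str
    rfs_level: str
    target_sensitivity_pct: float
    criterion_triggered: bool
    per_reader_ot: Mapping[str, float]
    ot: float
    alert_at_ot_pct: float
    aidt: float | None = None
    alert_at_aidt_pct: float | None = None
    youden_by_reader: Mapping[str, float] | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rfs"] = d.pop("rfs_level")
        d["per_reader_ot"] = dict(self.per_reader_ot)
        if self.youden_by_reader is not None:
            d["youden_by_reader"] = dict(self.youden_by_reader)
        return d


DEFAULT_SLOPE_WINDOW_PCT = 5.0


def linkage_slopes(
    curve: LinkageCurve, slope_window_pct: float | None = DEFAULT_SLOPE_WINDOW_PCT
) -> np.ndarray:
    """Slope of mean alert% against mean realized sensitivity% at each grid point.

    Two estimators share one convention — the change in mean alert rate is
    divided by the change in *realized* mean sensitivity, not the requested
    grid step.  On step-function ROC curves a fixed grid step sometimes
    crosses two operating points and sometimes one; the realized denominator
    keeps the estimate centred on d(alert)/d(sensitivity) instead of
    aliasing against the grid.  Steps reaching no new operating point (zero
    realized change, hence zero alert change) carry no information and get
    slope ``-inf`` (they cannot trigger the criterion).

    ``slope_window_pct`` > grid step selects a centred secant over +/- that
    many percentage points of sensitivity (truncated at the grid ends).  A
    single inter-case gap of the enriched cohort's positive scores gives a
    noisy one-step slope (relative spread of order one for reader panels
    with ~10^2 positives); the windowed secant averages over many gaps and,
    because the true curve's slope rises monotonically, is unbiased to first
    order at the crossing.  ``None`` or a window <= grid step yields the
    plain one-step forward difference.
    """
    grid = np.asarray(curve.sens_grid, dtype=float)
    if grid.size < 2:
        raise ValueError("linkage grid needs at least two points")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("linkage grid must be strictly ascending")
    alert = np.asarray(curve.mean_alert_pct, dtype=float)
    realized = np.asarray(curve.mean_sens_realized, dtype=float)

    step = float(np.min(np.diff(grid)))
    slopes = np.full(grid.size - 1, -np.inf)
    windowed = slope_window_pct is not None and slope_window_pct > step
    for k in range(grid.size - 1):
        if windowed:
            lo = int(np.searchsorted(grid, grid[k] - slope_window_pct, side="left"))
            hi = int(np.searchsorted(grid, grid[k] + slope_window_pct, side="right")) - 1
            lo, hi = min(lo, k), max(hi, k + 1)
        else:
            lo, hi = k, k + 1
        d_sens = realized[hi] - realized[lo]
        if d_sens > 1e-12:
            slopes[k] = (alert[hi] - alert[lo]) / d_sens
    return slopes


def find_target_sensitivity(
    curve: LinkageCurve, slope_window_pct: float | None = DEFAULT_SLOPE_WINDOW_PCT
) -> tuple[float, bool]:
    """First grid sensitivity whose slope of mean alert% exceeds 1.

    Scans the ascending grid with the :func:`linkage_slopes` estimator and
    returns ``(grid_sensitivity_pct, True)`` at the first slope > 1, or
    ``(max grid sensitivity, False)`` if the criterion never triggers
    (further sensitization is then never disproportionate).
    """
    grid = np.asarray(curve.sens_grid, dtype=float)
    slopes = linkage_slopes(curve, slope_window_pct)
    # roundoff guard on the strict > 1 criterion (see analytic oracle)
    hits = np.flatnonzero(slopes > 1.0 + 1e-9)
    if hits.size:
        return float(grid[int(hits[0])]), True
    return float(grid[-1]), False


def derive_ot(
    rocs: list[RocCurve],
    target_sensitivity_pct: float,
    aggregate: Literal["mean", "median"] = "mean",
) -> tuple[dict[str, float], float]:
    """Per-reader thresholds at the common target sensitivity, plus aggregate.

    Each reader's OT is the largest threshold on that reader's ROC curve
    achieving the target sensitivity; the aggregate OT is their mean (or
    median, by configuration).
    """
    if not 0.0 <= target_sensitivity_pct <= 100.0:
        raise ValueError("target sensitivity outside [0, 100]%")
    per_reader: dict[str, float] = {}
    for i, curve in enumerate(rocs):
        reader = curve.reader_id or f"reader{i + 1}"
        thr, _realized = threshold_for_sensitivity(curve, target_sensitivity_pct)
        per_reader[reader] = thr
    values = np.array(list(per_reader.values()))
    agg = float(np.mean(values)) if aggregate == "mean" else float(np.median(values))
    return per_reader, agg


def reader_roc_curves(
    enriched: EnrichedCohort, pathology: str, rfs_level
) -> list[RocCurve]:
    """One ROC curve per reference reader for a pathology under one RFS."""
    scores = enriched.score_vector(pathology)
    curves = []
    for reader in enriched.readers:
        labels, _prev = build_reference_standard(enriched, reader, pathology, rfs_level)
        curves.append(
            roc_curve(
                scores,
                labels,
                reader_id=reader,
                pathology=pathology,
                rfs_level=rfs_level.name,
            )
        )
    return curves


def optimize(
    enriched: EnrichedCohort,
    clinical: ClinicalCohort,
    subgroup: str,
    pathology: str,
    config: PathologyConfig | None = None,
    *,
    sens_grid_pct: np.ndarray | None = None,
    aggregate: Literal["mean", "median"] = "mean",
    slope_window_pct: float | None = DEFAULT_SLOPE_WINDOW_PCT,
) -> tuple[OptimizationResult, LinkageCurve]:
    """End-to-end optimized-threshold derivation for one pathology x subgroup.

    Pipeline: pooled reference standards per reader -> per-reader ROC curves
    -> linkage curve against the clinical subgroup -> slope-criterion target
    sensitivity -> per-reader and aggregate OT -> alert rate at the aggregate
    OT.  Youden thresholds per reader and the vendor default (with its alert
    rate) are recorded for comparison.
    """
    rfs = config.rfs_level if config is not None else None
    if rfs is None:
        from .cohorts import RfsLevel

        rfs = RfsLevel.IV
    if sens_grid_pct is None:
        sens_grid_pct = default_sens_grid()

    try:
        rocs = reader_roc_curves(enriched, pathology, rfs)
    except Exception as exc:
        raise RuntimeError(f"ROC stage failed for {pathology!r}: {exc}") from exc

    try:
        link = linkage_curve(rocs, clinical, subgroup, sens_grid_pct)
    except Exception as exc:
        raise RuntimeError(f"linkage stage failed for {pathology!r}/{subgroup!r}: {exc}") from exc

    target, triggered = find_target_sensitivity(link, slope_window_pct)
    per_reader_ot, ot = derive_ot(rocs, target, aggregate=aggregate)
    alert_at_ot, _ = alert_rate(clinical, subgroup, pathology, ot)

    youden = {c.reader_id: youden_threshold(c)[0] for c in rocs}
    aidt = config.vendor_default_threshold if config is not None else None
    alert_at_aidt = (
        alert_rate(clinical, subgroup, pathology, aidt)[0] if aidt is not None else None
    )

    result = OptimizationResult(
        pathology=pathology,
        subgroup=subgroup,
        rfs_level=rfs.name,
        target_sensitivity_pct=target,
        criterion_triggered=triggered,
        per_reader_ot=per_reader_ot,
        ot=ot,
        alert_at_ot_pct=alert_at_ot,
        aidt=aidt,
        alert_at_aidt_pct=alert_at_aidt,
        youden_by_reader=youden,
    )
    return result, link
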