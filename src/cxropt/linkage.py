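"""Alert rates in clinical subgroups and sensitivity-to-alert-rate linkage.

The linkage curve is the pipeline's key intermediate: for each target
sensitivity on a grid, each reader's ROC curve (enriched cohort) is inverted
to the largest threshold achieving that sensitivity, and the threshold is
applied to the clinical subgroup to obtain the alert rate — the fraction of
routine cases the AI would flag.  The mean curve across readers drives the
optimized-threshold slope criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohorts import ClinicalCohort
from .roc import RocCurve, threshold_for_sensitivity

__all__ = ["LinkageCurve", "alert_rate", "linkage_curve", "default_sens_grid"]


def default_sens_grid(step_pct: float = 1.0) -> np.ndarray:
    """Ascending sensitivity grid 0..100% (the criterion is phrased per 1%)."""
    if not 0.0 < step_pct <= 5.0:
        raise ValueError("grid step must lie in (0, 5] percent")
    return np.arange(0.0, 100.0 + step_pct / 2, step_pct)


def alert_rate(
    clinical: ClinicalCohort, subgroup: str, pathology: str, threshold: float
) -> tuple[float, int]:
    """Alert rate of one threshold in a clinical subgroup.

    Returns ``(percent, count)`` where count is the number of subgroup cases
    with ``score >= threshold``.
    """
    scores = clinical.subgroup_scores(subgroup, pathology)
    count = int((scores >= threshold).sum())
    return 100.0 * count / scores.size, count


@dataclass(frozen=True)
class LinkageCurve:
    """Sensitivity grid with per-reader and mean alert rates in one subgroup.

    ``table`` has one row per (grid sensitivity, reader): columns sens_target,
    sens_realized, reader_id, threshold, alert_pct.  ``mean_alert_pct`` is the
    arithmetic mean of per-reader alert rates at each grid point (curves are
    averaged at fixed sensitivity, not thresholds).
    """

    pathology: str
    subgroup: str
    rfs_level: str
    sens_grid: np.ndarray
    table: pd.DataFrame
    mean_alert_pct: np.ndarray
    mean_sens_realized: np.ndarray

    @property
    def reader_ids(self) -> list[str]:
        return list(dict.fromkeys(self.table["reader_id"]))

    def reader_series(self, reader_id: str) -> pd.DataFrame:
        sub = self.table[self.table["reader_id"] == reader_id]
        if sub.empty:
            raise KeyError(f"no linkage series for reader {reader_id!r}")
        return sub.reset_index(drop=True)

    def export(self) -> pd.DataFrame:
        """Flat CSV-ready table including the mean curve columns."""
        out = self.table.copy()
        mean_map = dict(zip(self.sens_grid, self.mean_alert_pct))
        realized_map = dict(zip(self.sens_grid, self.mean_sens_realized))
        out.insert(0, "pathology", self.pathology)
        out.insert(1, "subgroup", self.subgroup)
        out.insert(2, "rfs", self.rfs_level)
        out["mean_alert_pct"] = out["sens_target"].map(mean_map)
        out["sens_realized_mean"] = out["sens_target"].map(realized_map)
        return out


def linkage_curve(
    rocs: list[RocCurve],
    clinical: ClinicalCohort,
    subgroup: str,
    sens_grid_pct: np.ndarray,
) -> LinkageCurve:
    """Link achievable sensitivities (enriched cohort) to clinical alert rates.

    All ROC curves must share pathology and RFS level.  Grid sensitivities
    unreachable exactly on a step-function ROC map to the next achievable
    operating point; the realized sensitivity is stored alongside the target.
    """
    if not rocs:
        raise ValueError("at least one reader ROC curve is required")
    pathologies = {c.pathology for c in rocs}
    rfs_levels = {c.rfs_level for c in rocs}
    if len(pathologies) > 1 or len(rfs_levels) > 1:
        raise ValueError("reader ROC curves must share pathology and RFS level")
    pathology = rocs[0].pathology
    rfs_level = rocs[0].rfs_level

    grid = np.asarray(sens_grid_pct, dtype=float)
    if grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("sensitivity grid must be ascending with >= 2 points")
    if grid.min() < 0 or grid.max() > 100:
        raise ValueError("sensitivity grid must lie within [0, 100]%")

    # presort subgroup scores once; count(score >= t) via binary search
    scores = np.sort(clinical.subgroup_scores(subgroup, pathology))
    n_sub = scores.size

    rows = []
    per_reader_alert = np.empty((len(rocs), grid.size))
    per_reader_sens = np.empty_like(per_reader_alert)
    for i, curve in enumerate(rocs):
        reader = curve.reader_id or f"reader{i + 1}"
        for k, target in enumerate(grid):
            thr, realized = threshold_for_sensitivity(curve, target)
            count = n_sub - int(np.searchsorted(scores, thr, side="left"))
            pct = 100.0 * count / n_sub
            per_reader_alert[i, k] = pct
            per_reader_sens[i, k] = realized
            rows.append((float(target), realized, reader, thr, pct))

    table = pd.DataFrame(
        rows, columns=["sens_target", "sens_realized", "reader_id", "threshold", "alert_pct"]
    )
    return LinkageCurve(
        pathology=pathology,
        subgroup=subgroup,
        rfs_level=rfs_level,
        sens_grid=grid,
        table=table,
        mean_alert_pct=per_reader_alert.mean(axis=0),
        mean_sens_realized=per_reader_sens.mean(axis=0),
    )
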