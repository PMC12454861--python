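"""Synthetic cohort generator with closed-form linkage oracles.

Emulates the two-cohort design the pipeline assumes: a small
pathology-enriched reader-study cohort (deliberately composed, boosted
prevalences, several correlated Likert readers) and a large clinical routine
cohort split into inpatient/outpatient subgroups with realistic prevalences.

Score model
-----------
AI confidence scores are Beta mixtures per pathology: diseased cases score
``Beta(a1, b1)``, healthy cases ``Beta(a0, b0)`` with a higher diseased mean.
Bounded support matches the [0, 1] score range and right-skewed defaults put
most probability mass near zero, as routine chest-radiograph AI score
histograms show.

Reader model
------------
Each diseased case carries a latent severity ``s ~ Uniform(0, 1)``; healthy
cases have ``s = 0``.  A reader perceives ``s + Normal(0, sigma_r)`` and maps
the perception through four increasing cutpoints to a 0-4 Likert rating
(rating = number of cutpoints strictly below the perception).  The diseased
score is coupled to the same severity via the Beta quantile transform
(``score = Q_diseased(s)``), which induces reader-AI correlation.

With ``sigma_r = 0`` and the first cutpoint at 0 every reader reproduces the
ground truth exactly; in that regime the sensitivity-to-alert-rate linkage
has the closed form ``A(t) = pi * SF1(t) + (1 - pi) * SF0(t)`` used by the
analytic oracles below.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohorts import ClinicalCohort, EnrichedCohort, Subgroup

__all__ = [
    "ScoreModel",
    "PathologyParams",
    "GenParams",
    "AnalyticCurves",
    "OtOracle",
    "gen_enriched_cohort",
    "gen_clinical_cohort",
    "analytic_curves",
    "analytic_linkage",
    "analytic_ot",
    "save_params",
    "load_params",
]


class ParamError(ValueError):
    """Raised for infeasible generator parameters."""


@dataclass(frozen=True)
class ScoreModel:
    """Beta score channels for diseased (a1, b1) and healthy (a0, b0) cases."""

    a1: float = 2.0
    b1: float = 3.0
    a0: float = 1.0
    b0: float = 14.0

    def __post_init__(self) -> None:
        for v in (self.a1, self.b1, self.a0, self.b0):
            if v <= 0:
                raise ParamError("Beta parameters must be positive")
        if self.diseased_mean <= self.healthy_mean:
            raise ParamError("diseased score mean must exceed healthy score mean")

    @property
    def diseased_mean(self) -> float:
        return self.a1 / (self.a1 + self.b1)

    @property
    def healthy_mean(self) -> float:
        return self.a0 / (self.a0 + self.b0)

    def diseased_quantile(self, u: np.ndarray) -> np.ndarray:
        return stats.beta.ppf(u, self.a1, self.b1)

    def sf_diseased(self, t: np.ndarray) -> np.ndarray:
        return stats.beta.sf(t, self.a1, self.b1)

    def sf_healthy(self, t: np.ndarray) -> np.ndarray:
        return stats.beta.sf(t, self.a0, self.b0)


@dataclass(frozen=True)
class PathologyParams:
    """Prevalences and score model for one pathology."""

    prevalence_enriched: float
    prevalence_by_subgroup: Mapping[str, float]
    score_model: ScoreModel = ScoreModel()

    def __post_init__(self) -> None:
        fractions = [self.prevalence_enriched, *self.prevalence_by_subgroup.values()]
        if any(not 0.0 <= f <= 1.0 for f in fractions):
            raise ParamError("prevalences must lie in [0, 1]")


def _default_pathologies() -> dict[str, PathologyParams]:
    # Enriched prevalences 24.9/25.9/10.3/8.4%; routine subgroup prevalences
    # from 200-case sample readings per subgroup (outpatient vs inpatient).
    prev = {
        "pleural_effusion": (0.249, {"outpatient": 0.235, "inpatient": 0.465}),
        "consolidation": (0.259, {"outpatient": 0.235, "inpatient": 0.290}),
        "pneumothorax": (0.103, {"outpatient": 0.025, "inpatient": 0.125}),
        "nodule": (0.084, {"outpatient": 0.080, "inpatient": 0.055}),
    }
    return {
        name: PathologyParams(p_enr, dict(p_sub)) for name, (p_enr, p_sub) in prev.items()
    }


@dataclass(frozen=True)
class GenParams:
    """Full parameterization of the synthetic two-cohort study.

    Defaults mirror the reference study design: a 563-case enriched cohort
    read by six radiologists, and a 15,519-case clinical cohort split into
    11,900 inpatient and 3,619 outpatient examinations, with a 200-case
    expert sample reading per subgroup.
    """

    pathologies: Mapping[str, PathologyParams] = field(default_factory=_default_pathologies)
    n_enriched: int = 563
    n_readers: int = 6
    sigma_r: float = 0.1
    cutpoints: tuple[float, float, float, float] = (0.15, 0.35, 0.55, 0.75)
    n_clinical_by_subgroup: Mapping[str, int] = field(
        default_factory=lambda: {"inpatient": 11_900, "outpatient": 3_619}
    )
    sample_reading_per_subgroup: int = 200
    couple_scores: bool = True  # diseased score = Q_diseased(severity)

    def __post_init__(self) -> None:
        if self.n_enriched <= 0 or self.n_readers < 1:
            raise ParamError("cohort and reader counts must be positive")
        if self.sigma_r < 0:
            raise ParamError("sigma_r must be non-negative")
        cp = self.cutpoints
        if len(cp) != 4 or any(b <= a for a, b in zip(cp, cp[1:])):
            raise ParamError("cutpoints must be four strictly increasing values")
        for sg, n in self.n_clinical_by_subgroup.items():
            if n <= 0:
                raise ParamError(f"subgroup {sg!r} size must be positive")
            if self.sample_reading_per_subgroup > n:
                raise ParamError(
                    f"sample reading size {self.sample_reading_per_subgroup} exceeds "
                    f"subgroup {sg!r} size {n}"
                )

    @classmethod
    def oracle(cls, **overrides) -> "GenParams":
        """Noise-free configuration under which readers reproduce the truth.

        ``sigma_r = 0`` and a first cutpoint at 0 make every reader's RFS IV
        label equal the ground-truth disease state (healthy severity is
        exactly 0, diseased severity is positive almost surely), so the
        analytic linkage oracles are exact for the generated cohorts.
        """
        params = cls(sigma_r=0.0, cutpoints=(0.0, 0.25, 0.5, 0.75))
        return replace(params, **overrides) if overrides else params

    def reader_ids(self) -> list[str]:
        return [f"R{i + 1}" for i in range(self.n_readers)]


def _stream_seed(seed: int, *tokens: object) -> int:
    """Stable per-stream seed derived from the global seed and a purpose key."""
    key = ":".join([str(seed), *map(str, tokens)])
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _likert_from_perception(perception: np.ndarray, cutpoints: Sequence[float]) -> np.ndarray:
    # rating = number of cutpoints strictly below the perceived severity
    cp = np.asarray(cutpoints, dtype=float)
    return (perception[:, None] > cp[None, :]).sum(axis=1)


def gen_enriched_cohort(params: GenParams, seed: int) -> EnrichedCohort:
    """Generate the pathology-enriched reader-study cohort.

    Deliberate composition: exactly ``round(n * prevalence)`` diseased cases
    per pathology (the cohort is artificially enriched, not sampled), disease
    states independent across pathologies.  Deterministic for a fixed seed.
    """
    n = params.n_enriched
    case_ids = [f"S{i + 1:05d}" for i in range(n)]
    readers = params.reader_ids()

    score_rows: list[tuple[str, str, float]] = []
    rating_rows: list[tuple[str, str, str, int]] = []

    for pathology, pp in params.pathologies.items():
        rng = np.random.default_rng(_stream_seed(seed, "enriched", pathology))
        n_pos = int(round(n * pp.prevalence_enriched))
        diseased = np.zeros(n, dtype=bool)
        diseased[rng.choice(n, size=n_pos, replace=False)] = True

        severity = np.zeros(n)
        severity[diseased] = rng.uniform(size=n_pos)

        scores = np.empty(n)
        scores[~diseased] = rng.beta(pp.score_model.a0, pp.score_model.b0, size=n - n_pos)
        if params.couple_scores:
            scores[diseased] = pp.score_model.diseased_quantile(severity[diseased])
        else:
            scores[diseased] = rng.beta(pp.score_model.a1, pp.score_model.b1, size=n_pos)

        score_rows += [
            (cid, pathology, float(s)) for cid, s in zip(case_ids, np.round(scores, 6))
        ]

        for reader in readers:
            r_rng = np.random.default_rng(_stream_seed(seed, "reader", pathology, reader))
            perception = severity + r_rng.normal(0.0, params.sigma_r, size=n)
            likert = _likert_from_perception(perception, params.cutpoints)
            rating_rows += [
                (cid, reader, pathology, int(l)) for cid, l in zip(case_ids, likert)
            ]

    scores_df = pd.DataFrame(score_rows, columns=["case_id", "pathology", "ai_score"])
    ratings_df = pd.DataFrame(
        rating_rows, columns=["case_id", "reader_id", "pathology", "likert"]
    )
    return EnrichedCohort(scores_df, ratings_df)


def gen_clinical_cohort(params: GenParams, seed: int) -> ClinicalCohort:
    """Generate the clinical routine cohort with subgroup labels.

    Subgroup sizes are exactly as configured; disease states are Bernoulli
    draws at the subgroup prevalence (consecutive routine sampling).  A
    random expert sample reading (ground-truth labels) of the configured size
    is drawn per subgroup.
    """
    score_rows: list[tuple[str, str, str, float]] = []
    sample_rows: list[tuple[str, str, int]] = []

    for subgroup, n_sub in params.n_clinical_by_subgroup.items():
        Subgroup(subgroup)  # validate label
        prefix = subgroup[:3].upper()
        case_ids = [f"{prefix}{i + 1:06d}" for i in range(n_sub)]

        truth_by_pathology: dict[str, np.ndarray] = {}
        for pathology, pp in params.pathologies.items():
            pi = pp.prevalence_by_subgroup.get(subgroup, 0.0)
            rng = np.random.default_rng(_stream_seed(seed, "clinical", subgroup, pathology))
            diseased = rng.uniform(size=n_sub) < pi
            truth_by_pathology[pathology] = diseased

            scores = np.empty(n_sub)
            n_pos = int(diseased.sum())
            scores[~diseased] = rng.beta(pp.score_model.a0, pp.score_model.b0, size=n_sub - n_pos)
            if params.couple_scores:
                severity = rng.uniform(size=n_pos)
                scores[diseased] = pp.score_model.diseased_quantile(severity)
            else:
                scores[diseased] = rng.beta(pp.score_model.a1, pp.score_model.b1, size=n_pos)

            score_rows += [
                (cid, subgroup, pathology, float(s))
                for cid, s in zip(case_ids, np.round(scores, 6))
            ]

        sample_rng = np.random.default_rng(_stream_seed(seed, "sample_reading", subgroup))
        picked = sample_rng.choice(n_sub, size=params.sample_reading_per_subgroup, replace=False)
        for idx in sorted(picked):
            for pathology in params.pathologies:
                sample_rows.append(
                    (case_ids[idx], pathology, int(truth_by_pathology[pathology][idx]))
                )

    scores_df = pd.DataFrame(
        score_rows, columns=["case_id", "subgroup", "pathology", "ai_score"]
    )
    sample_df = pd.DataFrame(
        sample_rows, columns=["case_id", "pathology", "reference_positive"]
    )
    return ClinicalCohort(scores_df, sample_df)


# ---------------------------------------------------------------------------
# Closed-form oracles (exact in the noise-free reader regime).

@dataclass(frozen=True)
class AnalyticCurves:
    """Exact sensitivity and alert-rate curves as functions of the threshold.

    ``sensitivity(t) = SF1(t)`` (diseased score survival) and
    ``alert_rate(t) = pi * SF1(t) + (1 - pi) * SF0(t)`` for subgroup
    prevalence ``pi``.  Both are non-increasing in ``t``; the alert rate is 1
    at t = 0 and 0 above the score support.
    """

    pathology: str
    subgroup: str
    prevalence: float
    sensitivity: Callable[[np.ndarray], np.ndarray]
    alert_rate: Callable[[np.ndarray], np.ndarray]
    threshold_at_sensitivity: Callable[[np.ndarray], np.ndarray]


def analytic_curves(params: GenParams, pathology: str, subgroup: str) -> AnalyticCurves:
    pp = params.pathologies[pathology]
    pi = pp.prevalence_by_subgroup.get(subgroup)
    if pi is None:
        raise ParamError(f"no prevalence configured for subgroup {subgroup!r}")
    sm = pp.score_model

    def sensitivity(t):
        return sm.sf_diseased(np.asarray(t, dtype=float))

    def alert_rate(t):
        t = np.asarray(t, dtype=float)
        return pi * sm.sf_diseased(t) + (1.0 - pi) * sm.sf_healthy(t)

    def threshold_at_sensitivity(s):
        # smallest threshold achieving sensitivity s: SF1(t) = s  =>  t = Q1(1 - s)
        return sm.diseased_quantile(1.0 - np.asarray(s, dtype=float))

    return AnalyticCurves(pathology, subgroup, pi, sensitivity, alert_rate, threshold_at_sensitivity)


def analytic_linkage(
    params: GenParams, pathology: str, subgroup: str, sens_grid_pct: np.ndarray
) -> pd.DataFrame:
    """Exact (sensitivity, threshold, alert rate) linkage on a sensitivity grid.

    Valid as an oracle for the empirical pipeline when readers are noise-free
    (labels equal ground truth); columns: sens_pct, threshold, alert_pct.
    """
    grid = np.asarray(sens_grid_pct, dtype=float)
    if grid.min() < 0 or grid.max() > 100:
        raise ParamError("sensitivity grid must lie within [0, 100]%")
    curves = analytic_curves(params, pathology, subgroup)
    thresholds = curves.threshold_at_sensitivity(grid / 100.0)
    alert = curves.alert_rate(thresholds) * 100.0
    return pd.DataFrame({"sens_pct": grid, "threshold": thresholds, "alert_pct": alert})


@dataclass(frozen=True)
class OtOracle:
    """Ground-truth optimized threshold from the exact linkage curve."""

    pathology: str
    subgroup: str
    target_sensitivity_pct: float
    threshold: float
    alert_pct: float
    criterion_triggered: bool


def analytic_ot(
    params: GenParams, pathology: str, subgroup: str, grid_step_pct: float = 1.0
) -> OtOracle:
    """Slope criterion applied to the exact linkage curve.

    Scans the sensitivity grid (ascending, ``grid_step_pct`` spacing) and
    returns the first grid sensitivity whose forward-difference slope of
    alert% against sensitivity% exceeds 1.  If the slope never exceeds 1 the
    maximum-sensitivity point is returned with ``criterion_triggered=False``.
    """
    if grid_step_pct <= 0:
        raise ParamError("grid step must be positive")
    grid = np.arange(0.0, 100.0 + grid_step_pct / 2, grid_step_pct)
    link = analytic_linkage(params, pathology, subgroup, grid)
    alert = link["alert_pct"].to_numpy()
    slopes = np.diff(alert) / np.diff(grid)
    # strict criterion with a roundoff guard: a slope exactly at the boundary
    # (identical score channels give alert == sensitivity, slope == 1) must
    # not trigger through float jitter alone
    hits = np.flatnonzero(slopes > 1.0 + 1e-9)
    if hits.size:
        k = int(hits[0])
        triggered = True
    else:
        k = len(grid) - 1
        triggered = False
    return OtOracle(
        pathology=pathology,
        subgroup=subgroup,
        target_sensitivity_pct=float(grid[k]),
        threshold=float(link["threshold"].iloc[k]),
        alert_pct=float(alert[k]),
        criterion_triggered=triggered,
    )


# ---------------------------------------------------------------------------
# Parameter round-trip (sim_params.yaml).

def save_params(params: GenParams, path) -> None:
    """Serialize GenParams to YAML (lossless round-trip with load_params)."""
    import yaml
    from pathlib import Path

    payload = {
        "n_enriched": params.n_enriched,
        "n_readers": params.n_readers,
        "sigma_r": params.sigma_r,
        "cutpoints": list(params.cutpoints),
        "n_clinical_by_subgroup": dict(params.n_clinical_by_subgroup),
        "sample_reading_per_subgroup": params.sample_reading_per_subgroup,
        "couple_scores": params.couple_scores,
        "pathologies": {
            name: {
                "prevalence_enriched": pp.prevalence_enriched,
                "prevalence_by_subgroup": dict(pp.prevalence_by_subgroup),
                "score_model": {
                    "a1": pp.score_model.a1,
                    "b1": pp.score_model.b1,
                    "a0": pp.score_model.a0,
                    "b0": pp.score_model.b0,
                },
            }
            for name, pp in params.pathologies.items()
        },
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def load_params(path) -> GenParams:
    """Load GenParams from YAML written by save_params."""
    import yaml
    from pathlib import Path

    raw = yaml.safe_load(Path(path).read_text())
    pathologies = {
        name: PathologyParams(
            prevalence_enriched=float(pp["prevalence_enriched"]),
            prevalence_by_subgroup={k: float(v) for k, v in pp["prevalence_by_subgroup"].items()},
            score_model=ScoreModel(**{k: float(v) for k, v in pp["score_model"].items()}),
        )
        for name, pp in raw["pathologies"].items()
    }
    return GenParams(
        pathologies=pathologies,
        n_enriched=int(raw["n_enriched"]),
        n_readers=int(raw["n_readers"]),
        sigma_r=float(raw["sigma_r"]),
        cutpoints=tuple(float(c) for c in raw["cutpoints"]),
        n_clinical_by_subgroup={k: int(v) for k, v in raw["n_clinical_by_subgroup"].items()},
        sample_reading_per_subgroup=int(raw["sample_reading_per_subgroup"]),
        couple_scores=bool(raw["couple_scores"]),
    )
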