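"""Cohort data model: reader ratings, reference-standard pooling, validation.

Two cohorts drive the threshold-optimization pipeline:

* an *enriched* cohort — a pathology-enriched validation set in which every
  case carries an AI confidence score per pathology and a 5-point Likert
  suspicion rating (0 = no suspicion … 4 = certain finding) from each of
  several reference readers;
* a *clinical* cohort — consecutive routine cases with AI scores, a subgroup
  label (inpatient / outpatient / other) per case, and optionally a small
  expert-labelled "sample reading" used for prevalence-dependent metrics.

Reader Likert ratings are pooled to binary reference standards (RFS I–IV)
ordered from most specific (only "certain" counts as positive) to most
sensitive (anything above "no suspicion" counts as positive).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "PATHOLOGIES",
    "RfsLevel",
    "Subgroup",
    "ReaderRating",
    "ScoredCase",
    "EnrichedCohort",
    "ClinicalCohort",
    "PathologyConfig",
    "ValidationFinding",
    "ValidationReport",
    "pool_likert",
    "build_reference_standard",
    "validate_cohorts",
    "read_enriched_cohort",
    "read_clinical_cohort",
    "write_enriched_cohort",
    "write_clinical_cohort",
]

#: Default pathologies; an open set — configs may add others.
PATHOLOGIES = ("pleural_effusion", "consolidation", "pneumothorax", "nodule")

LIKERT_LEVELS = (0, 1, 2, 3, 4)


class Subgroup(str, enum.Enum):
    """Clinical routine subgroup of a case."""

    inpatient = "inpatient"
    outpatient = "outpatient"
    other = "other"


class RfsLevel(enum.Enum):
    """Binary reference standard pooled from 5-point Likert ratings.

    ``min_positive_score`` is the lowest Likert rating counted as positive:
    RFS I (most specific) requires a "certain" rating of 4; RFS IV (most
    sensitive) counts any suspicion >= 1 as positive.  The positive sets are
    therefore nested: positives(I) ⊆ positives(II) ⊆ positives(III) ⊆
    positives(IV).
    """

    I = 4
    II = 3
    III = 2
    IV = 1

    @property
    def min_positive_score(self) -> int:
        return self.value

    @classmethod
    def parse(cls, value: "RfsLevel | str | int") -> "RfsLevel":
        if isinstance(value, cls):
            return value
        if isinstance(value, int):
            return cls(value)
        name = str(value).strip().upper()
        if name in cls.__members__:
            return cls[name]
        raise ValueError(f"unknown RFS level {value!r} (expected I, II, III or IV)")


class CohortError(ValueError):
    """Raised for malformed cohort data or failed lookups."""


@dataclass(frozen=True)
class ReaderRating:
    """One reader's Likert suspicion rating for one case and pathology."""

    case_id: str
    reader_id: str
    pathology: str
    likert: int

    def __post_init__(self) -> None:
        if self.likert not in LIKERT_LEVELS:
            raise CohortError(
                f"case {self.case_id!r}, reader {self.reader_id!r}: "
                f"likert {self.likert} outside 0-4"
            )


@dataclass(frozen=True)
class ScoredCase:
    """AI confidence score in [0, 1] for one case and pathology."""

    case_id: str
    pathology: str
    ai_score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.ai_score <= 1.0:
            raise CohortError(
                f"case {self.case_id!r}: ai_score {self.ai_score} outside [0, 1]"
            )


@dataclass(frozen=True)
class PathologyConfig:
    """Per-pathology settings: vendor default threshold and RFS level."""

    pathology: str
    vendor_default_threshold: float
    rfs_level: RfsLevel = RfsLevel.IV

    def __post_init__(self) -> None:
        if not 0.0 <= self.vendor_default_threshold <= 1.0:
            raise CohortError(
                f"{self.pathology}: vendor default threshold "
                f"{self.vendor_default_threshold} outside [0, 1]"
            )


class EnrichedCohort:
    """Pathology-enriched validation cohort with AI scores and reader ratings.

    Internally holds two tidy DataFrames:

    * ``scores``: case_id, pathology, ai_score  (one row per case x pathology)
    * ``ratings``: case_id, reader_id, pathology, likert

    ``readers`` preserves the order readers first appear in the ratings table.
    """

    def __init__(self, scores: pd.DataFrame, ratings: pd.DataFrame):
        self.scores = scores.reset_index(drop=True)
        self.ratings = ratings.reset_index(drop=True)
        self.readers: list[str] = list(dict.fromkeys(ratings["reader_id"]))
        self.case_ids: list[str] = list(dict.fromkeys(scores["case_id"]))
        self.pathologies: list[str] = list(dict.fromkeys(scores["pathology"]))

    @classmethod
    def from_records(
        cls, cases: Iterable[ScoredCase], ratings: Iterable[ReaderRating]
    ) -> "EnrichedCohort":
        scores = pd.DataFrame(
            [(c.case_id, c.pathology, c.ai_score) for c in cases],
            columns=["case_id", "pathology", "ai_score"],
        )
        rt = pd.DataFrame(
            [(r.case_id, r.reader_id, r.pathology, r.likert) for r in ratings],
            columns=["case_id", "reader_id", "pathology", "likert"],
        )
        return cls(scores, rt)

    def n_cases(self) -> int:
        return len(self.case_ids)

    def score_vector(self, pathology: str) -> np.ndarray:
        """AI scores for one pathology, aligned to ``case_ids`` order."""
        sub = self.scores[self.scores["pathology"] == pathology]
        if sub.empty:
            raise CohortError(f"no scores for pathology {pathology!r}")
        aligned = sub.set_index("case_id")["ai_score"].reindex(self.case_ids)
        if aligned.isna().any():
            missing = aligned.index[aligned.isna()].tolist()[:5]
            raise CohortError(f"missing {pathology!r} scores for cases {missing}")
        return aligned.to_numpy(dtype=float)

    def likert_vector(self, reader_id: str, pathology: str) -> np.ndarray:
        """One reader's Likert ratings for one pathology, aligned to cases."""
        if reader_id not in self.readers:
            raise CohortError(f"unknown reader {reader_id!r}")
        sub = self.ratings[
            (self.ratings["reader_id"] == reader_id)
            & (self.ratings["pathology"] == pathology)
        ]
        if sub.empty:
            raise CohortError(
                f"no ratings by reader {reader_id!r} for pathology {pathology!r}"
            )
        aligned = sub.set_index("case_id")["likert"].reindex(self.case_ids)
        if aligned.isna().any():
            missing = aligned.index[aligned.isna()].tolist()[:5]
            raise CohortError(
                f"reader {reader_id!r}, pathology {pathology!r}: "
                f"missing ratings for cases {missing}"
            )
        return aligned.to_numpy(dtype=int)


class ClinicalCohort:
    """Consecutive clinical-routine cohort with AI scores and subgroup labels.

    ``scores`` columns: case_id, subgroup, pathology, ai_score.
    ``sample_reading`` (optional) columns: case_id, pathology,
    reference_positive — the expert-labelled random subset used for
    prevalence-dependent metric evaluation.
    """

    def __init__(self, scores: pd.DataFrame, sample_reading: pd.DataFrame | None = None):
        self.scores = scores.reset_index(drop=True)
        self.sample_reading = (
            sample_reading.reset_index(drop=True) if sample_reading is not None else None
        )
        self.pathologies: list[str] = list(dict.fromkeys(scores["pathology"]))

    def subgroup_scores(self, subgroup: str, pathology: str) -> np.ndarray:
        sg = Subgroup(subgroup).value
        sub = self.scores[
            (self.scores["subgroup"] == sg) & (self.scores["pathology"] == pathology)
        ]
        if sub.empty:
            raise CohortError(f"no cases in subgroup {subgroup!r} for {pathology!r}")
        return sub["ai_score"].to_numpy(dtype=float)

    def subgroup_size(self, subgroup: str) -> int:
        sg = Subgroup(subgroup).value
        return self.scores[self.scores["subgroup"] == sg]["case_id"].nunique()

    def labelled_sample(self, pathology: str, subgroup: str | None = None) -> pd.DataFrame:
        """Sample-reading rows joined with scores for one pathology."""
        if self.sample_reading is None or self.sample_reading.empty:
            raise CohortError("cohort has no sample reading")
        labels = self.sample_reading[self.sample_reading["pathology"] == pathology]
        if labels.empty:
            raise CohortError(f"no sample-reading labels for pathology {pathology!r}")
        scores = self.scores[self.scores["pathology"] == pathology]
        merged = labels.merge(scores, on=["case_id", "pathology"], how="left")
        if merged["ai_score"].isna().any():
            missing = merged.loc[merged["ai_score"].isna(), "case_id"].tolist()[:5]
            raise CohortError(f"sample-reading cases missing scores: {missing}")
        if subgroup is not None:
            merged = merged[merged["subgroup"] == Subgroup(subgroup).value]
            if merged.empty:
                raise CohortError(f"no labelled cases in subgroup {subgroup!r}")
        return merged.reset_index(drop=True)


def pool_likert(likert: int, rfs: RfsLevel) -> bool:
    """Pool one Likert rating to a binary label under an RFS level.

    Positive iff ``likert >= rfs.min_positive_score``: under RFS I only a
    "certain" 4 is positive; under RFS IV any suspicion >= 1 is positive.
    """
    likert = int(likert)
    if likert not in LIKERT_LEVELS:
        raise CohortError(f"likert {likert} outside 0-4")
    return likert >= rfs.min_positive_score


def build_reference_standard(
    cohort: EnrichedCohort, reader_id: str, pathology: str, rfs: RfsLevel
) -> tuple[np.ndarray, float]:
    """Binary reference labels for one reader x pathology x RFS level.

    Returns ``(labels, prevalence)`` with labels aligned to
    ``cohort.case_ids`` and prevalence the mean of the labels.
    """
    likert = cohort.likert_vector(reader_id, pathology)
    labels = likert >= rfs.min_positive_score
    return labels, float(labels.mean())


@dataclass(frozen=True)
class ValidationFinding:
    kind: str
    message: str


@dataclass
class ValidationReport:
    findings: list[ValidationFinding] = field(default_factory=list)

    def add(self, kind: str, message: str) -> None:
        self.findings.append(ValidationFinding(kind, message))

    @property
    def ok(self) -> bool:
        return not self.findings

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.ok:
            return "validation OK: no findings"
        return "\n".join(f"[{f.kind}] {f.message}" for f in self.findings)


def _check_scores(report: ValidationReport, df: pd.DataFrame, where: str) -> None:
    bad = df[(df["ai_score"] < 0) | (df["ai_score"] > 1) | df["ai_score"].isna()]
    for _, row in bad.iterrows():
        report.add(
            "score_range",
            f"{where}: case {row['case_id']!r} pathology {row['pathology']!r} "
            f"ai_score {row['ai_score']} outside [0, 1]",
        )
    dup = df.duplicated(subset=["case_id", "pathology"], keep=False)
    for key, _ in df[dup].groupby(["case_id", "pathology"]):
        report.add("duplicate_key", f"{where}: duplicate score rows for {key}")


def validate_cohorts(
    enriched: EnrichedCohort | None,
    clinical: ClinicalCohort | None,
    configs: Iterable[PathologyConfig] = (),
) -> ValidationReport:
    """Check cohort invariants; returns a report, empty iff all hold.

    Findings cover score-range violations, duplicate (case, pathology) or
    (case, reader, pathology) keys, Likert values outside 0-4, missing rating
    cells (every reader must rate every case for every pathology — missing
    cells are errors, not imputed), and sample-reading cases absent from the
    clinical cohort.
    """
    report = ValidationReport()
    configured = {c.pathology for c in configs}

    if enriched is not None:
        _check_scores(report, enriched.scores, "enriched")
        r = enriched.ratings
        bad = r[~r["likert"].isin(LIKERT_LEVELS)]
        for _, row in bad.iterrows():
            report.add(
                "likert_range",
                f"enriched: case {row['case_id']!r} reader {row['reader_id']!r} "
                f"likert {row['likert']} outside 0-4",
            )
        dup = r.duplicated(subset=["case_id", "reader_id", "pathology"], keep=False)
        for key, _ in r[dup].groupby(["case_id", "reader_id", "pathology"]):
            report.add("duplicate_key", f"enriched: duplicate rating rows for {key}")
        # every (case, reader, pathology) cell must be present
        expected = len(enriched.case_ids) * len(enriched.readers)
        for pathology in enriched.pathologies:
            have = r[r["pathology"] == pathology]
            n = len(have.drop_duplicates(subset=["case_id", "reader_id"]))
            if n < expected:
                report.add(
                    "missing_cell",
                    f"enriched: pathology {pathology!r} has {n} rating cells, "
                    f"expected {expected} (cases x readers)",
                )
        if not enriched.readers:
            report.add("no_readers", "enriched: cohort has no readers")

    if clinical is not None:
        _check_scores(report, clinical.scores, "clinical")
        known = {s.value for s in Subgroup}
        bad_sg = clinical.scores[~clinical.scores["subgroup"].isin(known)]
        for sg in sorted(set(bad_sg["subgroup"])):
            report.add("subgroup", f"clinical: unknown subgroup label {sg!r}")
        if clinical.sample_reading is not None:
            cohort_ids = set(clinical.scores["case_id"])
            stray = set(clinical.sample_reading["case_id"]) - cohort_ids
            for cid in sorted(stray):
                report.add(
                    "sample_reading",
                    f"clinical: sample-reading case {cid!r} not in cohort",
                )
            bad_lab = clinical.sample_reading[
                ~clinical.sample_reading["reference_positive"].isin((0, 1))
            ]
            for _, row in bad_lab.iterrows():
                report.add(
                    "sample_reading",
                    f"clinical: case {row['case_id']!r} reference_positive "
                    f"{row['reference_positive']} not binary",
                )

    for cohort, name in ((enriched, "enriched"), (clinical, "clinical")):
        if cohort is None or not configured:
            continue
        unknown = set(cohort.pathologies) - configured
        for p in sorted(unknown):
            report.add("pathology", f"{name}: pathology {p!r} not in config")

    return report


# ---------------------------------------------------------------------------
# CSV I/O — the four tabular schemas shared by every pipeline stage.

def read_enriched_cohort(scores_csv: Path | str, readings_csv: Path | str) -> EnrichedCohort:
    scores = pd.read_csv(scores_csv, dtype={"case_id": str, "pathology": str})
    ratings = pd.read_csv(
        readings_csv, dtype={"case_id": str, "reader_id": str, "pathology": str}
    )
    return EnrichedCohort(scores, ratings)


def read_clinical_cohort(
    scores_csv: Path | str, sample_reading_csv: Path | str | None = None
) -> ClinicalCohort:
    scores = pd.read_csv(
        scores_csv, dtype={"case_id": str, "subgroup": str, "pathology": str}
    )
    sample = None
    if sample_reading_csv is not None:
        sample = pd.read_csv(
            sample_reading_csv, dtype={"case_id": str, "pathology": str}
        )
    return ClinicalCohort(scores, sample)


def write_enriched_cohort(
    cohort: EnrichedCohort, scores_csv: Path | str, readings_csv: Path | str
) -> None:
    cohort.scores.to_csv(scores_csv, index=False)
    cohort.ratings.to_csv(readings_csv, index=False)


def write_clinical_cohort(
    cohort: ClinicalCohort,
    scores_csv: Path | str,
    sample_reading_csv: Path | str | None = None,
) -> None:
    cohort.scores.to_csv(scores_csv, index=False)
    if sample_reading_csv is not None and cohort.sample_reading is not None:
        cohort.sample_reading.to_csv(sample_reading_csv, index=False)
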