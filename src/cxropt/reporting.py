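"""Pipeline runner: configuration, per-scenario artifacts, figures, run log.

``run_pipeline`` executes the full threshold-optimization analysis for every
configured pathology x clinical subgroup and writes, per scenario: the
per-reader ROC curves (CSV), the linkage curve (CSV), the optimization
result (JSON), sample-reading metrics at OT / vendor-default / Youden
thresholds (JSON), and a four-panel figure (ROC curves; clinical score
histogram with threshold markers; positive fractions per reader; the
sensitivity-vs-alert-rate curve with the slope-criterion point).  A
threshold-comparison histogram across subgroups is written per pathology.
Numbers are the contract; figures are best-effort illustration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from .cohorts import (
    ClinicalCohort,
    PathologyConfig,
    RfsLevel,
    read_clinical_cohort,
    read_enriched_cohort,
    validate_cohorts,
)
from .linkage import LinkageCurve, default_sens_grid
from .metrics import confusion, metrics
from .optimize import OptimizationResult, optimize

logger = logging.getLogger("cxropt")

__all__ = ["RunConfig", "run_pipeline", "render_linkage_panel", "render_comparison_histogram"]


@dataclass
class RunConfig:
    """Declarative run configuration (YAML-loadable)."""

    enriched_scores: Path
    readings: Path
    clinical_scores: Path
    sample_reading: Path | None
    aidt: dict[str, float]
    rfs_level: RfsLevel = RfsLevel.IV
    subgroups: tuple[str, ...] = ("outpatient", "inpatient")
    sens_grid_step_pct: float = 1.0
    aggregate: str = "mean"
    seed: int = 0
    out_dir: Path = Path("cxropt_out")

    def __post_init__(self) -> None:
        self.rfs_level = RfsLevel.parse(self.rfs_level)
        if not 0.0 < self.sens_grid_step_pct <= 5.0:
            raise ValueError("sens grid step must lie in (0, 5] percent")
        if self.aggregate not in ("mean", "median"):
            raise ValueError("aggregate must be 'mean' or 'median'")
        for name in ("enriched_scores", "readings", "clinical_scores"):
            p = Path(getattr(self, name))
            setattr(self, name, p)
            if not p.exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        if self.sample_reading is not None:
            self.sample_reading = Path(self.sample_reading)
            if not self.sample_reading.exists():
                raise FileNotFoundError(f"sample_reading file not found: {self.sample_reading}")
        self.out_dir = Path(self.out_dir)

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        base = Path(path).parent
        def _p(key, optional=False):
            v = raw.get(key)
            if v is None:
                if optional:
                    return None
                raise KeyError(f"config missing {key!r}")
            p = Path(v)
            return p if p.is_absolute() else base / p
        return cls(
            enriched_scores=_p("enriched_scores"),
            readings=_p("readings"),
            clinical_scores=_p("clinical_scores"),
            sample_reading=_p("sample_reading", optional=True),
            aidt={str(k): float(v) for k, v in raw["aidt"].items()},
            rfs_level=RfsLevel.parse(raw.get("rfs_level", "IV")),
            subgroups=tuple(raw.get("subgroups", ("outpatient", "inpatient"))),
            sens_grid_step_pct=float(raw.get("sens_grid_step_pct", 1.0)),
            aggregate=raw.get("aggregate", "mean"),
            seed=int(raw.get("seed", 0)),
            out_dir=Path(raw.get("out_dir", "cxropt_out")),
        )

    def pathology_configs(self) -> list[PathologyConfig]:
        return [
            PathologyConfig(p, t, self.rfs_level) for p, t in sorted(self.aidt.items())
        ]

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "aidt": self.aidt,
                "rfs": self.rfs_level.name,
                "subgroups": list(self.subgroups),
                "step": self.sens_grid_step_pct,
                "aggregate": self.aggregate,
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _roc_export(rocs) -> pd.DataFrame:
    frames = []
    for c in rocs:
        frames.append(
            pd.DataFrame(
                {
                    "reader_id": c.reader_id,
                    "pathology": c.pathology,
                    "rfs": c.rfs_level,
                    "threshold": c.thresholds,
                    "sensitivity": c.sensitivity,
                    "specificity": c.specificity,
                    "youden_j": c.youden_j,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def render_linkage_panel(
    curve: LinkageCurve,
    result: OptimizationResult,
    clinical: ClinicalCohort,
    rocs,
    path: Path,
) -> Path:
    """Four-panel scenario figure mirroring the per-pathology report layout."""
    if (curve.pathology, curve.subgroup) != (result.pathology, result.subgroup):
        raise ValueError("linkage curve and optimization result do not match")
    readers = curve.reader_ids
    if not readers:
        raise ValueError("linkage curve has no readers")

    fig, axes = plt.subplots(4, 1, figsize=(5, 14))
    cmap = plt.get_cmap("tab10")

    ax = axes[0]
    for i, c in enumerate(rocs):
        ax.plot(1 - c.specificity, c.sensitivity, color=cmap(i % 10), lw=1,
                label=c.reader_id)
    ax.plot([0, 1], [0, 1], "k:", lw=0.5)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"{curve.pathology} ROC (RFS {curve.rfs_level})")
    ax.legend(fontsize=6)

    ax = axes[1]
    scores = clinical.subgroup_scores(curve.subgroup, curve.pathology)
    ax.hist(scores, bins=50, color="lightgray", edgecolor="gray")
    for i, (reader, thr) in enumerate(result.per_reader_ot.items()):
        ax.axvline(thr, color=cmap(i % 10), ls=":", lw=1)
    ax.axvline(result.ot, color="black", lw=1.5, label="OT (aggregate)")
    if result.aidt is not None:
        ax.axvline(result.aidt, color="red", lw=1.5, label="vendor default")
    ax.set_yscale("log")
    ax.set_xlabel("AI score")
    ax.set_ylabel("cases")
    ax.set_title(f"{curve.subgroup} score distribution")
    ax.legend(fontsize=6)

    ax = axes[2]
    from .linkage import alert_rate as _alert
    rates = [
        _alert(clinical, curve.subgroup, curve.pathology, thr)[0]
        for thr in result.per_reader_ot.values()
    ]
    labels = list(result.per_reader_ot)
    rates.append(result.alert_at_ot_pct)
    labels.append("mean")
    ax.bar(range(len(rates)), rates,
           color=[cmap(i % 10) for i in range(len(rates) - 1)] + ["black"])
    ax.set_xticks(range(len(rates)), labels, fontsize=6)
    ax.set_ylabel("AI-positive [%]")
    ax.set_title("positives at per-reader OTs")

    ax = axes[3]
    for i, reader in enumerate(readers):
        series = curve.reader_series(reader)
        ax.plot(series["sens_target"], series["alert_pct"], ls=":", lw=1,
                color=cmap(i % 10))
    ax.plot(curve.sens_grid, curve.mean_alert_pct, color="black", lw=1.8, label="mean")
    ax.plot(result.target_sensitivity_pct, result.alert_at_ot_pct, "ro")
    ax.annotate(
        f"sens {result.target_sensitivity_pct:.0f}%\nalert {result.alert_at_ot_pct:.1f}%",
        xy=(0.02, 0.98), xycoords="axes fraction", va="top", fontsize=8,
    )
    ax.set_xlabel("sensitivity in enriched cohort [%]")
    ax.set_ylabel(f"alert rate, {curve.subgroup} [%]")
    ax.set_title("sensitivity-to-alert-rate linkage")
    ax.legend(fontsize=6)

    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


def render_comparison_histogram(
    clinical: ClinicalCohort,
    pathology: str,
    results: dict[str, OptimizationResult],
    path: Path,
) -> Path:
    """Threshold-comparison histogram: subgroup OTs vs vendor default vs Youden."""
    fig, ax = plt.subplots(figsize=(7, 4))
    scores = clinical.scores[clinical.scores["pathology"] == pathology]["ai_score"]
    ax.hist(scores, bins=60, color="lightgray", edgecolor="gray")
    ax.set_yscale("log")
    styles = {"outpatient": ("tab:blue", "--"), "inpatient": ("tab:cyan", "-")}
    aidt = None
    for subgroup, res in results.items():
        color, ls = styles.get(subgroup, ("tab:purple", "-"))
        ax.axvline(res.ot, color=color, ls=ls, lw=1.6, label=f"OT ({subgroup})")
        aidt = res.aidt if res.aidt is not None else aidt
        if res.youden_by_reader:
            for thr in res.youden_by_reader.values():
                ax.axvline(thr, color="green", lw=0.5, alpha=0.4)
    if aidt is not None:
        ax.axvline(aidt, color="red", lw=1.6, label="vendor default")
    ax.set_xlabel("AI score")
    ax.set_ylabel("cases (log)")
    ax.set_title(f"{pathology}: threshold comparison")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns a manifest of written artifacts.

    Fails before any computation when the cohorts violate their schema
    invariants or the vendor-threshold map names unknown pathologies.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"config_hash={config.config_hash()}", f"seed={config.seed}"]

    enriched = read_enriched_cohort(config.enriched_scores, config.readings)
    clinical = read_clinical_cohort(config.clinical_scores, config.sample_reading)
    log_lines.append(f"enriched_rows={len(enriched.scores)} ratings={len(enriched.ratings)}")
    log_lines.append(f"clinical_rows={len(clinical.scores)}")

    configs = config.pathology_configs()
    report = validate_cohorts(enriched, clinical, configs)
    unknown = set(config.aidt) - set(enriched.pathologies)
    if unknown:
        report.add("pathology", f"config: vendor thresholds for unknown pathologies {sorted(unknown)}")
    if not report.ok:
        (out / "validation.txt").write_text(str(report) + "\n")
        raise ValueError(f"cohort validation failed:\n{report}")

    grid = default_sens_grid(config.sens_grid_step_pct)
    manifest: dict = {"scenarios": [], "figures": [], "log": str(out / "run.log")}

    for pcfg in configs:
        results_by_subgroup: dict[str, OptimizationResult] = {}
        for subgroup in config.subgroups:
            tag = f"{pcfg.pathology}_{subgroup}"
            logger.info("optimizing %s", tag)
            result, link = optimize(
                enriched,
                clinical,
                subgroup,
                pcfg.pathology,
                pcfg,
                sens_grid_pct=grid,
                aggregate=config.aggregate,  # type: ignore[arg-type]
            )
            results_by_subgroup[subgroup] = result

            from .optimize import reader_roc_curves

            rocs = reader_roc_curves(enriched, pcfg.pathology, config.rfs_level)
            roc_csv = out / f"{tag}_roc.csv"
            _roc_export(rocs).to_csv(roc_csv, index=False)
            link_csv = out / f"{tag}_linkage.csv"
            link.export().to_csv(link_csv, index=False)
            opt_json = out / f"{tag}_optimization.json"
            _json_dump(result.to_dict(), opt_json)

            metrics_json = out / f"{tag}_metrics.json"
            metric_payload: dict = {}
            if clinical.sample_reading is not None:
                thresholds = {"ot": result.ot}
                if result.aidt is not None:
                    thresholds["aidt"] = result.aidt
                if result.youden_by_reader:
                    thresholds["youden_mean"] = float(
                        np.mean(list(result.youden_by_reader.values()))
                    )
                for name, thr in thresholds.items():
                    table = confusion(clinical, pcfg.pathology, thr, subgroup)
                    metric_payload[name] = {
                        "threshold": thr,
                        "table": {"tp": table.tp, "fp": table.fp, "fn": table.fn, "tn": table.tn},
                        "metrics": metrics(table).to_dict(),
                    }
            _json_dump(metric_payload, metrics_json)

            fig_path = out / f"{tag}_panel.svg"
            render_linkage_panel(link, result, clinical, rocs, fig_path)

            log_lines.append(
                f"{tag}: target_sens={result.target_sensitivity_pct:.1f}% "
                f"triggered={result.criterion_triggered} ot={result.ot:.4f} "
                f"alert_at_ot={result.alert_at_ot_pct:.2f}%"
            )
            manifest["scenarios"].append(
                {
                    "pathology": pcfg.pathology,
                    "subgroup": subgroup,
                    "roc_csv": str(roc_csv),
                    "linkage_csv": str(link_csv),
                    "optimization_json": str(opt_json),
                    "metrics_json": str(metrics_json),
                    "figure": str(fig_path),
                }
            )

        cmp_path = out / f"{pcfg.pathology}_threshold_comparison.svg"
        render_comparison_histogram(clinical, pcfg.pathology, results_by_subgroup, cmp_path)
        manifest["figures"].append(str(cmp_path))

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    _json_dump(manifest, out / "manifest.json")
    return manifest
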