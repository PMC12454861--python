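# cxropt

Subgroup-specific decision-threshold optimization for diagnostic AI scores,
built for the two-cohort design used to validate chest-radiograph AI in
clinical routine: a small **pathology-enriched cohort** with a multi-reader
reference standard, and a large **clinical routine cohort** with only AI
scores and subgroup labels (inpatient / outpatient).

Vendors ship one fixed decision threshold per finding, usually tuned on
enriched data with prevalence-independent rules such as Youden's J.  In
routine use, what clinicians experience is prevalence-dependent: the *alert
rate* — the fraction of exams the AI flags.  `cxropt` links the two worlds
and selects thresholds per clinical subgroup.

## Method

For one pathology and one binary reference standard (pooled from 5-point
Likert ratings, levels RFS I–IV from most specific to most sensitive):

1. **Per-reader ROC.**  For each reference reader $r$, an empirical ROC
   curve over the enriched cohort's AI scores (call positive iff
   score ≥ t); AUC by trapezoid (= Mann–Whitney U with ties at ½).
2. **Linkage.**  For each target sensitivity $S$ on a grid (default 1%
   steps), invert each reader's ROC to the largest threshold $t_r(S)$
   achieving $S$, apply it to the clinical subgroup, and record the alert
   rate $A_r(S)$.  The mean curve $\bar A(S)$ averages readers at fixed
   sensitivity.
3. **Slope criterion.**  The target sensitivity $S^\*$ is the first grid
   point where $d\bar A/dS > 1$ — beyond it, each additional percentage
   point of sensitivity costs more than one percentage point of alert rate,
   so further sensitization stops being clinically meaningful.  The
   **optimized threshold** (OT) is the mean of the per-reader thresholds
   $t_r(S^\*)$; computed against the outpatient or inpatient subgroup it
   yields an OPOT or IPOT.
4. **Evaluation.**  On an expert-labelled random sample of the clinical
   cohort, 2×2 tables and the metric battery (sensitivity, specificity,
   accuracy, PPV, NPV, FNR, FPR) with 95% Wald intervals
   $\hat p \pm 1.96\sqrt{\hat p(1-\hat p)/n}$, comparing OT against the
   vendor default and Youden thresholds.

A synthetic-study generator (Beta score mixtures, latent-severity Likert
readers) reproduces the design's statistical structure and provides
closed-form oracles for the linkage curve and the optimized threshold; see
`docs/methods.md`.

Because published studies print summaries rather than counts, the package
also *reconstructs* integer 2×2 tables from printed
sensitivity/specificity/prevalence triples and re-renders every derived
metric and CI — useful for auditing published tables.

## Worked example

`python examples/reconstruct_published_metrics.py` rebuilds count tables
from printed summary rows (n = 200 expert-read cases per subgroup):

```
pleural effusion / outpatient / vendor default:
  counts: tp=22 fp=3 fn=25 tn=150
  accuracy 86.0% [81.2; 90.8]%, ppv 88.0%, npv 85.7%
pleural effusion / outpatient / optimized:
  counts: tp=41 fp=47 fn=6 tn=106
  accuracy 73.5% [67.4; 79.6]%, ppv 46.6%, npv 94.6%
outpatient effusion prevalence: 23.5% [17.6; 29.4]%
```

Reading: lowering the outpatient effusion threshold to its OT nearly
doubles detected cases (22 → 41 of 47) at the price of 44 extra false
positives and an accuracy drop from 86.0% to 73.5% — the OT marks the
*upper limit* of justifiable sensitization, not a recommendation.

`python examples/synthetic_threshold_optimization.py` runs the full
pipeline on a generated study (563 enriched cases, six readers, 15,519
clinical exams) and prints the subgroup-specific OTs next to the
generator's exact-curve oracle:

```
outpatient:
  target sensitivity 76% (criterion triggered: True)
  optimized threshold 0.236 -> alert rate 20.5% of outpatient exams
  vendor default 0.145 -> alert rate 30.8%
  oracle (exact curves): target 87%, threshold 0.165, alert 26.5%
```

`python examples/full_pipeline_report.py` writes the complete artifact set
(ROC and linkage CSVs, optimization and metrics JSON, four-panel figures)
for every pathology × subgroup.  The same pipeline is scriptable from the
shell via the `cxropt` command (`simulate`, `validate`, `roc`, `linkage`,
`optimize`, `evaluate`, `reconstruct`, `run`).

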