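"""Rebuild integer 2x2 tables from published one-decimal summary metrics.

Diagnostic accuracy papers print sensitivity/specificity/accuracy with CIs
but rarely the underlying counts.  Given sensitivity, specificity, the
subgroup prevalence and the sample size, `reconstruct_table` recovers the
only integer table consistent with the printed percentages, and `metrics`
re-renders the full battery with Wald CIs.
"""

from cxropt import metrics, reconstruct_table, wald_ci

ROWS = [
    # (label, sens%, spec%, prevalence%, n)
    ("pleural effusion / outpatient / vendor default", 46.8, 98.0, 23.5, 200),
    ("pleural effusion / outpatient / optimized", 87.2, 69.3, 23.5, 200),
    ("nodules / inpatient / optimized", 90.9, 82.0, 5.5, 200),
]

for label, sens, spec, prev, n in ROWS:
    t = reconstruct_table(sens, spec, prev, n)
    m = metrics(t)
    print(f"{label}:")
    print(f"  counts: tp={t.tp} fp={t.fp} fn={t.fn} tn={t.tn}")
    print(
        f"  accuracy {m.accuracy.value:.1f}% "
        f"[{m.accuracy.ci.lower:.1f}; {m.accuracy.ci.upper:.1f}]%, "
        f"ppv {m.ppv.value:.1f}%, npv {m.npv.value:.1f}%"
    )

# a CI bracket on its own: prevalence 47/200 in the outpatient sample reading
ci = wald_ci(47, 200)
print(f"outpatient effusion prevalence: 23.5% [{ci.lower:.1f}; {ci.upper:.1f}]%")
# The tp/fp/fn/tn counts are the only integers that re-render to the printed
# percentages; the derived accuracy and CIs therefore reproduce the published
# cells exactly.
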