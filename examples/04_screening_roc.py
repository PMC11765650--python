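"""ROC/cutpoint screening of condylar hyperplasia from FA indices.

Each FA predictor is scanned for the Youden-optimal cutpoint
(rule: score >= cutpoint -> CH) and summarized by sensitivity,
specificity, PPV, NPV, Youden's index and the pair-counting AUC.
"""

from forasym import cohort_fa_table, default_config, generate_cohort
from forasym.pipeline import render_screening_table
from forasym.screening import screening_report

cohort, _ = generate_cohort(default_config(seed=7))
report = screening_report(cohort_fa_table(cohort), cohort, positive_class="CH")
print(render_screening_table(report))

best = report.loc[report["auc"].idxmax()]
print(f"\nBest predictor: {best['predictor']} (AUC {best['auc']:.3f}).")
print("The Total FA2 composite typically dominates single traits because"
      "\nindependent per-trait asymmetries add up in the CH group.")
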