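"""Worked example on the published multi-site cohort aggregates.

Reconstructs the categorical cohort from published per-center counts,
reproduces the summary percentages, and applies the p < 0.05 gate to the
published univariate and multivariate Cox tables.
"""

from glioprog import screen_pvalues, summarize_cohort
from glioprog.reference import (MULTIVARIATE_RESULTS, UNIVARIATE_RESULTS,
                                build_reference_cohort)

table = build_reference_cohort()
s = summarize_cohort(table)

count, pct = s.entries["gender"]["Male"]
print(f"cohort: {table.n} patients across 4 centers")
print(f"male: {count} ({pct}%)")
print(f"ATRX intact (tested-only denominator, n={s.denominators['atrx']}):"
      f" {round(s.entries['atrx']['intact'][1])}%")
print(f"MGMT unmethylated (n={s.denominators['mgmt_methylated']}): "
      f"{round(s.entries['mgmt_methylated'][False][1])}%")

uni = screen_pvalues(UNIVARIATE_RESULTS["p"])
multi = screen_pvalues(MULTIVARIATE_RESULTS["p"])
print(f"\nunivariate screen at p<0.05: {len(uni)} of "
      f"{len(UNIVARIATE_RESULTS)} features retained")
print("  " + ", ".join(UNIVARIATE_RESULTS["feature"].iloc[uni]))
print(f"multivariate model at p<0.05: {len(multi)} of "
      f"{len(MULTIVARIATE_RESULTS)} independent predictors")
print("  " + ", ".join(MULTIVARIATE_RESULTS["feature"].iloc[multi]))
# These counts and percentages are the arithmetic the pipeline must
# reproduce exactly from the published aggregates.
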