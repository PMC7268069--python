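"""Recompute group statistics directly from published summary tables.

Demonstrates the from-summary ANOVA twin (F from mean +/- SD (N) triples)
and the chi-square test on a demographic count table — no raw data needed.
"""

from editedmrs.stats import (GroupSummary, anova_from_summary,
                             chi_square_contingency)

# gender (M/F) counts for NC, MCI, AD
chi2, df, p = chi_square_contingency([[16, 11], [16, 3], [10, 8]])
print(f"gender x group: chi2({df}) = {chi2:.3f}, p = {p:.3f}")

# GSH_cl concentration, mean +/- SD (N) per group, three cingulate regions
tables = {
    "ACC": [(1.9502, 0.4223, 26), (1.6224, 0.3865, 18), (1.5624, 0.3407, 16)],
    "PCC": [(2.3674, 0.4049, 25), (1.7708, 0.3444, 16), (1.7794, 0.4361, 16)],
    "CINGULATE": [(4.3221, 0.7052, 24), (3.3019, 0.5658, 15),
                  (3.3848, 0.6609, 14)],
}
for region, rows in tables.items():
    F, dfb, dfw, p = anova_from_summary([GroupSummary(*r) for r in rows])
    print(f"{region:9s} GSH_cl concentration: F({dfb},{dfw}) = {F:.3f}, "
          f"p = {p:.4f}")
print("identical to a raw-data one-way ANOVA on any dataset with these "
      "exact moments; the NC > MCI ~ AD depletion drives every F")
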