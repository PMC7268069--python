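"""Group-level inference on a simulated NC/MCI/AD cohort.

Quantifies a small cohort drawn at the published group moments, then runs
the one-way ANOVA, Tukey post hoc comparisons and the covariate-adjusted
linear model (group + region + interaction, age and sex as covariates) with
Bonferroni pairwise contrasts.
"""

import editedmrs as em
from editedmrs.stats import (add_cingulate_rows, fit_glm, one_way_anova,
                             tukey_posthoc)

cfg = em.CohortSimConfig(seed=5, n_subjects={"NC": 8, "MCI": 6, "AD": 6})
truth, series = em.simulate_cohort(cfg)
cal = em.calibrate_phantom(em.simulate_phantom_series([1, 2, 3, 4, 5]),
                           [1, 2, 3, 4, 5])
res = em.quantify_cohort(truth, series, cal)
res = res[res.qc_pass]

pcc = res[res.region == "PCC"]
groups = [pcc.loc[pcc.group == g, "pvc_mm"].to_numpy() for g in ("NC", "MCI", "AD")]
F, dfb, dfw, p = one_way_anova(groups)
print(f"PCC PVC-GSH one-way ANOVA: F({dfb},{dfw}) = {F:.2f}, p = {p:.4f}")
print(tukey_posthoc(groups, ["NC", "MCI", "AD"]).to_string(index=False))

full = add_cingulate_rows(res.rename(columns={"pvc_mm": "measure"}), "measure")
glm = fit_glm(full, "measure")
print("\ncovariate-adjusted linear model (type-III tests):")
print(glm.effects.to_string(index=False))
print("\nBonferroni-adjusted pairwise group contrasts of adjusted means:")
print(glm.contrasts.query("factor == 'group'").to_string(index=False))
print("\nlower GSH in MCI/AD than NC (negative MCI-NC / AD-NC estimates) is "
      "the oxidative-stress signature the cohort was configured with")
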