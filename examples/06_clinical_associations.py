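"""Clinical association statistics for the discovered groups.

Age contrast (Mann-Whitney), tumor-location association (chi-square or
Fisher's exact, selected automatically), and progression-free survival
(Kaplan-Meier curves with the log-rank test). Group 1 is generated
younger, supratentorial-dominant, and faster-progressing.
"""

import pandas as pd

import snfomics as sf
from snfomics.clinical import SurvivalTable

cohort = sf.simulate_cohort(sf.CohortConfig(n_samples=60), seed=1)
df = cohort.clinical.data

g1 = df[df["group"] == "group1"]
g2 = df[df["group"] == "group2"]
_, age_p = sf.ratio_shift_test(g1["age"], g2["age"])
print(f"mean age: {g1['age'].mean():.1f} vs {g2['age'].mean():.1f} years "
      f"(Mann-Whitney p = {age_p:.3g})")

counts = pd.crosstab(df["group"], df["location"])
stat, loc_p, method = sf.categorical_association(counts.to_numpy())
print(f"location association: {method}, p = {loc_p:.3g}")
print(counts.to_string())

surv = SurvivalTable.from_clinical(cohort.clinical)
chi2, lr_p = sf.logrank_test(surv)
curves = sf.km_curves(surv)
for g, c in curves.items():
    final = c["survival"].iloc[-1]
    print(f"KM {g}: {len(c)} time points, survival at last follow-up = {final:.2f}")
print(f"log-rank: chi2 = {chi2:.2f}, p = {lr_p:.3g} "
      "(group 1 progresses faster by construction)")
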