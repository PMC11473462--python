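"""Kaplan–Meier, log-rank and multivariate Cox on a simulated cohort.

The simulator embeds a ground-truth hazard ratio of 2.37 for the
high-pulmonary-fat-index group and 1.05 per year of age; everything else
is survival-neutral.  At the clinical sample size (n = 71) the point
estimates are noisy — the larger cohort below shows the effects cleanly.
"""

from ctbca import (
    CohortSpec,
    km_fit,
    logrank,
    median_split,
    run_cox_per_index,
    simulate_cohort,
    survival_at,
)

cohort = simulate_cohort(CohortSpec(n=500, seed=1))
split = median_split(cohort["pulmonary_fat_index"].to_numpy(), "pulmonary_fat_index")
low = cohort[split.labels == "low"]
high = cohort[split.labels == "high"]

km_low = km_fit(low["time"], low["event"])
km_high = km_fit(high["time"], high["event"])
for h in (24, 60):
    print(f"{h}-month survival: low PFI {100 * survival_at(km_low, h):.0f}% "
          f"vs high PFI {100 * survival_at(km_high, h):.0f}%")

lr = logrank(low["time"], low["event"], high["time"], high["event"])
print(f"log-rank: chi2 = {lr.chi_square:.2f}, p = {lr.p_value:.2g}\n")

model = run_cox_per_index(cohort, "pulmonary_fat_index")
print("multivariate Cox (enter-method, index group + clinical covariates):")
print(model.summary[["covariate", "hr", "ci95_low", "ci95_high", "p"]]
      .round(3).to_string(index=False))
print("\nhr is the hazard ratio per unit (per year for age; high-vs-low for "
      "the index group); the simulated truths are 2.37 (PFI group) and 1.05 (age).")
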