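"""Simulate a stable-nodule cohort and recover the proportional-error slope.

Builds 89 stable nodules (3-1300 mm^3, 3-8 scans each) whose volume
measurements carry Gaussian noise with SD proportional to the true volume
(a = 0.057), then regresses per-nodule SD on per-nodule mean through the
origin.  The fitted slope should land close to the generating 0.057; the
CV check confirms that above 100 mm^3 the relative scatter stays under 15%.
"""

from vctgrowth import (
    CohortConfig,
    cv_profile,
    fit_proportional_sd,
    simulate_cohort,
    summarize_nodule,
)

cohort = simulate_cohort(CohortConfig(seed=1))
summaries = [summarize_nodule(s) for s in cohort]
fit = fit_proportional_sd(summaries)

print(f"nodules: {fit.n_nodules}, scans: {sum(s.n_scans for s in cohort)}")
print(f"fitted slope a = {fit.slope:.4f} +/- {fit.slope_se:.4f} "
      f"(generated with a = 0.057)")
print(f"r^2 = {fit.r_squared:.3f}, p = {fit.p_value:.2e}")
frac = cv_profile(summaries, volume_threshold=100.0, cv_limit=0.15)
print(f"fraction of nodules >100 mm^3 with CV < 0.15: {frac:.2f}")
print("-> the SD of repeat volume measurements grows linearly with nodule "
      "size; the slope is the single reproducibility parameter of the "
      "decision analysis.")
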