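# vctgrowth

Measurement-error and decision analysis for volumetric CT (vCT) follow-up of
small pulmonary nodules.

Incidentally detected sub-centimeter lung nodules are followed with repeat CT
scans, and malignancy is suspected when the nodule's volume doubling time
falls in a clinically defined band (conventionally 30–400 days). But the
growth rate is estimated from two noisy volume measurements, so a truly
stable nodule can *appear* to grow — and the shorter the scan interval, the
larger the apparent rate a given measurement error produces. This package
implements the complete chain from a reproducibility model of the volume
measurement to a recommended follow-up interval, for radiologists,
biostatisticians and screening-program designers who want the trade-off made
explicit.

## The model

Nodule growth is exponential, `V(t) = V(0)·e^{kt}` with `k` in day⁻¹ and
doubling time `DT = ln2/k`. Two scans separated by `Δt` days give

    k = ln(V₂/V₁) / Δt.

Repeat vCT of stable nodules shows a volume SD proportional to the mean,
`σ_V = a·V̄` (fitted through the origin; `a ≈ 0.057` for non-calcified
nodules, `≈ 0.052` for a calcified validation arm). Propagating that error
through the estimate of `k` gives

    σ_k = a·√2 / Δt,

which is independent of nodule volume. Consequences, each implemented here:

- **False-positive rate.** A stable nodule's estimated `k` is
  `N(0, σ_k)`; the FPR is the normal mass on the band
  `ln2/400 < k < ln2/30` and falls as `Δt` grows.
- **Optimal interval.** The smallest integer `Δt` with FPR below a target
  (5% by default) — the same for a 3 mm and a 13 mm nodule.
- **True-positive rate.** Malignant growth rates follow
  `lognormal(μ_L = ln 0.015, σ_L = 0.83)` (least-squares fit to a published
  120-case histogram). Measurement noise blurs that distribution with a
  `N(0, σ_k)` kernel; the blurred band mass is the TPR and rises toward the
  pure lognormal ceiling (≈ 0.69) as `Δt` grows.
- **Empirical FPR.** For measured series, every forward-in-time scan pair
  contributes one `k`; the fraction landing in the band is the empirical FPR,
  directly comparable with the analytic value.
- **Synthetic cohorts.** A generator reproduces the study conditions
  (89 stable nodules of 3–1300 mm³, scan-count mix 44:26:9:6:1:3 over 3–8
  scans, proportional noise), so the whole pipeline is testable without
  patient data.

## Worked example

```python
from vctgrowth import (CohortConfig, simulate_cohort, summarize_nodule,
                       fit_proportional_sd, optimal_interval, stable_fpr)

cohort = simulate_cohort(CohortConfig(seed=1))          # 89 stable nodules
fit = fit_proportional_sd([summarize_nodule(s) for s in cohort])
print(f"fitted slope a = {fit.slope:.4f} +/- {fit.slope_se:.4f}")
best = optimal_interval(fit.slope, alpha=0.05)
print(f"optimal interval: {best} days (FPR {stable_fpr(best, fit.slope):.4f})")
```

prints

```
fitted slope a = 0.0560 +/- 0.0029
optimal interval: 76 days (FPR 0.0482)
```

meaning: the regression of per-nodule SD on mean volume recovers the
generating error slope (0.057) within one standard error, and with that
measured reproducibility a follow-up scan should wait 76 days before a
doubling-time call keeps the false-alarm probability for stable nodules
under 5%. At the canonical slope 0.057 the interval is 77 days with
FPR 0.0489.

The `examples/` directory holds one short script per capability (error-slope
fitting, optimal interval, FPR/TPR curves, empirical pairwise FPR, lognormal
histogram fitting), each printing its numbers with a line on what they mean.
The same operations are exposed as a thin CLI:

```
vctgrowth optimal-interval --slope 0.057 --alpha 0.05
vctgrowth simulate --preset paper-stable --seed 1 --out cohort.csv
vctgrowth fit-sd cohort.csv
vctgrowth rates --slope 0.057 --grid 30:180:10
```

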