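# Methods

## Growth model and decision rule

Nodule volume follows simple exponential kinetics, `V(t) = V(0)·e^{kt}`,
with `k` in day⁻¹, time in days and volumes in mm³. The doubling time is
`DT = ln2/k`; a stable nodule has `k = 0`, for which the doubling time is
reported as an explicit infinity rather than a numeric overflow (negative
`k` yields a negative value, i.e. a halving time). All analysis is carried
out in `k`-space rather than `DT`-space because the estimation error of `k`
for a stable nodule is symmetric about zero while `DT` diverges there.

A nodule is called positive when its estimated `k` lies strictly inside the
band corresponding to doubling times between `dt_min = 30` and
`dt_max = 400` days: `ln2/400 < k < ln2/30` (0.001733–0.023105 day⁻¹).
Only the positive-growth band counts; apparent shrinkage is never a
positive call.

## Proportional measurement error

The reproducibility model is `σ_V = a·V̄`: the SD of repeat volume
measurements of a stable nodule is proportional to its mean measured
volume, with a single dimensionless slope `a` and no intercept. Defaults
are `a = 0.057` (non-calcified nodules) and `a = 0.052` (calcified
validation arm). The slope is estimated by ordinary least squares of the
per-nodule sample SD (n−1 denominator) on the per-nodule mean, with the
intercept fixed at zero — the repeated-measures route recommended when
each subject contributes more than two repeats, where a Bland–Altman
difference analysis does not apply.

Two R² conventions exist for through-origin fits. The fit reports the
*centered* R² (`1 − SS_res/Σ(y−ȳ)²`), comparable with ordinary regression,
as the primary value, and keeps the uncentered value (which no-intercept
software defaults tend to print, and which is systematically higher) in a
secondary field. The slope's p-value is the two-sided t-test of zero slope
on n−1 degrees of freedom. The numerical fit is delegated to statsmodels
OLS; the centered R² is computed alongside.

First-order error propagation through `k = ln(V₂/V₁)/Δt` gives

    σ_k² = (σ_V1/(Δt·V₁))² + (σ_V2/(Δt·V₂))²,

which under `σ_V = a·V` collapses to `σ_k = a√2/Δt` — independent of
volume. That volume independence is what makes a single optimal follow-up
interval meaningful across the whole 3–1300 mm³ range, and it is asserted
structurally: the proportional form takes no volume argument.

## Classification rates and the optimal interval

**FPR.** A stable nodule's estimated `k` is `N(0, σ_k)`, so
`FPR(Δt) = Φ(k_high/σ_k) − Φ(k_low/σ_k)`. With `a = 0` the FPR is defined
as exactly zero. FPR is not monotone over all `Δt` (at extremely short
intervals σ_k is so wide that little mass sits in the band), but beyond
`σ_k < k_low` it decays monotonically to zero.

**Optimal interval.** The smallest integer `Δt` (days) with
`FPR(Δt) < α`, found by exhaustive scan from 1 upward with a strict
inequality; the scan is trivially cheap and exact, so no faster search is
layered on top. If `Δt = 1` already satisfies the target the result is
degenerate and logged as such. At `a = 0.057`, `α = 0.05` and the default
band the interval is 77 days (FPR 0.0490; 0.0512 one day earlier).

**Malignant growth-rate law.** Malignant `k` follows
`lognormal(μ_L, σ_L)` with defaults `μ_L = ln 0.015`, `σ_L = 0.83`, as
obtained by least squares against a published histogram of 120 malignant
nodules. The histogram fit (`fit_lognormal_to_histogram`) estimates an
amplitude jointly with `(μ_L, σ_L)` because a curve fitted to raw counts is
not automatically normalized — the amplitude absorbs sample size and bin
width and is reported, never silently divided out. The fit presumes
equal-width bins (counts then proportional to the density at bin centers);
log-spaced bins would need a bin-width correction first, otherwise the
fitted `μ_L` shifts by `+σ_L²`. Probability statements (TPR) always use
the normalized density.

**TPR.** The pure TPR is the lognormal mass on the band
(0.6940 at the defaults). At a finite interval, the estimated `k` of a
malignant nodule is its true `k` plus `N(0, σ_k)` noise, so the observable
distribution is the lognormal convolved with the Gaussian kernel, and the
TPR is the blurred mass on the band. Blurring at the default parameters
always loses band mass, and TPR(Δt) rises to the pure ceiling as
`Δt → ∞` with an `O(σ_k²)` gap (the second-order edge correction
`(σ_k²/2)·[f′(k_low) − f′(k_high)]`).

## Numerical choices

- The band integral of the blurred density is evaluated in exchanged order
  as a single adaptive quadrature,
  `∫ f_logn(x)·[Φ((k_high−x)/σ_k) − Φ((k_low−x)/σ_k)] dx` over the
  lognormal support (0, e^{μ_L+10σ_L}), which is mathematically identical
  to convolve-then-integrate but exact to quadrature tolerance even for
  very narrow kernels. The Φ factor transitions within ~σ_k of each band
  edge; those boundary layers are cut into their own integration segments
  (edges ± 8σ_k), without which an adaptive rule on a long segment can step
  straight over them and undershoot the TPR by ~0.4·σ_k·(f(k_low)+f(k_high)).
- The pointwise blurred density integrates in the standardized kernel
  variable `t = (k−x)/σ_k` over (−12, 12), keeping the Gaussian factor
  O(1) wide regardless of σ_k, with the lognormal mode flagged to the
  subdivider. Quadrature error estimates above 1e−6 raise an explicit
  numerical-failure error rather than returning a doubtful value.
- Normal and lognormal CDFs come from scipy.stats; no spreadsheet
  semantics are emulated beyond the mathematical definitions.
- Elapsed time is the whole-day difference of calendar dates; no
  time-of-day resolution. Window membership uses strict inequalities on
  both edges.
- Duplicate scan dates within a nodule are rejected (Δt = 0 leaves the
  rate undefined) rather than silently dropped.

## Synthetic cohorts

The generator emulates the study conditions the pipeline was calibrated
on: 89 stable non-calcified nodules (49 calcified at `a = 0.052`), true
volumes uniform on 3–1300 mm³, 3–8 scans per nodule with frequencies
44:26:9:6:1:3, inter-scan gaps uniform on 60–400 days from an arbitrary
calendar anchor (only day differences enter any computation), and, for the
malignant arm, per-nodule `k` drawn from `lognormal(ln 0.015, 0.83)` with
the true volume evolving exponentially between scans.

Noise is additive zero-mean Gaussian on the volume scale with SD
proportional to the *true* volume; non-positive draws are resampled, not
clipped, so the mean stays unbiased even for 3 mm³ nodules (where
truncation is astronomically rare at `a ≈ 0.057` anyway). A multiplicative
lognormal noise mode with matched CV is available behind a config switch
for sensitivity analysis. The proportionality constant was observed on
*measured summaries*, so the generative law is a modelling choice; the
additive-Gaussian default is the simplest law consistent with it.

**Sample-SD calibration.** The error slope is defined operationally as the
through-origin regression coefficient of per-nodule *sample* SDs. For
small n the Gaussian sample SD is biased low by the classical factor
`c4(n)` (`E[s] = c4(n)·σ`, `c4(3) = 0.886`), so a generator whose true
per-draw SD were `a·V` would yield fitted slopes centred near `0.91·a`,
not `a`. By default the generator therefore scales the per-draw SD by
`1/c4(n)` so that the expected n-scan sample SD — the quantity the
regression actually sees — equals `a·V` exactly, making the fitted slope
an unbiased recovery of the nominal `a`. The switch
`calibrate_sample_sd=False` restores true per-draw SD `= a·V`; that mode
is the right premise when comparing Monte-Carlo classification rates with
the analytic formulas, whose assumption is `σ_V = a·V` for the individual
measurement, and it is what the analytic-equivalence tests use.

What the generator does *not* emulate: segmentation failures and the
associated ~30% exclusion rate, scanner/kernel/dose effects, correlated
errors between scans of the same patient, sub-solid or perivascular
morphology, and any deviation from exponential kinetics. Passing recovery
tests therefore show the *statistical* chain is correct under the stated
error law, not that the error law holds for any particular scanner or
software.

## Problem sizes

Recovery tests run at the study sizes (89 and 49 nodules) plus a
1000-nodule tightening check; Monte-Carlo/analytic equivalence tests use
10⁴–2·10⁴ independent two-scan pairs, chosen so binomial error is well
below the effects under test. The acceptance script reports slope
recoveries as the mean over 16 replicate cohorts at the study sizes, since
a single 89-nodule cohort's fitted slope has Monte-Carlo scatter
(SD ≈ 0.004) comparable to the recovery tolerance itself.

## Known limitations

- The 25% stability filter is formalized as max absolute deviation from
  the per-nodule mean relative to that mean; the reference volume (mean
  vs first scan) and threshold are configurable because the operational
  definition in clinical use varies.
- The blurred-TPR machinery treats the measurement-noise kernel as
  Gaussian in `k`-space; for very short intervals and very small nodules
  the log-ratio noise is only approximately Gaussian.
- Forward pairs within one nodule share measurements, so pairwise
  empirical FPRs on few nodules with many scans have more variance than a
  binomial count of independent pairs; equivalence tests use two-scan
  cohorts where pairs are independent.
- The empirical FPR of a real stability-filtered cohort sits below the
  analytic prediction by construction: the filter removes exactly the
  large-deviation measurements that drive false positives. The analytic
  model carries no such filter.
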