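# Methods

## Positivity model and threshold

Per marker, all segmented cells' mean intensities are pooled over every
core and patient and modeled as a two-component mixture

    f(x) = π_noise · f_χ²(x; df, s)  +  (1 − π_noise) · N(x; μ, σ²),   x ≥ 0,

where the noise (marker-negative) component is a *scaled* chi-squared
density — equivalently a gamma with shape df/2 and scale 2s — and the
signal (marker-positive) component is normal. The scale parameter s is
essential: raw fluorescence units are arbitrary, and an unscaled
chi-squared pins the noise mean to its degrees of freedom. The degrees of
freedom are treated as a continuous positive parameter and estimated.

**EM.** The E-step computes each cell's posterior probability of having
come from the noise component. The M-step updates the normal parameters by
weighted mean/variance in closed form and the gamma-form noise parameters
by exact weighted maximum likelihood: for fixed shape the optimal scale is
the weighted mean over the shape, and the profiled shape solves
log a − ψ(a) = log(weighted mean) − weighted mean of logs, a
one-dimensional root found by Brent's method. Iteration stops when the
observed-data log-likelihood changes by less than `tol` (default 1e−8,
`max_iter` 500); the log-likelihood is computed with log-sum-exp and is
non-decreasing by construction (asserted in tests). Zero intensities are
nudged to 1e−12 so the gamma likelihood is defined.

**Initialization** is deterministic: the noise weight starts at the
fraction of cells below the 75th percentile, noise moments are matched on
the lower half, signal moments on the upper quartile. If the default start
fails to converge, two fixed fallback starts are tried (a more separated
configuration, and a near-degenerate one with 5% noise weight for data
that is essentially all signal — without it, a flexible gamma can mimic
the normal and split a pure-signal sample spuriously); the highest
log-likelihood wins. Non-convergence is reported via a flag, never an
exception.

**Threshold.** The positivity cut is the intersection of the weighted
component densities: the root of
π_noise·f_χ²(x) − (1 − π_noise)·N(x) between the noise mode and μ,
located by a 2048-point bracketing grid plus bisection to 1e−8 intensity
units. With several crossings the largest root below μ is used — the
point where the signal density finally overtakes the noise. If the
weighted densities never cross (one component dominates everywhere), the
threshold falls back to the noise component's upper 1e−4 tail quantile
and the fit is flagged. Cells are called positive strictly above the
threshold; a boundary cell is equidensity by construction, so the
convention is immaterial for continuous data but fixed for
reproducibility. The fit is pooled per marker across all samples — one
global threshold per marker, no per-patient hierarchy.

## Compartment densities

Each 1-mm core contributes a tumor and a stroma area (mm²); area not
attributed to either (excluded/blank regions) simply does not enter any
denominator. Duplicate cores of a patient are combined by pooling counts
and areas (ratio of sums) rather than averaging per-core densities, which
is unbiased when evaluable areas differ between duplicates. Whole-core
density pools both compartments, so the area-weighted-mean identity
whole × total area = tumor × tumor area + stroma × stroma area holds
exactly per patient. Double positivity requires the CK call and the
marker call on the same cell, so double-positive density can never exceed
CK⁺ density. Cores with zero or missing total area are excluded with a
warning; a patient left without cores gets missing densities.

## Dichotomization

The primary cut-off is the sample median, high strictly above, ties low —
a fixed convention that makes the split reproducible (with distinct values
and even n it is an exact half split). ROC analysis over all empirical
thresholds reports the AUC and the Youden-optimal (max sensitivity +
specificity − 1) candidate, and whether that candidate improves J over the
median split by more than a margin (default 0.05); the ROC-reported
cut-off is shifted to the midpoint between adjacent observed values so the
package-wide strict-`>` rule selects exactly the maximizing confusion
matrix. Shape diagnostics use the small-sample-adjusted (G1, G2) skewness
and excess-kurtosis formulas, the default in the clinical statistics
packages this analysis style comes from; they require n ≥ 4. When both a
full cohort and an outcome-complete subset exist, the median is computed
on the full cohort and the association on the complete subset.

## Association statistics

The 2×2 layout is rows = exposure (low, high), columns = outcome (none,
event); the cross-product odds ratio (d·a)/(b·c) is the odds of the event
in the high group over the low group. The 95% CI is Woolf's: symmetric
around log OR with SE = √(1/a + 1/b + 1/c + 1/d). Any zero cell triggers
the Haldane–Anscombe +0.5 correction to all four cells (flagged in the
result); a zero row/column margin leaves the OR undefined and raises. The
chi-square test is the uncorrected Pearson statistic on 1 df — with
Yates' correction the published-style p on the example table would be
≈0.007 rather than 0.003, so no correction is applied. Fisher's exact
test is two-sided by the minimum-likelihood rule (sum of hypergeometric
probabilities not exceeding the observed table's), delegated to
`scipy.stats.fisher_exact` and cross-checked in tests against an
exhaustive enumeration oracle.

Logistic regression is fitted by IRLS (statsmodels GLM, binomial family)
with Wald CIs — consistent with the Woolf CI in the saturated 2×2 case,
where exp(slope) equals the cross-product OR exactly. Separation is
detected post-fit: a coefficient with |estimate| > 10 and SE > 50 is
flagged and its odds ratio reported as undefined while the near-1 Wald
p-value is kept, mirroring how clinical packages print unresolved
separation (no Firth or exact-logistic rescue is attempted). Categorical
covariates expand to indicators — stage against reference IA, histology
as adenocarcinoma vs rest, sex as female vs male — and age stays
continuous. The screening battery runs each dichotomized density and each
clinical covariate univariately against three outcomes (any relapse, CNS
relapse vs rest, non-CNS relapse), then one multivariate model of density
+ age + histology + stage.

## Survival

Kaplan–Meier product-limit curves per group and the two-group log-rank
test (hypergeometric variance, chi-squared on 1 df) are delegated to
`lifelines`, with the standard tie convention of events before censorings
at equal times. The comparison groups are CNS relapse versus all other
patients (non-relapsed pooled with otherwise-relapsed). Rendered reports
print p-values below 1e−4 as "<0.0001"; structured output keeps full
precision.

## Synthetic cohort

The generator emulates the data a multiplexed-immunofluorescence TMA study
produces, not the images: per patient, duplicate 1-mm cores
(area π/4 mm²) with Poisson cell counts (default mean 800 per core, a
realistic segmented-cell yield for a 1-mm core); cells assigned to the
tumor compartment with the configured area fraction (default 0.6), the
area table split with the same fraction; marker intensities drawn from the
chi-squared + truncated-normal mixture with the generating component
recorded as a truth label; a CNS-relapse indicator drawn per patient from
expit(β₀ + β₁ · true NRF2⁺/CK⁺ whole-core density); other relapse sites
multinomial with frequencies from the observed cohort distribution;
overall survival exponential with group medians (defaults 12 months for
CNS relapse, 60 otherwise) under uniform administrative censoring at
57–117 months of follow-up; covariates (age, sex, histology, stage,
smoking) drawn independently of density from the observed cohort
frequencies; relapse-site missingness completely at random with an exact
count.

A marker may carry between-patient heterogeneity: the per-patient positive
fraction is Beta-distributed with configurable concentration. This is what
makes the patient-level density distribution strongly right-skewed, as in
real cohorts, and gives the median split something real to separate; with
the dispersion disabled all patients share one positive fraction and
densities vary only by counting noise.

The study-sized preset has 304 patients with exactly 46 missing relapse
sites (258 analyzable). Its logistic intercept and slope
(−4.1298, 0.0055257 per cell/mm²) were calibrated once, by Monte-Carlo
solution of the two group-rate equations, so the *expected* counts of the
(median-split density × CNS relapse) table match the observed study table
(2/126 low-group and 14/132 high-group relapse rates, implied OR 7.356);
they are fixed constants, not refit at run time. A patient-level companion
generator draws true densities directly from their exact marginal
(Poisson cell count, binomial double-positive count) and is used for
large-scale recovery checks where cell tables would be pointlessly heavy.

What the generator does **not** emulate: spatial structure within cores,
segmentation errors, staining artefacts, marker cross-talk or
compartment-dependent marker rates (CK positivity is independent of the
compartment label), informative censoring, and covariate–outcome
confounding. Tests passing on these cohorts therefore validate the
statistical machinery and its calibration, not robustness to imaging
artefacts.

## Problem sizes and numerical choices in the checks

Parameter-recovery checks run 20 simulations of 50,000 cells at the
canonical mixture (70% chi-squared(2) noise, N(8, 1.5²) signal); the
threshold oracle is a 10⁶-point grid scan. The grid/bisection agreement
tolerance is 2%; recovery tolerance 5% relative per parameter. At a 90%
noise weight the signal component has ~5,000 cells and the Monte-Carlo
spread of σ alone approaches 3%, so the 5%-recovery check is run at the
canonical 70% weight while the noise-weight sweep (0.5/0.7/0.9) constrains
the threshold, whose sampling spread stays under 2%. Classification
accuracy is compared against the analytic Bayes accuracy of the generating
mixture (≈94% at the canonical parameters) rather than a round target —
the intersection rule *is* the Bayes rule, so no threshold can do better.
Null calibration uses 100 replicate cohorts of 150 patients × 2 cores ×
~100 cells with the density effect zeroed and a 10% baseline relapse rate,
each run through the full threshold → density → median-split →
odds-ratio path; coverage of 1 by the 95% Woolf CI is required in ≥ 90.
The exhaustive Fisher cross-check enumerates every 2×2 table with total
≤ 30 and 1,000 random tables with totals to 60 (the full enumeration to
60 adds ~600,000 tables for no additional structural coverage).
Multivariate odds-ratio recovery uses the patient-level preset at 100×
(30,400 patients).

## Known limitations

- One global threshold per marker; no per-sample or hierarchical
  thresholds, and no more than two mixture components.
- Separation in logistic models is reported, not resolved.
- The ROC cut-off search optimizes Youden's J only.
- The survival module fits no regression model (no Cox); it estimates and
  compares curves.
- The mixture fit assumes the signal component is far enough from zero
  that normal truncation is negligible in the likelihood; markers whose
  positive population hugs zero would need a truncated-normal M-step.
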