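# tmaquant

Quantification and relapse-risk analysis for multiplexed immunofluorescence
tissue-microarray (TMA) cohorts.

In early-stage non-small cell lung cancer, the density of tumor cells
co-expressing cytokeratin (CK) and the antioxidant-response transcription
factor NRF2 has been linked to the risk of first relapse in the central
nervous system (CNS). `tmaquant` implements the full analysis path from
segmented-cell intensity tables to that clinical association:

1. **Positivity thresholding.** For each marker, all cells' mean
   fluorescence intensities are pooled and modeled as a two-component
   mixture: a scaled chi-squared density for the marker-negative (noise)
   population and a normal density for the marker-positive population,

   f(x) = π·f<sub>χ²</sub>(x; k, s) + (1 − π)·𝒩(x; μ, σ²),

   fitted by EM. The positivity threshold is the intersection of the two
   weighted component densities — the intensity where a cell becomes more
   likely to be signal than noise (the Bayes decision boundary).
2. **Compartment densities.** Per patient, CK⁺ and double-positive
   (NRF2⁺/CK⁺, TrxR1⁺/CK⁺) cell counts from duplicate 1-mm cores are
   pooled and divided by compartment area, in cells/mm², for the tumor,
   stroma and whole-core compartments.
3. **Dichotomization.** Densities are split at the sample median (ties
   low); ROC/Youden analysis checks for a better cut-off; skewness and
   excess kurtosis diagnose the distribution shape.
4. **Association.** The 2×2 cross-tab of density group against CNS relapse
   gives a cross-product odds ratio with a Woolf 95% CI
   (SE = √(1/a + 1/b + 1/c + 1/d) on the log scale), an uncorrected
   Pearson chi-square, and Fisher's exact test; univariate and
   multivariate binary logistic regression (IRLS) add covariate-adjusted
   odds ratios with detection of separation.
5. **Survival.** Kaplan–Meier curves and the log-rank test compare overall
   survival of CNS-relapse patients against everyone else.

Because patient-level data of this kind are not publicly available, the
package includes a synthetic-cohort generator that reproduces the
statistical structure of such a study — per-cell mixture intensities,
duplicate cores, compartment areas, and a CNS-relapse outcome generated
through a logistic link to the true NRF2⁺/CK⁺ density — with ground-truth
labels for oracle testing.

## Worked example

```python
import numpy as np
from tmaquant import fit_mixture, find_threshold, classify_cells
from tmaquant import ContingencyTable2x2, odds_ratio, pearson_chi2, fisher_exact

# cross-tab of median-split whole-core NRF2+/CK+ density vs CNS relapse:
# 126 low-density patients (2 CNS relapses), 132 high (14 CNS relapses)
t = ContingencyTable2x2(a=124, b=2, c=118, d=14)
res = odds_ratio(t)
stat, p = pearson_chi2(t)
print(f"OR = {res.or_:.2f} (95% CI {res.ci_low:.2f}-{res.ci_high:.2f})")
print(f"chi-square = {stat:.2f}, p = {p:.3f}; Fisher p = {fisher_exact(t):.4f}")

# threshold a simulated marker: 70% chi-squared(2) noise, 30% N(8, 1.5) signal
rng = np.random.default_rng(0)
n = 20_000
noise = rng.random(n) < 0.7
x = np.where(noise, rng.chisquare(2.0, n), rng.normal(8.0, 1.5, n))
fit = fit_mixture(np.maximum(x, 0.0))
thr = find_threshold(fit)
calls = classify_cells(x, thr)
print(f"threshold={thr:.3f}  positive fraction={calls.mean():.3f}")
```

prints

```
OR = 7.36 (95% CI 1.64-33.06)
chi-square = 9.01, p = 0.003; Fisher p = 0.0033
threshold=5.585  positive fraction=0.329
```

The odds ratio says high-density patients had 7.4 times the odds of CNS
relapse of low-density patients, with a chi-square p-value of 0.003; the
fitted threshold (5.59 intensity units) recovers the crossing of the
generating densities, and the positive-call fraction matches the 30%
signal weight up to the overlap of the components.

The full pipeline — simulate or ingest, threshold, classify, densities,
cut-offs, association, survival — runs from the command line:

```sh
tmaquant simulate --seed 1 --out sim/
tmaquant threshold --cells sim/cells.csv --marker NRF2 --out fit_NRF2.json
tmaquant run --config pipeline.yaml
```

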