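# Methods

## Harmonization

Raw scores on bounded instruments are mapped to percent of their range,
`100·(raw − min)/(max − min)`; open-ended instruments (semantic fluency) pass
through. Follow-up is capped at 72 months after study entry. Every cohort ×
scale stream is then standardized to its own baseline: a subject's baseline is
their earliest visit with a nonmissing value, and the baseline mean and SD
(n−1 denominator) standardize all of that cohort's visits for the scale. The
percent step is affine per scale and therefore cannot change the z-scores; it
is kept so intermediate tables are on the conventional reporting scale.
Because PC directions are arbitrary anyway, scale directions are left as-is
by default; `flip=True` makes "worse" the positive direction on every scale,
which is convenient when interpreting synthetic-data tests.

Hoehn & Yahr stage is treated as numeric on its 0–5 half-point grid; cohort
differences between modified and original staging are absorbed by the
within-cohort standardization.

## Mixed-effects random slopes

Each scale's model has fixed effects for age at onset (centered), sex, and
cohort (indicator contrasts, largest cohort as reference), each also
interacted with time from self-reported symptom onset; cognitive scales add
years of education before higher education (centered) and a higher-education
flag, likewise interacted with time. Subjects carry a correlated random
intercept and random slope on time. Estimation is REML via `statsmodels`
`MixedLM`; time is linear (no visit-level polynomials). Subjects with only a
single visit are retained — their slope prediction is the population-
conditional shrinkage value. Subjects missing a covariate are dropped with a
logged count.

Two numerical edge cases are handled explicitly:

* **Noise-free data.** When the per-subject OLS lines interpolate the data
  (pooled residual SD below 10⁻⁸ of the response SD), the REML objective is
  unbounded and no optimizer output is trustworthy. The BLUP limit as the
  residual variance tends to zero in a balanced design is the per-subject OLS
  slope minus the fixed-effect prediction, and that limit is returned
  directly (`method = "noise-free-limit"` in the diagnostics).
* **Boundary covariance.** If the fitted 2×2 random-effect covariance is
  singular (smallest eigenvalue below 10⁻⁸ of the largest), the model is
  refit with independent intercept and slope and flagged
  (`method = "reml-diagonal"`); non-convergence is reported in the
  diagnostics, never by silently dropping a column.

The test suite verifies the BLUPs against a hand-coded Henderson
mixed-model-equations solver at the fitted variance components. Note the
componentwise shrinkage bound (|predicted slope| ≤ |OLS deviation|) holds
only when intercept and slope are decoupled (diagonal covariance, centered
balanced times); with a free 2×2 covariance the predictor legitimately
borrows strength across the intercept, so only aggregate shrinkage is
guaranteed.

## PCA progression scores

The slope matrix is reduced by correlation-matrix PCA (zero-centered, unit
variance columns) on complete cases per domain: motor (MDS-UPDRS III,
MDS-UPDRS II, Hoehn & Yahr), cognitive (MoCA, semantic fluency, MDS-UPDRS
1.1), and composite (all six pooled — the composite PCA re-pools raw slope
columns rather than re-using the domain PC1s). PC1 is the progression score.
Since eigenvector signs are arbitrary, an explicit orientation is imposed and
logged: motor and composite scores are oriented so the MDS-UPDRS III loading
is positive, the cognitive score so the MoCA loading is negative — in all
three, larger scores mean faster deterioration (anchors flip accordingly when
direction harmonization was applied upstream). Near-degenerate leading
eigenvalues (gap < 10⁻⁸) are logged as fragile.

## GWAS

Per variant, OLS of the score on alt-allele dosage plus intercept, cohort
indicators, and the leading genetic principal components (default 5, computed
from the column-standardized dosage matrix). The Wald p-value uses the t
reference with residual degrees of freedom; at n ≈ 2,000 this is
indistinguishable from the normal reference (a flag switches to normal).
Variants with minor allele frequency below 1% are excluded and counted.
Missing dosages are handled per variant as complete cases with per-variant n.
The scan is vectorized by Frisch–Waugh–Lovell residualization against the
shared covariates, which is algebraically identical to the per-variant joint
fit; the tests pin this to a brute-force normal-equations oracle at 10⁻⁸
relative. Genomic control λ is median(Wald²)/0.4549. Sex-stratified scans
rerun the GWAS within stratum (sex removed from covariates; strata under a
configurable minimum n are flagged and skipped).

## Conditional analysis, stepwise selection, gene-based test

Conditioning is exact: the conditioned dosages enter the per-variant OLS as
covariates (not the summary-statistic approximation used when only an
external LD reference is available; the two agree when the LD reference
equals the analysis sample). Stepwise selection greedily adds the variant
with the smallest conditional p while it is below the significance threshold
(default 5×10⁻⁸), ties broken by genomic position and logged, and reports the
final joint model.

The gene-based statistic is the sum of per-variant Wald χ² inside the region
(BED input is converted from 0-based half-open to 1-based inclusive).  Its
null distribution is simulated as Σzᵢ² with z drawn from N(0, R), R the
correlation matrix of the covariate-residualized dosages in the region
(eigenvalue-clipped at zero for numerical safety); p = (1 + exceedances)/(1 +
draws). Draws stop early once the 99% CI of p excludes the Bonferroni
reporting threshold 0.05/(number of tested genes). This plays the same
inferential role as SNP-wise gene aggregation tools but is fully specified
here; its p-values are not expected to match any external tool numerically.

## Targeted associations and sensitivity procedures

Genetic risk scores are Σ weight × effect-allele dosage with allele
orientation resolved against the genotype ref/alt (effect = ref flips dosage
to 2−d); strand-ambiguous A/T and C/G variants are flagged but included, and
unmatched weight rows are reported. Carrier flags, risk scores, and candidate
dosages all go through the same OLS Wald machinery as the GWAS, so a
single-dosage predictor reproduces that variant's GWAS row exactly.

Misdiagnosis filters: subjects with recorded diagnostic certainty below the
threshold (default 90%) are removed — subjects without a rating are retained,
matching cohorts that never collected one; extreme-progressor trimming drops
⌈fraction·n⌉ subjects from each tail of the named score (default 5%, applied
per score). Symmetric outcome trimming attenuates a true slope by roughly the
truncated-variance factor (≈ 0.62 for the middle 90% of a Gaussian), so tests
assert sign preservation with attenuation in that band rather than
near-equality.

The medication adjustment reconstructs untreated motor-exam severity as
`observed + attenuation × LEDD` *before* harmonization, rather than entering
dose as a model covariate: dose tracks underlying severity, so covariate
adjustment would remove part of the outcome itself. The attenuation
coefficient (exam points per mg/day) is a user input; the simulator embeds a
known value so the procedure is testable without external estimates. Visits
without a recorded dose pass through flagged; values pushed outside the scale
range are clipped with a logged count. Covariate-mode adjustment remains
available for comparison via the GWAS `CovariateSet.extra` mechanism.

## Synthetic cohort generator

The generator emulates the study design the pipeline assumes, with truth
tables for recovery testing.

* **Genotypes.** Two haplotypes per subject; each haplotype is a latent
  AR(1) Gaussian vector within blocks of `ld_block_size` (correlation
  `ld_rho`, independence across blocks) thresholded at the normal quantile of
  the allele frequency — Hardy–Weinberg marginals with controllable LD. A
  helper inverts the copula numerically to hit target *dosage* correlations,
  used to construct blocks with specified r². An optional two-group allele
  frequency shift exists solely to validate genetic-PC adjustment.
* **Latent severity.** Per domain (motor, cognitive), severity is linear in
  time from onset with correlated Gaussian random intercepts and slopes
  (defaults: intercept SD 1, slope SD 0.2/yr, intercept–slope covariance
  0.02, motor–cognitive slope correlation 0.3); slopes also carry small age,
  sex, and (cognitive) education effects, optional carrier effects, and the
  configured causal dosage effects in slope-SD units. Gaussian random effects
  are assumed, as in standard mixed models.
* **Observed scales.** Each instrument is an affine map of its domain's
  severity (anchors/amplitudes at typical early-PD values, e.g. MDS-UPDRS III
  ≈ 24 ± 12) plus a scale-specific random intercept and slope (SD 0.5 and
  0.12/yr) — real instruments do not share one latent trajectory exactly,
  and without this the domain PCAs would be degenerate (~100% PC1) — a
  cohort × scale measurement offset, and visit-level Gaussian noise (SD
  0.35), truncated to the scale range. Values are not rounded to integer
  grids.
* **Design.** Entry occurs 2.9 ± 2.6 years after onset (truncated normal);
  visits follow the configured schedule (default annual to 72 months) with
  per-visit jitter, monotone dropout (default 6%/visit, optionally
  severity-dependent), and per-measurement missingness (default 5%, MCAR).
  LEDD is `300 + 100·(motor severity) + noise` mg/day, and an optional
  treatment attenuation subtracts `attenuation × LEDD` motor-exam points, so
  medication masks severity with a known confounding structure.

What the generator does *not* emulate: item-level scale structure, integer
scoring grids, rater effects and practice effects, informative missingness
beyond the optional severity-linked dropout, imputation uncertainty in
dosages, and realistic genome-wide LD beyond block-AR(1). Passing tests
therefore show the estimators are correct and calibrated under the assumed
generative model, not that real cohorts satisfy those assumptions.

## Reference experiments and problem sizes

The acceptance-level experiments (package `experiments` module) use desk
scale: ~2,000 subjects, 5,000 variants for the null-calibration lambda; 20
replicates for the effect-recovery and signal-dissection ensembles; 200 genes
× 10 variants for gene-test calibration. These sizes give sampling error
comfortably inside the asserted tolerances (e.g. the median-based λ has SD ≈
0.033 at 5,000 variants) while keeping each experiment in seconds to minutes.

In the signal-dissection experiment the two causal effects are deliberately
unequal (0.5 and 0.4 slope-SD). With exactly equal effects, whenever the
secondary variant is selected first the r² = 0.9 proxy of the primary becomes
statistically near-interchangeable with the primary in the conditional scan,
and no selection procedure can reliably prefer the true causal — the unequal
design mirrors the strong-primary/weaker-secondary pattern of real
multi-signal loci and makes the target identifiable.

The slope-fidelity experiments are designed around closed-form limits. The
noise-free check keeps trajectory dispersion small enough that no value
reaches a scale bound, because a truncated observation no longer lies on its
subject's line and the exact-OLS limit does not apply to censored data. The
noisy-recovery check uses complete attendance (its design prescribes five
visits per subject) and measurement-error SD 0.25 latent units: the
correlation between any slope estimate and the truth is capped at
√(τ²S_tt/(τ²S_tt+σ²)), and this noise level puts the ceiling at ≈0.89,
leaving headroom to detect estimator defects against the 0.8 requirement
(at the cohort-default noise of 0.35 the ceiling itself is 0.805).

The effect-recovery oracle defines the "induced score-scale effect" as
(regression of the final score on the true latent cognitive slope) × (realized
regression of that slope on dosage); the variant influences the score only
through the latent slope, so this product is the exact expectation of the
GWAS beta under the generative model.

## Known limitations

* Hoehn & Yahr is modelled as continuous; no ordinal or generalized mixed
  models.
* No kinship/mixed-model GWAS, no meta-analysis across cohorts (cohorts are
  pooled at the individual level), no imputation, and no summary-statistic
  conditional mode.
* The gene-based Monte-Carlo p has resolution 1/(1 + draws); genome-wide
  Bonferroni thresholds need draw counts of order 10⁶ (the default), which is
  the slow path.
* PCA requires complete cases per domain; slope cells are not imputed.
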