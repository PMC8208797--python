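# Methods

This note records the models the package implements, the defaults it
ships, and the numerical and design choices made where more than one
reasonable option existed. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## The clocks

**PhenoAge (Gompertz mortality clock).** A linear predictor *xb* over
nine clinical-chemistry biomarkers and chronological age parameterizes a
Gompertz proportional-hazards model, h(t) = e^xb · e^γt with t in months
and γ = 0.0076927 per month. The 120-month cumulative hazard gives the
10-year mortality risk, risk = 1 − exp{−e^xb (e^120γ − 1)/γ}, mapped to
years by PhenoAge = 141.50 + ln(−0.00553 · ln(1 − risk))/0.09165. Note
the constant 0.00553 *multiplies* the log-survival term — the equivalent
published form 141.50 + ln(0.00553 · 1.51714 · e^xb / 0.0076927)/0.09165
fixes the algebra unambiguously, and only this reading produces PhenoAges
on a human scale (the division variant maps a 6% ten-year risk to ~167
years). The γ unit is months, inferred from the 120-month horizon inside
the exponent.

Implementation details:

- CRP enters on the natural-log scale; raw CRP ≤ 0 is treated as missing.
- The shipped coefficients (`params/phenoage_nhanes3.toml`) are tied to
  their NHANES training units (albumin g/L, creatinine µmol/L, glucose
  mmol/L, CRP mg/dL, MCV fL, ALP U/L, WBC 10³/µL). Scoring *refuses* to
  run when a cohort's declared units contradict the parameter set's,
  rather than silently producing garbage; no unit conversion is
  attempted.
- Extreme *xb* saturates the risk at the nearest representable value
  inside (0, 1) instead of 0/1, keeping the outer log-transform finite.
  Monotonicity of PhenoAge in *xb* therefore holds up to float
  saturation (risk within one ulp of 1), which the tests respect by
  checking strictly below that point.

**BioAge (Klemera–Doubal BA_E).** With per-biomarker regression-on-age
parameters (q_j intercept, k_j slope, s_j residual SD),

BA = [Σ_j (x_j − q_j)·k_j/s_j² + age/s_BA²] / [Σ_j k_j²/s_j² + 1/s_BA²],

a precision-weighted average of the biomarker-implied ages
(x_j − q_j)/k_j and chronological age; s_BA defaults to 31.63 years. Two
exact identities follow from the algebra and are tested: biomarkers on
their age-expected profile (x_j = q_j + k_j·age) force BA = age, and
scaling every s_j and s_BA by a common factor leaves BA unchanged. The
published training values of (q_j, k_j, s_j) live in restricted
supplementary material, so `params/kdm_template.toml` ships clearly
labelled synthetic placeholders, and `kdm_params_from_sim` derives the
exact parameters implied by the synthetic generator (intercept plus half
the sex offset as q_j, age slope as k_j, noise SD as s_j) so the
synthetic pipeline is self-consistent.

**Age acceleration** is the OLS residual of a clock on (1, age), fitted
on complete pairs; residuals have mean zero and zero age-covariance by
construction.

## Biomarker preparation

Winsorization clips each biomarker to its 1st and 99th sample
percentiles. Percentiles use the inverted-CDF definition (Hyndman–Fan
type 1, an observed order statistic) computed over non-missing values.
This choice is deliberate: with interpolating percentile definitions the
re-computed 1st percentile of an already-clipped vector moves strictly
inside the clipped range, so winsorization would not be a fixed point;
with the inverted CDF the map is exactly idempotent and monotone, which
the property tests assert. Clip counts per tail are reported and logged.

## The synthetic cohort

The generator emulates the features the analysis relies on, with
defaults chosen once to resemble a mid-life population cohort:

- **Ages** uniform on [40, 70] (a recruitment-window shape, not a
  population pyramid); sex Bernoulli(1/2).
- **Genotypes**: each haplotype's allele indicator is a thresholded
  latent Gaussian; within an LD block (default 10 SNPs, ρ = 0.4) the
  latents share an equicorrelation, inducing LD while each SNP stays
  marginally Bernoulli(MAF) per haplotype and hence in exact HWE. MAFs
  are uniform on [0.05, 0.5] by default. Positions are laid out on
  chromosomes 1–22 at 500 kb spacing, each chromosome holding at least
  one full block.
- **APOE locus**: two chromosome-19 SNPs (rs429358 T/C at 45,411,941 and
  rs7412 C/T at 45,412,079, GRCh37) generated by random pairing of
  e2/e3/e4 haplotypes at frequencies (0.08, 0.77, 0.15).
- **Biomarkers**: value = intercept + age-slope·age + sex-offset·male +
  Σ effect·dosage + N(0, sd), with intercepts/slopes/SDs set to typical
  clinical values on the NHANES unit scales (e.g. albumin 50 g/L − 0.08
  per year, RDW 12.8% + 0.008 per year). CRP is given a small SD around
  a positive mean so the Gaussian model essentially never produces the
  non-positive values the log transform would reject. Default causal
  effects plant the APOE inversion (e4 allele: cholesterol +0.25 mmol/L,
  CRP −0.008 mg/dL per allele; e2 allele the opposite sign) and, in
  panels over 40 SNPs, two detectable non-APOE signals (RDW +0.12 and
  glucose +0.10 per allele).
- **Mortality**: death times by inverse transform of the Gompertz
  cumulative hazard H(t) = e^xb(e^γt − 1)/γ (t in months), with *xb* the
  PhenoAge linear predictor of the simulated biomarkers and γ the
  clock's own 0.0076927; censoring exactly at the 10-year follow-up
  horizon. γ ≤ 0 falls back to the exponential limit. This closes the
  loop: the clock's mean predicted 10-year risk must match the simulated
  death fraction up to Monte-Carlo error, which the acceptance suite
  checks at n = 20,000.

What the generator does *not* emulate: population structure and
relatedness, genotyping/imputation error (info scores are simulated as
1.0), skewed or heteroscedastic biomarker distributions, biomarker-
biomarker correlations beyond those induced by age, sex and shared SNPs,
and competing risks. Passing tests therefore demonstrate correctness of
the algorithms under the stated model, not robustness to those real-data
complications.

Each stage draws from its own RNG stream spawned from the master seed,
so any stage can be re-run reproducibly in isolation.

## Association scan

QC removes SNPs with imputation info < 0.3 (or missing, when the panel
claims info scores), minor-allele frequency < 0.001 (recomputed from
dosages as mean/2), or an exact HWE p-value below 0.05/m with m the
number of SNPs entering QC. The HWE test is the exact conditional test:
given the allele counts, the heterozygote count's distribution is
enumerated and the two-sided p sums all outcomes no more likely than the
observed one; genotype counts come from rounding dosages.

The scan is per-SNP OLS of a biological-age vector on dosage plus
covariates (age and sex by default — conditioning on age makes the
dosage coefficient an *acceleration* effect). A mixed model is
unnecessary because the generator produces unrelated individuals without
structure; this is the principal simplification relative to biobank
practice, where a linear mixed model absorbs relatedness. Missing
dosages are mean-imputed per SNP. The implementation residualizes
outcome and dosages against the covariates once (Frisch–Waugh), giving
coefficients identical to per-SNP full OLS (asserted against statsmodels
in the tests) at vectorized cost. Genome-wide significance uses 5×10⁻⁸;
the genomic inflation factor is the median association χ² over 0.4549.

Lead-SNP selection is greedy conditional pruning: promote the
smallest-p significant SNP, drop candidates within a 10,000 kb window
whose multiple-regression R² against the already-selected in-window
leads exceeds 0.9, repeat. SNPs farther apart are treated as
linkage-free. Ties in p break by (chromosome, bp), making the output
independent of input order. R² uses in-sample dosages (composite LD),
not phased haplotypes or an external reference panel.

## APOE

Haplotypes written as (rs429358, rs7412): e2 = (T,T), e3 = (T,C),
e4 = (C,C); the rare e1 = (C,T) is assumed absent. Of the nine unphased
genotype pairs, six map uniquely; the double heterozygote (TC, TC) is
called e2e4 — its only alternative explanation requires e1 — and the
three pairs explicable *only* via e1 return "ambiguous". Dosage inputs
are hard-called at 0.5/1.5 with calls within 0.1 of a threshold set
missing (uncertain imputations). Contrasts z-transform each outcome and
regress it on non-e3e3 group indicators plus covariates, so estimates
are mean SD-differences versus e3e3, reported with significance tiers at
0.05/0.01/0.001 and sorted by p within outcome.

## PRS and stratification

The cohort splits 1:2 into training and testing (train size =
round-half-up of n/3; n = 10 gives 3/7). Training summary statistics are
clumped greedily in p-ascending order at pairwise r² < 0.1 within a
250 kb window — the window is a configuration knob because the
literature's stated window sizes are inconsistent at the base-pair
scale, and 250 kb is the conventional choice. The p-threshold grid
search scores the testing set at each threshold and maximizes the
incremental R² of the biological-age outcome on the PRS beyond
covariates (nested OLS fits, hence non-negative); the default grid is 11
logarithmic points from 10⁻⁵ to 1 — a dense 50,001-point arithmetic grid
adds nothing at these panel sizes but is available via `full_grid`.
Quintile assignment sorts scores with a stable order (ties resolve by
input position, making groups invariant to monotone transforms); group
5 is the top 20%.

Outcome association contrasts quintile 5 vs 1 and 3 vs 1 with covariate
adjustment: z-scored OLS for continuous outcomes, logistic regression
(odds ratios; separation detected and the estimate withheld with a note)
for binary outcomes, and a parametric Gompertz proportional-hazards
maximum-likelihood fit for lifespan outcomes. The Gompertz family is
chosen over Cox partial likelihood because it matches the generator's
hazard exactly, making simulator→inference recovery checkable parameter
by parameter; the tests nevertheless cross-check its covariate
coefficient against a semiparametric Cox fit. The fitter maximizes the
censored Gompertz log-likelihood by BFGS followed by a Newton polish on
the analytic gradient and Hessian; standard errors come from the inverse
observed information; near γ = 0 the cumulative-hazard terms switch to
their series limits so the exponential model is reached continuously.
Benjamini–Hochberg FDR at 5% is applied across all contrasts of one
stratification run (the natural family for a single forest plot).

## Problem sizes

The acceptance checks run at the sizes their statistical tolerances are
stated for: n = 20,000 for closed-loop mortality calibration and
Gompertz recovery; 1,000 null SNPs × n = 2,000 for scan calibration
(99% binomial band around 0.05, λ ∈ [0.9, 1.1]); 100 replicates for
0.4-year effect recovery; 300 replicates for the odds-ratio coverage
check (the larger replicate count keeps the Monte-Carlo error of the
empirical coverage below one percentage point at the unchanged 93%
threshold); exhaustive enumeration to n = 50 for the HWE oracle; and 100
random 10–15-SNP instances each for the clumping and lead-selection
oracle equivalences.

## Known limitations

- The OLS scan is anti-conservative under population structure or
  relatedness; on real biobank data a mixed model should replace it.
- The PhenoAge coefficients are unit-locked; cohorts on other assay
  scales need external conversion before scoring.
- KDM parameters must be estimated on a training cohort; the shipped
  template is a placeholder, not a published parameter set.
- The Gompertz PH fit assumes the hazard family; for real survival data
  with non-Gompertz baselines the Cox route is preferable.
- Quintile stratification reports association, not calibration of
  absolute risk.
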