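# Methods

## Generative model

The synthetic cohort emulates the statistical structure a vitamin D MR study
in a mid-life European cohort would face. For individual *i*:

* **Genotypes.** Each SNP *j* is drawn independently as
  `G_ij ~ Binomial(2, maf_j)` (Hardy–Weinberg equilibrium, no linkage
  disequilibrium). When a regional gradient is configured for one SNP, its
  allele frequency follows a linear South → Scotland trend of total width
  `region_maf_shift` (default 0.05) across the four region levels, which are
  sampled with probabilities (0.30, 0.25, 0.30, 0.15).
* **Exposure.** `ln x_i = ln(gm_x) + Σ_j β_j (G_ij − 2·maf_j)
  + β_sex (sex_i − ½) + Σ_c γ_c (C_ic − p_c) + ε_i`, with
  `ε_i ~ N(0, σ²_resid)` scaled so `Var(ln x) = sd_lnx²` exactly in
  population; `x_i = exp(ln x_i)` (log-normal 25(OH)D). All contributions are
  mean-centered so the population geometric mean of x equals `gm_x`; the
  uncentered parameterization would shift the geometric mean by the mean
  genetic and covariate load, contradicting the `gm_x` contract.
* **Lifestyle factors.** Bernoulli with configured prevalence; a factor may
  optionally depend on a SNP's dosage on the log-odds scale
  (`snp_log_odds` per centered allele), which is how genotype–lifestyle
  confounding is injected for the screen tests.
* **Outcome.** A standardized variable combining the causal term
  `c·(x − E[x])/10` (c = `causal_effect_per10`), centered confounder effects,
  and Gaussian noise scaled to unit total variance, then mapped to
  `outcome_mean + outcome_sd·(·)`. The causal effect is therefore **linear in
  x on the outcome-SD scale**: the default c = −0.05 means 0.05 outcome-SD
  less blood pressure per 10 nmol/L more 25(OH)D. The statement "a 5%
  reduction per 10 nmol/L" is ambiguous between an SD-scale and a
  percent-of-mean effect; the SD-scale reading is the default and
  `causal_scale="percent_mean"` gives the alternative
  (c·outcome_mean/outcome_sd on the SD scale). With the default outcome
  (125 ± 15 mmHg), the SD-scale default corresponds to −0.75 mmHg per
  10 nmol/L.
* **Biomarkers.** Standardized loadings on standardized ln 25(OH)D
  (mediated paths) and/or directly on SNP dosages (pleiotropic paths), noise
  filled to the configured marginal variance.

Default parameters: geometric mean 25(OH)D 53 nmol/L; total ln-scale SD 0.48
(back-calibrated from the strongest instrument's variance fraction, see
below); sex effect −0.05 ln units; outcome 125 ± 15 mmHg (a typical mid-life
systolic blood pressure scale); five instrument SNPs — *GC* rs4588
(MAF 0.30, β −0.08), *DHCR7* rs12785878 (0.22, −0.05), *CYP2R1* rs10741657
(0.40, +0.03), *CYP24A1* rs6013897 (0.20, −0.03), *CYP27B1* rs10877012
(0.33, −0.02) — all per-minor-allele effects on ln 25(OH)D. These imply a
synthesis-score R² of 0.56% and a metabolism^GWA-score R² of 1.04% on
ln 25(OH)D, matching the observed instrument strengths.

`calibrate_sd_lnx` inverts `R²_j = β_j²·2·maf_j(1−maf_j)/sd_lnx²` for
`sd_lnx`; with several SNPs the least-squares compromise in `u = 1/sd_lnx²`
is used and inconsistent targets (e.g. rounded published fractions) trigger a
warning with per-SNP relative residuals rather than an error.

### What the generator does not emulate

No linkage disequilibrium (each SNP independent; proxy relationships between
tightly linked variants cannot be studied), no seasonal cycle in 25(OH)D, no
genotype missingness by default, no ascertainment or relatedness structure,
and confounders are mutually independent Bernoulli variables. Passing tests
therefore demonstrate correctness of the statistical machinery under the
assumed structure, not robustness to LD, seasonality or complex missingness
in real cohorts.

## Association and instrument strength

Per-SNP fits are OLS with additive coding; betas, SEs and Wald p-values come
from the sex-adjusted model while R² and the F-statistic come from the simple
(unadjusted) regression, the convention for first-stage strength reporting.
Dosages are re-oriented so betas always refer to the minor allele. Complete
cases are used per SNP and n is always reported. Instrument metrics:
`F = (n−2)R²/(1−R²)` (identical to the simple regression's F), weak-instrument
flag at F < 10, relative bias of IV vs OLS ≈ 100/F percent, reported to one
decimal and undefined below F = 1.9 where the approximation breaks down.

QC uses strict inequalities (HWE p > 0.01, MAF > 0.01, call rate > 0.80): a
SNP exactly at a boundary fails. HWE is a 1-df chi-square goodness-of-fit
test with the allele frequency estimated from the data. Selection carries
GWA-confirmed SNPs forward by default and admits others at
p < 0.05/(number of candidate genes); a rejected SNP with prior replication
evidence within twice the threshold is marked *borderline* rather than
excluded, reflecting how marginal but replicated candidates are handled in
practice. The factor of two is a pragmatic bound on "just above threshold",
configurable via `borderline_factor`.

## Allele scores

Scores count 25(OH)D-lowering alleles; a member whose minor allele raises
25(OH)D contributes `2 − G`. Orientation is fixed from the designated
lowering alleles, never re-estimated from the data at hand (avoiding
winner's-curse flips); individuals missing any member genotype are excluded.
Sparse categories are merged downward from the top while the topmost count is
below `collapse_min` (default 100, inferred from the merges a ~6,000-person
cohort requires); labels join the merged values as `"4, 5, 6"`. Per-category
summaries report geometric means `exp(mean(ln x))` with
`exp(mean ± 1.96·sd/√n)` CIs and ln-scale contrasts against the
zero-allele reference; the per-allele model treats the score as a single
linear term and reports the same instrument metrics as single SNPs.

## Screens

Lifestyle screens are logistic regressions of each binary factor on the
instrument, Bonferroni-corrected over however many factors are supplied
(0.05/14 for the default list, region dichotomized South/Middle vs
North/Scotland). Biomarker screens are linear regressions of each biomarker
on the instrument plus ln 25(OH)D (0.05/15 by default): adjustment for
ln 25(OH)D empties a purely mediated path but leaves a pleiotropic one
flagged. Sensitivity contrasts fit a single joint model per adjustment set
(not sequential single-covariate fits) and mark an association *attenuated*
when it is significant unadjusted (p < 0.05) but not adjusted.

## 2SLS and power

`tsls_fit` projects the design onto the instrument space and computes the
usual 2SLS coefficient with residuals taken against the observed exposure;
inference is asymptotic normal, with an optional HC0 sandwich. A first-stage
partial F below 10 attaches a warning but does not abort. With one instrument
and no covariates the estimate equals the Wald ratio cov(z,y)/cov(z,x); the
implementation is verified against an independent reference 2SLS in the test
suite to 1e-10.

Power at sample size n is the rejection rate of the 2SLS test over `reps`
freshly simulated cohorts (default 1,000; desk-scale runs use ≥ 200–500 and
are labelled accordingly). Scores enter the power models per-allele as a
single column; "both" uses the synthesis and metabolism scores as two
columns. SNPs a run does not use are dropped from the generative model before
simulating — their ln-scale contribution folds into the residual, leaving the
joint law of instrument, exposure and outcome unchanged — which makes large-n
runs substantially cheaper.

`sample_size_for_power` warm-starts at the analytic approximation
`n ≈ (z_{1−α/2} + z_{power})² (1 − ρ²) / (R²_zx · ρ²)`, where ρ is the
standardized exposure–outcome correlation implied by the causal slope and the
log-normal SD of x, and R²_zx is the instrument–exposure R² mapped from the
ln to the natural scale by the factor `σ²/(e^{σ²} − 1)` (the correlation
damping between a linear score and exp of a normal). Bisection then brackets
and refines. Stopping: bracket narrower than 2,000 individuals, or the
current point's 95% Monte-Carlo CI contains the target *and* the bracket is
within max(2,000, 15% of the midpoint) — without the bracket condition the CI
rule can fire on a midpoint far from the true crossing and inflate the
variance of the returned n several-fold.

Numerical notes:

* The 2SLS Wald test is conservative when the first stage is weak (the SE is
  computed from residuals against the observed exposure, which inflate when
  the estimate wanders): under a null causal effect, rejection runs at
  ~1–3% for first-stage F around 10–20 and reaches the nominal 5% once
  F ≳ 50. Calibration checks are therefore run at sample sizes where the
  instrument is strong.
* Monte-Carlo problem sizes used by the test suite and the acceptance script
  (500 replicates for the mean first-stage F at n = 6,027; 200 replicates of
  n = 5,856 for the per-allele score effect; 400–500 replicates per bisection
  point for sample-size runs; 2,000 replicates for type-I calibration) were
  chosen so each quantity's Monte-Carlo error is small against the tolerance
  it is compared at, while remaining desk-scale.
* All stochastic entry points take explicit integer seeds (or a
  `numpy.random.Generator`) and are bit-reproducible given them.

## Known limitations

Single-instrument weak-instrument-robust inference (e.g. LIML,
Anderson–Rubin) is out of scope, as are binary outcomes, weighted scores
(the score machinery is deliberately un-weighted), formal mediation analysis,
and pleiotropy estimators that require many instruments. The analytic
sample-size formula is a first-order approximation used only to seed the
search; reported sample sizes always come from the Monte-Carlo bisection.
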