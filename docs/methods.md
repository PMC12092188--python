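# Methods

## The association models

All dosages live on the copies scale: females in [0, 2], males in [0, 1]
on the non-pseudoautosomal X (PAR1 chrX:10,001–2,781,479 and PAR2
chrX:155,701,383–156,030,895 on GRCh38 are excluded at ingest; both
intervals are 1-based inclusive at interfaces and half-open internally).

**r-XCI.** Under random inactivation a heterozygous female expresses one
risk copy with probability ½, so a hemizygous male carrier is
statistically equivalent to a homozygous female. Coding males {0, 2} and
females {0, 1, 2} makes the additive logistic model linear in the expected
expressed dose. The coded genotypic variance is 4p(1−p) in males versus
2p(1−p) in females, so the model-based variance of the joint fit is
misspecified whenever case sampling differs by sex; the default variance
is therefore the HC0 Huber–White sandwich (bread⁻¹·Σ sᵢsᵢᵀ·bread⁻¹ with
score residuals; no small-sample correction — HC0 is the canonical choice
here, and its agreement with an explicit bread/meat product is unit-
tested). A sex-adjusted fit with model-based variance is the alternative;
it is also the correct model when allele frequencies differ between the
sexes, where the genotype is confounded with sex and *no* variance fix
helps (see calibration below).

**e-XCI.** Escape from inactivation means both female copies are
expressed: identity coding, effects estimated separately per sex (plain
model-based variance within a single sex) and pooled by fixed-effect IVW
across studies and sexes, or fitted jointly with a sex adjustment for
studies that cannot be stratified.

**s-XCI.** Skewed inactivation makes the heterozygous female effect land
anywhere between 0 and the homozygote effect. The female genotypic model
`logit P(case) = a + β_add·G + β_dom·1[G het]` is exactly saturated for
this family: with risk-copy activity probability s and real-scale log-OR
b, β_add = b/2 and β_dom = b(s − ½). The dominance χ² is added to the
additive χ² of the joint r-XCI fit, giving a 2-df statistic whose p-value
is exp(−χ²/2). Dominance evidence is pooled across studies by IVW on the
per-study dominance betas before squaring the pooled z — matching the
fixed-effect treatment of the additive part; a per-study χ²-sum variant is
available as `sxci_2df_study_sum`. On continuous (imputed) dosages the
heterozygote indicator uses the window [0.5, 1.5]; a hard-call mode
(round, then test == 1) is provided.

**Proxy correction.** A parental-history phenotype is linked to the
subject's genotype through one transmitted maternal X, which halves the
genotype–phenotype covariance; female-proxy effect sizes and standard
errors are multiplied by 2 (z and p unchanged), and re-application is an
error. Male proxies (mother's status only) are used uncorrected, and a
female-proxy study contributes its raw female proxy-case count divided by
four to the effective case total used by the coverage filter. In a
proxy study the male proxy-case count (if any) enters raw — the ÷4 rule is
defined for the female-proxy arm.

**Reporting scale.** Fitting and QC happen on the analysis codings;
odds ratios and CIs are converted to the real XCI scale (males {0, 1},
females {0, 0.5, 1} under r/s-XCI), i.e. OR = exp(2β); the e-XCI coding is
already on its real scale.

**Quantitative traits.** Biomarker-style analyses use OLS on the same
codings after a Blom rank-inverse-normal transform of the trait
(offset 0.375). The MAF floor is 1%, raised to 5% for batches under 250
samples; a variant below the floor is not fitted.

**Missingness** is handled by per-variant listwise deletion; p-values are
two-sided Wald throughout.

## Meta-analysis and QC

Fixed-effect IVW: weights 1/SE², Cochran's Q against χ²_{k−1},
I² = max(0, (Q − (k−1))/Q)·100; k = 1 defines Q = 0 with p_het withheld.
Effect alleles are harmonized to the first study (flips negate β and map
eaf → 1 − eaf); palindromic A/T, C/G variants with any study eaf in
[0.4, 0.6] are rejected as strand-ambiguous.

Filters use strict inequalities, so printed boundary values are kept, and
report the first failing rule. Pre-meta (per study): missing β/SE/p;
|β| > 5; imputation r² < 0.3; effective allele count — imputation quality ×
expected minor-allele count in the smaller of cases/controls, counting 2
copies per female and 1 per male — below 5 (10 for family designs); an
externally supplied build-conversion failure flag; reference-panel
frequency difference > 0.5. Post-meta: effective case coverage < 40%;
heterogeneity p < 5 × 10⁻⁸; cross-study frequency spread > 0.4. A missing
imputation quality is treated as 1 (hard genotypes) and skips the info
rule. Every threshold is a config field.

## Inflation and thresholds

λ is the median association χ² over eligible variants divided by
0.4549364231 (the χ²₁ median, fixed to 10 digits for bit-stability).
Eligibility: common variants (MAF above the 0.01 floor) surviving greedy
LD pruning at r² < 0.2 within a 500-variant window (window size is a
config field; no value is canonical). Pruning keeps the higher-MAF member
of a correlated pair, ties keep the smaller position; zero-variance
variants never enter the r² computation; the kept set is idempotent under
re-pruning. r² is the squared Pearson correlation on sex-pooled dosages.

The X-wide threshold is 0.05/(R·10⁶): the genome-wide 5 × 10⁻⁸ level
corresponds to one million independent tests, rescaled by the X-to-
autosome test ratio R; R = 3.12% gives 1.6 × 10⁻⁶. Bonferroni helpers
display at 3 significant figures.

## The synthetic-data generator

The generator emulates the statistical structure of a multi-study XWAS of
a late-onset dementia: sex-specific sample sizes, X-linked genotypes by
Hardy–Weinberg sampling (Binomial(2, p) females, Binomial(1, p) males;
random mating, no inbreeding), case status from a logistic liability on
the *expressed* dose (per XCI state: heterozygous females contribute ½
under random inactivation, the skew under skewed, their full genotype
under escape; males always their copy), optional sex effects and nuisance
covariates (uniform age 65–90, standard-normal PCs, APOE ε4/ε2 counts as
independent Binomial(2, 0.15)/(2, 0.08) — configurable; defaults reflect
European-ancestry frequencies). Per-study allele-frequency heterogeneity
follows the Balding–Nichols Beta parameterization with variance
F·p(1−p). Proxy phenotypes are generated structurally: each subject's
mother (diploid) and father (haploid) are simulated, one meiosis
transmits a maternal allele to every child plus the paternal X to
daughters, parents receive statuses from the same liability, and the
proxy label is "any parent affected" for daughters but "mother affected"
for sons. The attenuation that motivates the ×2 correction therefore
emerges from transmission rather than being imposed. Because no published
rate links parental status to non-disease misclassification, a
contamination fraction (unaffected parents labelled demented) is exposed
as a free parameter with default 0.

Imputation noise replaces the standardized dosage z by
√t·z + √(1−t)·ε rescaled to the original mean/variance and clipped to the
sex-valid range. Clipping truncates noise and would inflate the realized
r² above the target, so the mixing weight is calibrated by bisection
(20 iterations, tolerance 2 × 10⁻³) against the post-clip r², reusing a
single noise draw so the result stays a pure function of the seed; the
realized per-variant r² is re-estimated and reported. Noisy dosages are
quantized to float32 so they round-trip bit-exactly through VCF DS fields.
Zero-variance variants pass through unchanged with missing info.

What the generator does *not* emulate: linkage disequilibrium (variants
are independent, except duplicates injected for pruning tests),
haplotype-level imputation error (noise is marginal and Gaussian),
genotyping-batch artefacts, relatedness beyond the parent pair, and
ancestry-correlated covariate structure beyond an optional PC mean shift.
Passing tests therefore validate the statistical machinery under clean
sampling, not robustness to cryptic structure in real cohorts.

## Calibration and recovery experiments

`xwas.experiments` runs the replicate studies used for validation.

*Clean null* (no effect, shared MAF 0.2, prevalence logistic(−1),
n = 4000, 2000 replicates): the r-XCI robust test, the sex-adjusted e-XCI
test and the 2-df s-XCI test must all reject at 5% within the 99% binomial
band [0.0375, 0.0625].

*Variance heterogeneity* (equal MAF 0.4; 5% of females are cases vs 50%
of males, n = 4000): the coded male genotypic variance is double the
female one and co-varies with the residual variance, so the model-based
("plain") joint r-XCI test is anticonservative while the sandwich and the
sex adjustment stay in the band. The 5%/50% split was chosen to make the
mechanism visible at n = 4000; milder imbalance shrinks the effect
smoothly.

*Sex-differential MAF* (0.25 female / 0.35 male, with a sex effect of 0.4
log-odds): the genotype is now confounded with sex, which biases the
point estimate itself; both the plain and the robust test inflate, and
only the sex-adjusted model stays calibrated. This is the scenario in
which a robust-variance r-XCI scan produces false positives and a
sex-adjusted sensitivity analysis is the appropriate check — the sandwich
fixes variance misspecification, never confounding.

*Recovery* (real OR 1.3, MAF 0.25, n = 20,000, 500 replicates per state):
each generative inactivation state analysed with its matched model
(random → joint robust r-XCI; skewed 0.75 → female genotypic model,
additive part; escape → sex-adjusted identity coding) must recover the
real-scale log-OR within 3 Monte-Carlo SEs with 95% CI coverage inside
[0.93, 0.97].

`scripts/acceptance.py` re-runs these experiments at 1000/600/300
replicates (sizes chosen so the whole script is a few minutes on one CPU;
the test suite uses the full sizes above) plus λ on a two-study null
portfolio of 150 variants, all seeded from `--seed`.

## Numerical choices and conventions

- Logistic fits: statsmodels GLM/Binomial IRLS, tolerance 1e-8, max 25
  iterations; non-convergence, quasi-complete separation (detected via
  perfectly separated fitted probabilities with |η| > 15, plus the
  upstream separation error) and rank deficiency (reported with the
  collinear column names) abort the variant with no statistics emitted.
- Effect-allele convention: statistics refer to the designated effect
  allele; flipping negates β and maps eaf → 1 − eaf. Frequencies count 2
  copies per female, 1 per male.
- Coordinates are 1-based inclusive in all user-facing files. Male VCF
  records may be haploid GT, diploid-homozygous GT, or DS in [0, 1];
  diploid-coded male dosages in (1, 2] are halved with a warning, and
  heterozygous male hard calls become missing (counted in the log).
- Summary-statistics p-values are serialized in shortest-unique scientific
  notation with at least 6 significant digits; p below the float64 floor
  is reported as 0 with the log10 p carried in an auxiliary column
  (always emitted, computed from the z statistic).
- Pipeline runs are deterministic given config and inputs; per-variant
  errors are logged with study/variant context and the run continues.

## Known limitations

- No GEE family models or mixed models for biobank-scale relatedness;
  externally fitted β/SE can still enter the meta-analysis via the
  summary-statistics reader.
- No genotype imputation, array QC, or coordinate liftover (liftover
  failures enter as a flag).
- The ×2 proxy correction is derived for common variants with modest
  effects; for rare, large-effect variants the transmission argument is
  first-order only, and the generator can be used to quantify the
  residual bias.
- LD pruning is greedy and window-limited, appropriate for the
  weakly-correlated panels produced by the generator, not a replacement
  for reference-panel pruning on real data.
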