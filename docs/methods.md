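# Methods

## Generative model

The simulator reproduces the structure that makes case-only genetic
association studies biased, with every parameter known.

**Liability and onset.**  Individual liability is

    L = Σⱼ βⱼ (gⱼ − 2fⱼ) + U + γ_age(age − 54.5) + γ_sex(sex − 0.5)
        + γ_bmi(BMI − 27) + γ_smk(smk − 0.45) + ε,      ε ~ N(0, 1)

with dosages gⱼ ~ Binomial(2, fⱼ) and a prevalent case declared when
`L > T` (probit/liability-threshold model; a logistic switch is provided).
Centering every term makes the threshold interpretable: the predicted
prevalence is `Φ(−T/σ_L)` with `σ_L²` the sum of component variances, and
`T` is placed by default at the quantile giving prevalence 0.045.  With the
default survival selection this leaves ≈5 000 recruited cases out of
200 000 — a deliberate scale-down of a large-biobank two-subsample design
(≈10 000 prevalent cases against ≈400 000 disease-free).

**Shared factor.**  `U ~ N(0, 0.5)` enters the liability with unit
coefficient and the prognosis logit with coefficient 1.2.  It is never
observed by any analysis step; it is what makes case status a collider
between the genetic score and prognosis.

**Recruitment.**  Cases enter the study with probability
`expit(logit(0.8) − 0.5·L/σ_L)`: higher-liability cases are more likely to
have died before enrolment.  This is the second bias channel; disease-free
individuals are recruited with probability 1.

**Prognosis and follow-up onset.**  A fixed-horizon binary death outcome is
generated for every recruited individual from
`logit p = logit(0.20) + Σⱼ βⱼᵖʳᵒᵍ(gⱼ − 2fⱼ) + 1.2·U + covariate terms`;
among cases this is the case-only prognosis outcome, and the acceptance
scenarios set all direct genetic effects βᵖʳᵒᵍ = 0 so any estimated
genetic association among cases is pure bias.  Disease-free individuals
additionally receive a follow-up onset outcome driven by the same liability
(`logit p = logit(0.05) + 0.6·L`), so the disease-free stratum has a
positive-control outcome whose per-SD odds ratio (~1.3) is in the range
published onset PRS effects occupy.

Death is simulated in **both** strata (for non-cases it reads as follow-up
mortality) so that the same outcome can be compared across strata by the
heterogeneity test; the case-only GWAS and all case-only estimates still
use only recruited cases.

**Defaults and their rationale** (per-SNP quantities drawn once per seed):

| parameter | default | why |
|---|---|---|
| n_individuals / n_snps | 200 000 / 100 | scaled-down biobank; enough SNPs for slope regression |
| allele frequencies | U(0.1, 0.9) | common variants, as in a pruned GWAS panel |
| Σⱼβⱼ²·2fⱼ(1−fⱼ) | 0.30 | genetic share ~16% of liability variance |
| var(U) / prognosis effect | 0.50 / 1.2 | collider strong enough to detect at 5 000 cases |
| survival coefficient | 0.5 per SD L | visible depletion of high-risk cases |
| prevalence / death rate | 0.045 / 0.20 | ≈5 000 recruited cases; well-conditioned logistic fits |
| external GWAS | 15 000/15 000 | incidence SEs small relative to the spread of true effects (I²_GX ≈ 99%) |
| age | U(40, 69) years | the biobank recruitment window |

**LD** is optional and block-structured: per-haplotype latent Gaussians
with AR(1) correlation ρ inside blocks, thresholded at the allele-frequency
quantile.  This induces positive adjacent-SNP dosage correlation decaying
with distance — enough to exercise clumping and pruning without a
coalescent simulator.  No imputation-quality heterogeneity is simulated
(INFO ≡ 1.0), no principal-component structure (the prognosis GWAS adjusts
for age and sex instead of ancestry components — a documented
simplification), and outcomes are fixed-horizon binaries, not
time-to-event.

## Per-SNP GWAS fits

Both GWAS emulators fit one logistic model per SNP
(`outcome ~ dosage + age + sex`) by a Newton solver vectorized across SNPs;
the test suite pins its estimates to statsmodels' generic ML fit at 1e-6
(they agree to ~1e-12 on non-degenerate data).  Monomorphic SNPs are
dropped with a warning; fits that diverge (|log-OR| > 15, separation) are
flagged and excluded downstream.

## Summary-statistics layer

Harmonization intersects on variant id and aligns the second table to the
first table's effect allele, negating betas and complementing frequencies
on swapped alleles and resolving strand flips by complementation.
Palindromic (A/T, G/C) variants are oriented by frequency agreement when
the effect-allele frequency is outside [0.4, 0.6] on both sides, and
dropped otherwise — the common harmonization convention.

Clumping is greedy by ascending P (ties broken by position): a variant is
kept iff r² < r²max with every kept variant within ±window on the same
chromosome.  Pruning is P-agnostic; the dropped member of a violating pair
is always the later-position one, and the procedure is run to its fixed
point, which equals the left-to-right rule "keep a variant iff no earlier
*surviving* variant within the window is in LD with it".  This fixed point
is canonical (independent of window stride); the step-size argument is
kept for interface familiarity only.  Variants absent from the LD
reference are treated as independent with a warning, because refusing them
would empty synthetic runs that use sparse panels.  Window endpoints are
inclusive and positions 1-based.

## Scoring

Weights are the per-allele log-odds of the thresholded, clumped incidence
records.  Scores are raw weighted allele counts (so the worked arithmetic
is transparent); missing dosages are imputed with 2·EAF when the model
carries a frequency, else the column mean.  Standardization divides by the
pooled (unstratified) sample SD with the n−1 denominator, so case and
disease-free effect estimates share the same "per SD" unit; per-stratum
rescaling is deliberately rejected.  Flipping a model entry's effect
allele and negating its weight shifts every raw score by the constant −2w,
so orientation invariance holds exactly for centered/standardized scores —
the form every downstream analysis consumes.

## Stratified estimates and heterogeneity

Logistic fits use statsmodels maximum likelihood with Wald standard
errors; the heterogeneity test is the standard two-sample comparison of
independent estimates on the log-odds scale,
`z = (b₁ − b₂)/√(se₁² + se₂²)`, two-sided normal P.  No multiple-testing
correction is applied across outcomes (raw P-values are reported, as is
conventional in the analyses this mirrors).  Covariate profiles at score
quintiles (20/40/60/80%) are linear-model predictions at the empirical
score quantiles with adjustment covariates held at their means; binary
covariates use the same linear presentation, which is why a strongly
associated, highly prevalent covariate can show a top-quintile prediction
above 1.0.  Raw quantile-bin means are available behind a flag.

## Bias slope, I²_GX, adjustment, IVW

The naive slope is unweighted least squares of β₂ on β₁ with an intercept
(absorbing directional pleiotropy; a `--no-intercept` switch exists).
Because β₁ is estimated, the naive slope is attenuated by the reliability
ratio var(β₁)/(var(β₁) + mean(se₁²)); Hedges-Olkin removes the
measurement-error variance from the denominator, with a leave-one-out
jackknife SE (assumption-light; no closed form is standard for this
estimator).  SIMEX averages the naive slope over replicates with inflating
noise λ·se₁ⱼ² at λ ∈ {0, 0.5, 1, 1.5, 2} and extrapolates a quadratic to
λ = −1; since the extrapolated value is linear in the per-λ means, their
Monte-Carlo variances propagate exactly into the reported SE, and per-λ
replicate variances are exposed as the convergence diagnostic.  Restricting
the slope set to SNPs nominally associated with incidence (P < 0.05) is
supported natively as the standard remedy when noisy SNP sets prevent
SIMEX convergence.

I²_GX = max(0, (Q − (k − 1))/Q) with Q the inverse-variance-weighted
heterogeneity of the incidence effects; values near 1 mean the incidence
effects are nearly noise-free and slope attenuation is minor.

Adjustment subtracts b·β₁ⱼ from each prognosis beta and widens its SE to
√(se₂ⱼ² + b²·se₁ⱼ²).  Slope-estimation uncertainty is **not** propagated
by default (matching the per-SNP adjustment rule); an optional
var(b)·β₁ⱼ² term can be enabled, and the end-to-end coverage study enables
it because at a few hundred SNPs the slope error is not negligible
relative to the IVW SE.

The IVW estimator is fixed-effect: weighted regression of β₂ on β₁ through
the origin with weights 1/se₂ⱼ² and SE 1/√(Σwⱼβ₁ⱼ²) (dispersion fixed at
1).  The instrument list is a distinct, stricter SNP set
(genome-wide-significant, LD-clumped) than the slope-estimation set, and
both lists are explicit configuration inputs, never inferred inside the
estimator.  After correction the default IVW weights use the adjusted SEs;
an unadjusted-weight mode is provided in which the algebraic identity
`corrected β_IVW = raw β_IVW − b` holds exactly and is tested.

## Reproducibility

One master seed is expanded into per-stage child seeds by hashing the
stage name (CRC-32) into a numpy `SeedSequence` alongside the seed, so any
stage can be re-run in isolation and two runs of the same configuration
are bit-identical.  Configurations round-trip through YAML losslessly.
Stage boundaries log records in/out for every filter.

## Problem sizes used by the tests

Unit tests run on a 2 000-person, 50-SNP fixture bundle with exaggerated
bias parameters (so the collider sign is visible at fixture scale).  The
acceptance suite uses: 2 000 replicates (n = 400 per stratum) for
heterogeneity type-I error; 200 seeds of a 6 000-person null scenario for
P-uniformity; 500 replicates of 500 SNP pairs for slope recovery; one full
200 000-person run for the stratified sign structure; 20 seeds at 60 000
for the slope sign; and 200 replicates at 25 000 (≈2 000 recruited cases,
100 SNPs, 12 instruments) for post-correction coverage of the null.  These
sizes were chosen so each check's Monte-Carlo error is small relative to
the effect it verifies.

## Known limitations

* No real LD panels, no imputation-INFO heterogeneity, no multi-allelic
  variants, no VCF/liftover support.
* Binary fixed-horizon outcomes only; no competing risks or Cox models.
* The correction assumes direct genetic effects on incidence and prognosis
  are independent; when they are correlated (shared biological pathways)
  the adjusted estimates inherit that violation — an intrinsic property of
  the method, visible here by simulating correlated direct effects.
* Passing tests on synthetic data show the machinery is correct and
  calibrated under the stated generative model; they do not certify
  behaviour under real-data pathologies the generator omits (population
  structure, cryptic relatedness, phenotype misclassification).
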