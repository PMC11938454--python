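# Methods

This note documents the statistical models implemented in `brainpath`,
the defaults and why they were chosen, what the synthetic cohorts do and
do not emulate, and the numerical choices that affect results.

## Study designs emulated

Two cohort styles are supported, mirroring the two kinds of datasets this
analysis is run on in practice:

- **proxy** (population-biobank style): no clinical diagnosis; the outcome
  is a continuous family-history proxy score; assessment site is a
  covariate (fixed-effect indicators).
- **case_control** (clinical-cohort style): binary diagnosis; site is
  omitted (many small sites make site indicators unstable, and
  standardized acquisition limits site effects).

## Phenotype derivation

**APOE ε4 coding.** The haplotype at (rs429358, rs7412) defines the APOE
allele: ε1 = (C,T), ε2 = (T,T), ε3 = (T,C), ε4 = (C,C). From two unphased
site genotypes the coder enumerates all consistent haplotype pairs and
counts ε4. The only ambiguous configuration is the double heterozygote
(C/T at both sites), consistent with ε2/ε4 and ε1/ε3; since ε1 has
negligible frequency in European-ancestry populations the call is resolved
to ε2/ε4 (count 1) and flagged `ambiguous`. Missing genotypes at either
site yield a missing call, and the participant drops out of APOE models
only (model-specific listwise deletion throughout the package).

**Proxy score.** Each affected parent contributes 1; each unaffected
parent contributes the age weight (100 − age)/100, floored at 0 (ages
above 100 would otherwise go negative) and capped at 0.32, the maximum
population prevalence of the disease in the oldest age bands. Affected
parents contribute 1 regardless of age — the score is designed to reflect
the *number* of affected parents. Participants with no available parental
information raise an exclusion signal rather than receiving a score.

**Brain measures.** Left/right values are summed for surface area and
volume and averaged for thickness. Total surface area is the sum of the
34 cortical areas; global mean thickness is the surface-area-weighted mean
of the 34 cortical thicknesses (a convex combination, so it always lies
between the regional extremes). All measures, including the globals, are
z-scored within the analysis cohort with the sample SD (n − 1); the
standardization population is the cohort after exclusions, since no
external reference is available.

**Genotype QC.** Variants fail when missingness exceeds 10% or the
Hardy–Weinberg 1-df chi-square test (expected counts from the sample
allele frequency) gives p below 1e−9. The chi-square rather than the
exact test matches large-cohort practice; monomorphic variants get p = 1
(no test possible) and a `monomorphic` flag.

## Mediation analysis

Each variant × measure model adjusts for age and sex, site indicators when
the design includes site, and one global brain measure matched to the
mediator's type: total surface area for areas, global mean thickness for
thicknesses, intracranial volume for volumes — correcting regional
effects for overall brain size. Dosage is numeric 0/1/2 (additive
coding), including the ε4 allele count.

The indirect effect is estimated inside the potential-outcomes framework:

- **linear outcome** — product of coefficients a·b, which for nested
  least-squares fits sharing covariates satisfies c = c′ + a·b exactly
  (Frisch–Waugh); the package asserts this identity to 1e−8.
- **logistic outcome** — ACME on the risk-difference scale by
  g-computation: for each participant, with covariates fixed and the
  direct path held at the observed dosage d, the model-predicted outcome
  probability is evaluated with the mediator at its predicted mean under
  d and under d + 1; the ACME is the mean difference. Logit rather than
  probit is used for the binary outcome.

Inference is a nonparametric bootstrap over participants (default 5000
resamples; recovery studies use 500, unit tests less): each resample
refits both models and records the indirect effect; the CI is the 2.5/97.5
percentile interval (BCa offers little at these n) and the two-sided
p-value is 2·min(P(draws ≤ 0), P(draws ≥ 0)). Resampling failures
(singular or separated refits) are tolerated up to 20% of draws, beyond
which the model carries an error state. `bootstrap_reps=0` switches to an
analytic screening mode (point estimates plus a Sobel-type normal
p-value), used where thousands of grid cells must be fitted quickly.

Grid significance uses Benjamini–Hochberg step-up with the Li–Ji
effective number of tests in place of the raw count: per ascending rank i
the threshold is i·q/Meff, and the per-test threshold is reported with
each model. Meff is computed globally for the grid by applying the Li–Ji
eigenvalue rule to the Kronecker product of the measure-correlation and
dosage-correlation matrices (its eigenvalues are the pairwise products),
since both the mediators and the variants are correlated families of
tests.

Because the proxy score is bounded and non-normal, the package includes a
type-I-error harness: under a null generator (genotype with zero effect on
a proxy-shaped outcome) the path-c linear test is run repeatedly and the
rejection rate compared to a 99% binomial band around the nominal level.
The shipped study uses 5000 replicates of n = 500 participants; it
confirms that ordinary linear regression keeps its size under this
outcome, at both α = 0.05 and 0.01.

## Meta-analysis

Cohort-level mediation estimates are pooled with fixed-effect
inverse-variance weights; with only two cohorts a heterogeneity variance
cannot be usefully estimated, so no random-effects option is provided.
Each cohort's SE is recovered from its bootstrap CI width as
(hi − lo)/(2·z₍₁₊L₎⁄₂); degenerate (zero-width) intervals propagate an
error row rather than an infinite weight.

## Mendelian randomization

One-sample design: exposure and outcome associations are estimated in the
same participants, one single-variant regression per panel member with the
mediation covariates. For the reverse direction with a binary disease
outcome the exposure associations are logistic coefficients, so the
reverse causal estimate is per log-odds of disease; the scale is recorded
in the output.

Estimators (exposure orientation normalized so every β̂ₓ ≥ 0 where it
matters):

- **IVW**: weighted regression of β̂ᵧ on β̂ₓ through the origin with
  weights 1/se(β̂ᵧ)²; fixed-effect SE (no multiplicative inflation), with
  Cochran's Q reported so heterogeneity can be judged directly.
- **Weighted median**: the Wald ratios sorted, the estimate interpolated
  where the cumulative standardized weight sⱼ = Σᵢ≤ⱼwᵢ − wⱼ/2 crosses ½;
  SE by a 200-draw parametric bootstrap of the summary statistics.
- **MR-Egger**: weighted regression with a free intercept (the
  directional-pleiotropy test); the residual variance is floored at 1, the
  standard summary-data convention that never deflates below the
  fixed-effect model. With the intercept constrained to zero the slope is
  algebraically identical to IVW — kept as a cross-check.

Diagnostics: Cochran's Q (chi-square, k − 1 df), leave-one-out IVW
re-estimates, and I²_GX = max(0, (Q_GX − (k−1))/Q_GX) from the
inverse-variance-weighted dispersion of the exposure associations; values
below 0.80 set a weak-instrument flag indicating the Egger estimate
suffers regression dilution (no SIMEX correction is attempted — the flag
is reported instead). P-values are BH-adjusted at q = 0.05 across
measures within each direction × method stratum.

## Synthetic cohorts

The generator draws genotypes from Hardy–Weinberg proportions at the
specified allele frequencies (no linkage disequilibrium between the
non-APOE SNPs — a stated non-goal), APOE genotypes from two independent
haplotype draws (default frequencies ε2/ε3/ε4 = 0.08/0.77/0.15; ε1
omitted as negligible, though the coder handles it), ages from a Gaussian
truncated to [40, 100] (default mean 64.4, SD 7.7), sex at a 0.477 male
fraction, and three assessment sites.

Regional measures follow the linear mediator model on the standardized
scale — Σ βᵥ·dosage + N(0, 1) by default — and are emitted as raw-unit
left/right columns whose recombination reproduces the latent standardized
measure exactly. The default variant panel plants mediator effects of the
magnitudes observed for medial-temporal structures in case-control data
(e.g. −0.424 SD of hippocampal volume per ε4 allele) on ε4 and two named
risk SNPs, with eight null SNPs alongside.

Binary outcomes are Bernoulli with logistic probability in the direct
genetic effects plus the path-b mediator terms. Proxy outcomes simulate
two parental records per participant: each parent's affection probability
is logistic in the participant's own liability scaled by the 0.5
parent–offspring transmission share — parental genotypes are not
simulated explicitly, which is simpler and sufficient to create a nonzero
total path. Parental ages are Gaussian (mean 78, SD 9) truncated to
[40, 100], and the affection intercept (logit 0.16) was chosen once so
the resulting proxy score has mean ≈ 0.66 and SD ≈ 0.41; the exact shape
of the score's (non-normal) distribution is otherwise unconstrained.
Missingness, when requested, is missing-completely-at-random; model-wise
exclusions downstream emulate per-SNP exclusion patterns.

What the generator does *not* emulate — and what passing recovery tests
therefore cannot certify about real data: LD structure and population
stratification, imputation uncertainty, scanner/site effects beyond an
exchangeable site label, non-linear covariate effects, measurement error
in the regional segmentation, and recall bias in family history.

## Numerical choices and problem sizes

- OLS is solved via the normal equations after a pivoted-QR rank check
  that names collinear columns; classical (homoskedastic) SEs, t-based
  p-values. Logistic fits use IRLS (statsmodels GLM) with a
  quasi-separation guard (|coef| > 50 or SE > 1e3 flags the fit).
- Site indicator levels are sorted before dummy coding, making results
  invariant to row order and level labels.
- Bootstrap and simulation seeds all flow through
  `numpy.random.default_rng`; a fixed seed reproduces cohorts and CIs bit
  for bit. Grid cells get deterministic per-cell substreams.
- Default study sizes: recovery simulations use n = 5000 (path a) and
  n = 10,000 with 500 resamples (ACME); the type-I study uses 5000
  replicates of n = 500; the CI-coverage study uses 300 datasets of
  n = 1000 with 300 resamples. These sizes put Monte-Carlo error
  comfortably inside the tolerances the studies are judged against while
  keeping each study in the seconds-to-minutes range.

## Known limitations

- No exposure–mediator interaction terms and no sensitivity analysis for
  sequential ignorability; the mediation estimates carry the usual
  no-unmeasured-confounding assumptions.
- No multilevel site models; site is fixed-effect or absent.
- The weighted-median SE is a parametric bootstrap, slightly optimistic
  when instruments are weak.
- One-sample MR is vulnerable to winner's curse and weak-instrument bias
  toward the confounded association; the I²_GX flag and leave-one-out
  table surface, but do not correct, these problems.
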