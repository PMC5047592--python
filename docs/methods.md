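# Methods

## The testing problem

Given a binary trait measured on a sample that mixes unrelated individuals
with members of known pedigrees, we test each biallelic variant for
association while (i) adjusting for covariates on the logistic scale,
(ii) accounting for familial correlation through an additive polygenic
variance component, and (iii) using individuals with partially missing data
(most importantly, phenotyped individuals whose genotype is missing but who
have genotyped relatives).

## Phenotypic null model

Only the first two conditional moments of the phenotype are specified
(a quasi-likelihood model, not a full likelihood):

    E(Y_i | X)  = mu_i,          logit(mu_i) = X_i' beta
    Var(Y | X)  = Gamma^{1/2} (xi * Phi + (1 - xi) * I) Gamma^{1/2}

with `Gamma = diag(mu_i (1 - mu_i))` and `Phi` the pedigree kinship matrix
(off-diagonal `2*phi_ij`, diagonal `1 + h_i`).  The sandwich form keeps the
Bernoulli mean-variance relationship exact for outbred individuals while
`xi in [0, 1]` interpolates between independence and fully kinship-
structured standardized covariance.  `beta` solves the quasi-score equation
`X' Gamma^{1/2} Sigma^{-1} Gamma^{-1/2} (Y - mu) = 0` and `xi` a method-of-
moments equation matching the kinship-weighted quadratic form of the
standardized residuals to its expectation.  The fit alternates damped
quasi-Fisher scoring in `beta` (solved in a column-scaled basis so the
convergence tolerance, 1e-11 on the max score component, is unit-free) with
bracketed scalar root finding for `xi` on [0, 1]; when the moment equation
has no interior root the boundary with the smaller absolute gap is used.
Outer alternation stops when no parameter moves by more than 1e-6 (at most
100 outer rounds); fitted means are clamped to [1e-10, 1 - 1e-10] before
forming `Gamma^{+/-1/2}`.  Initialization is the ordinary logistic fit
(`Sigma = I`).  The phenotype subset must contain both cases and controls.

All `Sigma^{-1}` products use one spectral decomposition `Phi = A J A'` per
family block; blocks are zero-padded to a common size (the padding is an
identity block whose unit eigenvalues are inert) so every solve is a pair
of batched matrix products, and unrelated singletons are handled as a
diagonal.  This is what makes replicate-heavy studies and genome scans
cheap without restricting pedigree structure.

## Retrospective test

Significance is assessed under the null conditional distribution of the
genotype given phenotype and covariates:

    E0(G | Y, X) = X alpha,      Var0(G | Y, X) = sigma_G^2 * Phi.

Because only genotype moments matter, the level of the test survives
misspecification of the phenotype model (wrong covariates, wrong link,
ascertainment).  `sigma_G^2` is estimated robustly as the mean squared
residual of the GLS regression of `G` on `X` with covariance proportional
to `Phi`, computed on the set `Q` of genotyped individuals with complete
covariates; no Hardy-Weinberg assumption (`sigma_G^2 = 2p(1-p)`) is made.

With complete data the statistic is `(Z'G)^2 / (sigma_G^2 * Z' Phi Z)`
with `Z = Gamma^{1/2} Sigma^{-1} Gamma^{-1/2} (Y - mu)` the transformed
null residuals, referred to a chi-square with 1 df.  With partially
missing data, residuals live on the set `W` (complete phenotype and
covariates) and genotypes on `R`; the statistic contracts the two through
`F = M Phi_RW Z_W`, where `M` is the `Phi_R^{-1}`-weighted centering
projection.  This is algebraically identical to scoring the BLUP-imputed
genotype vector `G_hat_W = 1 p_hat + Phi_WR Phi_R^{-1} (G_R - 1 p_hat)`
against its retrospective variance — BLUP imputation with the imputation
error and the imputation-induced correlation priced in exactly — and it
reduces to the complete-data statistic when nothing is missing.  `p_hat`
is the kinship-weighted GLS mean of the observed genotypes (the best
linear unbiased estimator on the 0/1/2 scale, i.e. of twice the allele
frequency; reports halve it).

Ungenotyped individuals are used only when they can contribute: they need
complete phenotype and covariates plus either a genotyped relative
(`2*phi > 0`) or a family member with complete phenotype/covariates who is
genotyped or has a genotyped relative.  Everyone else is dropped from the
variant's analysis.  Genotyped individuals with missing phenotype (e.g.
unscreened population controls) still inform the allele frequency and the
genotypic variance.  One point the interface makes explicit: such
individuals do shift the statistic — that is why they are worth genotyping
— so removing them is not a no-op, and the variance of the BLUP score is
monotone nondecreasing as more relatives are genotyped.

The MQLS-LOG and MQLS-LIN variants replace `Z_W` with residuals from
ordinary logistic regression and from OLS, respectively; they share the
missing-data machinery but fit no variance component.

For genome scans the variance component is estimated once per genome on
all individuals with complete phenotype/covariates, and only `beta` (hence
`Z_W`) is re-solved per variant; per-variant `xi` refits, a fixed-`xi`
mode, and a fixed-`Z` mode (one residual vector for the whole scan, with
the fixed complete-data subset standing in for every variant's `W`) are
available.  Partitions and null fits are memoized by the
variant's missingness pattern, which repeats heavily in practice.
Per-variant failures (monomorphic variants, no informative individuals,
non-convergence) become flagged output rows, never scan aborts.  The scan
reports the genomic-control inflation factor `lambda_GC =
median(statistic) / 0.4549` as a diagnostic only; p-values are never
rescaled by it.

Full-parameter estimation (effect size `gamma` with standard error) solves
the three-equation system with design `(G, X)`; the covariance is the
inverse quasi-information `(Xt' Gamma^{1/2} Sigma^{-1} Gamma^{1/2} Xt)^{-1}`.
No standard error is reported for `xi`: that would require third- and
fourth-moment assumptions the model deliberately avoids.  With missing
data, estimation (unlike testing) restricts the BLUP-completed genotypes
to ungenotyped individuals with a genotyped first-degree relative, because
low-information imputations dilute the effect estimate toward zero.

## Synthetic-data generator

The generator is the package's study design, not a test fixture: its
defaults are the conditions under which the operating characteristics are
quoted.

**Structure.** Samples combine 16-person three-generation families (two
grandparent couples, each with one child who marries a married-in founder;
each second-generation couple has four children; generation sizes 4/4/8,
six founders, fixed alternating sexes) with unrelated singletons.  The two
grandparental branches share no ancestor, so the two sibships are
unrelated — a deliberate feature that exercises within-family unrelated
pairs.  Default sample: 60 families + 240 unrelateds (n = 1,200).

**Covariates.** Age is uniform on {78..88}/{48..58}/{18..28} by generation
(unrelateds are assigned generations 50/25/25); sex is fixed within
families and balanced among unrelateds (coded male = 1, female = 2);
height is multivariate normal around a sex-and-age mean (176.5/172.5 male
under/over 65, 163.2/160.2 female) with covariance `36 * Phi + 13 * I`
(narrow-sense heritability 36/49 ~ 73%); plus an independent N(8, 9)
covariate.  The coefficient vector puts equal loadings on the standardized
covariates, centered and scaled by Monte Carlo (1e6 draws at a fixed
calibration seed) so that `E(X'beta) = 0` and `Var(X'beta)` hits its
target within 1%.

**Traits.** Two causal SNPs (MAFs .1 and .2, unlinked, gene-dropped
through pedigrees with founders at Hardy-Weinberg) act epistatically:
carrying at least one minor allele at each sets the high-penetrance state.
The mixed-effects logistic model draws `Y_i ~ Bernoulli(expit(f(G_i) +
X_i'beta + u_i))` with `u ~ MVN(0, sigma_a^2 Phi)` and `Var(X'beta) +
sigma_a^2 = 100` (split by `theta_a`); the liability threshold model sets
`Y_i = 1{X_i'beta + u_i + eps_i >= lambda(G_i)}` with total liability
variance 100, error variance 20, and `pi_a + pi_c = .8`.  Offsets
`f1/f0` (logistic, solved by bracketed root finding on the Monte-Carlo
mean penetrance) and thresholds `lambda1/lambda0` (Monte-Carlo quantiles)
are calibrated to mean penetrances .15 (carriers) and .05 (others),
implying population prevalence `.19*.36*.15 + (1-.19*.36)*.05 ~ .057`.
Calibration uses the unrelated-individual covariate distribution; the
family age mix differs slightly (25/25/50 by generation), which perturbs
realized penetrances negligibly.  Variants: a sibship shared-environment
effect at 10% of liability variance (error reduced to 10%), and a
low-prevalence variant that rescales both penetrance targets by a common
factor (preserving their 3:1 ratio) so prevalence is .01.

**Ascertainment and missingness.** Families are rejection-sampled until
each contains at least four affected members (setting A samples unrelateds
at random; setting B forces an exact 1:1 case-control ratio among them).
Within families, phenotype and covariates are jointly missing with
probability .2; a genotype is observed iff the member is phenotyped and
affected, or at least half of their phenotyped first-degree relatives are
affected (vacuously false when none are phenotyped).  Unrelateds are
genotype-only: all phenotypes/covariates missing.  Acceptance rates are
low (~1-5% of drawn families), so ascertainment draws in adaptively sized
vectorized batches.

**What the generator does not emulate.** Linkage disequilibrium between
markers, population stratification, genotyping error, and real pedigree
variety (every family shares one topology).  Passing studies therefore
demonstrate correct level and sensible power under the stated sampling
design, not robustness to those real-data features.

## Replicate studies and problem sizes

`run_study` simulates ascertained replicates and analyzes each under any
set of analyses (subset "All" vs "MX" = complete-cases-only; covariates in
or out of the fitted model), sharing the simulated data across analyses so
comparisons are paired.  Per-replicate randomness is derived from
`SeedSequence([seed, replicate])` for reproducibility.  Rates come with
exact Clopper-Pearson 95% intervals; per-replicate failures are excluded
and counted.  The acceptance suite and `scripts/acceptance.py` use 5,000
replicates per scenario — rejection-rate standard error ~ .003 at the .05
level — which keeps a full rerun within desk-scale single-CPU runtime;
p-value uniformity is checked by Kolmogorov-Smirnov over 5,000 replicates
of a smaller complete-data design (15 families + 60 unrelateds), and the
power-ordering check uses 400 replicates of a 30-family design at the
first causal SNP.

## Numerical policy

Double precision throughout; all denominators guarded (variants with
`sigma_G^2` or score variance below 1e-12 are flagged monomorphic rather
than tested); eigenvalues of `Sigma` below 1e-12 raise a singularity
error; block computations are verified against dense single-expression
oracles at 1e-10 in the test suite.  Degenerate inputs — constant
phenotype, constant genotype, rank-deficient designs, separation in the
logistic fits — raise or flag explicitly.

## Known limitations

- Kinship is autosomal only; sex chromosomes would need a different
  recursion.
- The estimating-equation covariance for `(gamma, beta)` assumes the
  phenotypic moment model is correct; the *test* does not.
- The `xi` equation may select a boundary (0 or 1) in small or weakly
  informative samples; no standard error accompanies `xi`.
- The iteration order and damping of the alternation are a design choice;
  other schedules reach the same fixed point but are not guaranteed to
  match any particular software step-for-step.
- Condition (2) of the retention rule is read as requiring the anchoring
  relative to be a sampled, genotyped individual; the phrasing admits a
  wider reading.
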