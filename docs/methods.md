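# Methods

This package quantifies how strongly quantitative feather traits and a binary
colour morph differ among wild populations, and compares that phenotypic
differentiation (P<sub>ST</sub>) with the neutral genetic differentiation
(F<sub>ST</sub>) expected from drift alone.  It was built around the design of
a nine-population European tawny owl (*Strix aluco*) survey — repeated feather
measurements per individual on two body sides, a brown/grey morph score, an
eight-locus microsatellite panel, and per-population winter climate — but the
estimators are generic.

## Phenotypic differentiation

Each trait (plumulaceous length, barb density, barbule density; per feather
side) is first reduced to one value per individual: the unweighted arithmetic
mean over that individual's repeated measurements.  The mean total feather
length is averaged the same way and standardised to zero mean and unit
variance before entering the plumulaceous-length model as a covariate.  The
per-individual means are modelled with a Gaussian linear mixed model

y<sub>i</sub> = Xβ + u<sub>pop(i)</sub> + w<sub>year(i)</sub> + ε<sub>i</sub>

with population and (by default) collection year as scalar random intercepts.
Fixed effects follow the study design: morph plus standardised total length
for plumulaceous length, morph plus measurer identity for the count traits.
Year can be switched to a fixed factor (`C(year)` in the fixed terms), but
the random-year default is what the variance-partition output assumes.

P<sub>ST</sub> is the ratio σ²<sub>pop</sub> / (σ²<sub>pop</sub> +
σ²<sub>res</sub>) of the REML estimates.  The year component is deliberately
excluded from the denominator; it is reported instead through the full
variance-proportion table in which every component (population, year,
residual) is divided by their sum.  Because of this exclusion, P<sub>ST</sub>
is never smaller than the population's share of total variance.  No c/h²
scaling of the generalised P<sub>ST</sub> literature is applied: the ratio is
reported exactly as defined above, and readers should treat it as an upper
bound on additive-genetic differentiation, since in-situ phenotypes confound
genetic and environmental differences between populations.

### REML engine

The restricted log-likelihood is maximised over log-variances with analytic
gradients (L-BFGS-B) and polished with average-information Newton steps.
Numerical choices: starting values split the OLS residual variance equally
across components; log-variances are bounded at ±(data scale × e<sup>±23</sup>)
to keep the Cholesky factorisations well-posed; the polish stops when the
gradient norm falls below 1e-10 or the likelihood is flat to double
precision; a fit is declared non-converged only if the remaining gradient
norm exceeds 1e-5 (1e-3 when the line search has stalled at machine
precision), with boundary components exempted.  A component smaller than
1e-10 × the residual variance is reported as exactly zero.  Aliased fixed
columns are dropped greedily left-to-right in declaration order.  On balanced
one-way designs the estimates agree with the closed-form ANOVA estimators to
1e-8 relative; this is a test oracle, not part of the implementation.

The covariance of the variance estimates is the inverse average-information
matrix, AI<sub>jk</sub> = ½ (Py)ᵀ G<sub>j</sub> P G<sub>k</sub> (Py).  The
standard error of P<sub>ST</sub> follows by the delta method with gradient
(σ²<sub>res</sub>, −σ²<sub>pop</sub>) / (σ²<sub>pop</sub> + σ²<sub>res</sub>)².
Whether the study's own software used average or observed information is not
documented; average information was chosen for its numerical robustness, and
the delta-method SE agrees with a parametric bootstrap within 20% on balanced
designs of the study's size.

Random-effect significance uses a likelihood-ratio test against the model
without that term, referred to χ²₁.  Testing a variance on its boundary makes
this reference conservative; no ½:½ mixture correction is applied, matching
the 1-df convention of the study-style output.  Fixed effects are tested with
Wald χ²₁ = (estimate/SE)².

## Morph on the latent scale

The brown (1) / grey (0) morph, one observation per individual, is modelled
with a binomial logit mixed model with intercept and random intercepts for
population and year.  The marginal likelihood is approximated by the Laplace
method with a penalised-IRLS inner loop for the joint mode of (intercept,
random effects); variances are optimised on the log scale.  Standard errors
of the variances come from the numerically differentiated Hessian of the
Laplace log-likelihood, and each variance is reported with a Z ratio
(estimate/SE) and a one-sided normal tail probability.  Note the one-sided
convention: the variance-ratio-to-p mapping used by some mixed-model packages
is not reproducible from a normal tail, so this package states its convention
explicitly.

The population share of morph variance is computed on the latent (liability)
scale: σ²<sub>pop</sub> / (σ²<sub>pop</sub> + σ²<sub>year</sub> + π²/3),
where π²/3 ≈ 3.29 is the variance of the standard logistic distribution
implied by the logit link.  Adding π²/3 strictly shrinks the proportion
relative to the raw variance ratio.  The Laplace approximation differs from
penalised quasi-likelihood fits by small numerical amounts, so latent-scale
variances from other software may deviate in the second decimal at this
sample size.

## Genetic differentiation

Per-locus F<sub>ST</sub> is a two-level analysis of molecular variance over
gene copies with allele-identity distance (0 if the two copies carry the same
allele code, 1 otherwise) — the "number of different alleles" distance that
microsatellite AMOVA conventionally uses.  Loci are pre-filtered to those
with strictly less than 20% missing calls across all individuals pooled (the
threshold is configurable); missingness is locus-wise, i.e. both gene copies
of a call are missing together.  Monomorphic loci have no variance to
partition and are reported as undefined.  Negative per-locus estimates are
retained, keeping the across-loci mean unbiased.  No within-individual
(F<sub>IS</sub>) level and no stepwise-mutation (R<sub>ST</sub>) distance are
modelled.

The global estimate is the unweighted mean across defined loci; its 95%
confidence interval is mean ± 1.96 × SD/√L using the across-loci standard
deviation.  This interval describes dispersion among loci, not a bootstrap or
permutation interval; it is the reconstruction that matches how an
across-loci mean ± SD summary converts to a CI.  Significance comes from a
whole-individual permutation test (default 10 000 permutations): individuals
are shuffled among populations keeping population sizes, the global mean is
recomputed, and p = (1 + #{perm ≥ observed}) / (n<sub>perm</sub> + 1), which
can never be exactly zero.

## The P<sub>ST</sub>–F<sub>ST</sub> comparison

A trait is flagged as exceeding neutral expectation when its P<sub>ST</sub>
point estimate is strictly greater than the upper bound of the F<sub>ST</sub>
95% CI; the margin (P<sub>ST</sub> − CI upper) is reported alongside.  The
morph enters the comparison via its latent-scale proportion.  This is a
point-versus-interval screen, not a formal joint test; its purpose is to rank
candidate traits for local adaptation, and it can only be conservative or
anticonservative depending on the (unavailable) trait heritabilities.

Climate associations are plain Pearson product–moment correlations between
per-population trait means (two-stage averaging: individuals first, then
populations) and per-population mean winter temperature and precipitation,
with the two-sided t reference t = r√(n−2)/√(1−r²).  With six trait-side
means and two covariates there are twelve correlations; no multiple-testing
correction is applied, and the output says so — at n = 9 populations a
single correlation must reach |r| ≈ 0.67 for p < 0.05.

## Synthetic data

The generator exists so that every estimator has a recovery test with known
truth; it emulates the study design, not any particular dataset.

* **Traits** — y = grand mean + year + morph·effect + slope·z(total length)
  + u<sub>pop</sub> + v<sub>ind</sub> + ε, all effects zero-mean Gaussian.
  Defaults: nine populations with the published per-population individual
  counts (9–52), two measurements per individual and side, grand mean 6 cm
  (a plausible plumulaceous length), σ²<sub>pop</sub> = 0.09,
  σ²<sub>ind</sub> = 0.10, σ²<sub>year</sub> = 0.02, σ²<sub>res</sub> = 0.12
  (the scale of the ventral plumulaceous-length analysis), morph shift 0.1,
  length slope 0.3 per SD, total length ~ N(10, 1) cm.  The same law is
  applied independently to each response trait and side, so cross-trait and
  cross-side correlations — present in real feathers — are absent by design.
  Year is generated (and fitted) as a random effect.  The plumulaceous part
  is clipped at the total feather length; at the default means this clip is
  essentially never active.
* **Morph** — Bernoulli per individual with population prevalence
  inverse-logit(intercept + u<sub>pop</sub>); defaults intercept 0.405
  (≈60% brown) and logit variance 0.18, the study scale.
* **Genotypes** — Balding–Nichols island model: population allele frequencies
  Dirichlet(ancestral × (1−θ)/θ), genotypes by random union of gametes,
  Bernoulli missingness per individual × locus.  Defaults: 9 populations ×
  30 diploids, 8 loci × 8 equifrequent ancestral alleles, θ = 0.022 (the
  study's global F<sub>ST</sub>).  θ = 0 short-circuits to identical
  population frequencies.  No linkage, mutation model, or spatial structure.
* **Climate** — independent uniform draws over typical European winter means
  (−6 to 12 °C, 30–160 mm); deliberately uncorrelated with the traits, so
  pipeline tests exercise the machinery, not a built-in effect.

All generators are bit-reproducible for a fixed seed.  Passing recovery
tests on these data shows the estimators are correct under the generating
model; it does not validate the model against real feathers (no
side-by-side trait correlations, no genotyping artefacts beyond random
missingness, no observer drift).

## Problem sizes used in the checks

The test suite runs replicate-based checks at reduced sizes chosen so each
check's Monte-Carlo error is well below its tolerance: REML recovery over 30
replicates of a 9 × 12 × 2 design; P<sub>ST</sub> recovery over 20 replicates
at 30 populations (at nine populations the ratio estimator carries an O(1/K)
Jensen bias that is a property of the statistic, not the fit); GLMM recovery
over 15 replicates of 40 × 50; permutation calibration over 100–150 panmictic
datasets with 99 permutations each.  The F<sub>ST</sub> recovery check runs
the full 200-replicate, 9 × 30, 8-locus × 8-allele design at θ = 0.022.

## Known limitations

* P<sub>ST</sub> here has no heritability scaling; conclusions about local
  adaptation inherit every caveat of in-situ phenotypes.
* The binomial fit is a Laplace approximation; with few, small populations
  its variance estimate is noisy and can sit on the zero boundary.
* The F<sub>ST</sub> CI describes across-loci dispersion only and ignores
  sampling error within a locus; with eight loci it is itself noisy.
* The LRT for variances is conservative at the boundary by construction.
* Genepop output stores populations as anonymous blocks, so population
  labels are regenerated as pop1..popK on re-reading.
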