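# Methods

`ldacc` measures how much of the accuracy of genomic estimated breeding
values (GEBVs) comes from additive-genetic relationships between training
and validation animals, and how much from marker–QTL linkage
disequilibrium (LD), in a progeny-testing dairy population.  The design is
a relationship-constrained cross-validation: splits are constructed so that
no training bull is related to any validation bull above a cap a_max, and
the decay of accuracy across a_max scenarios is decomposed by regression
into a persistent LD component and a transient relationship component.

## Models

### Phenotype model

The phenotype of bull *i* is a daughter yield deviation (DYD) y_i, a
progeny-test summary of his daughters' performance.  All predictors share

    y_i = mu + g_i + e_i,     Var(e_i) = sigma2_e / w_i,

where g_i is the bull's additive breeding value and w_i the reliability of
his DYD (its squared accuracy).  Accurate, heavily progeny-tested bulls get
small residual variance.

### BayesB

g_i = sum_k x_ik beta_k delta_k over K SNP dosages x_ik in {0,1,2}, with
Pr(delta_k = 1) = pi and locus-specific effect variances sigma2_bk under
scaled-inverse-chi-square priors (a t-like marginal effect prior).  The
sampler is MCMC: Gibbs steps for the intercept, included effects and the
residual variance; a Metropolis–Hastings step for (delta_k, sigma2_bk)
jointly.  The MH move proposes delta* ~ Bernoulli(pi) and, when included,
sigma2* from the prior, and accepts on the marginal likelihood of the
residuals with beta_k integrated out (prior and proposal densities cancel).
This choice of proposal is validated by an oracle: at pi = 1 with the locus
variance pinned, the chain is a weighted Bayesian ridge whose posterior
mean must match the closed-form ridge solution (asserted at GEBV
correlation ≥ 0.98 in the tests).

The locus-variance prior scale derives from the additive variance as
sigma2_beta = sigma2_a / (pi · sum_k 2 p_k q_k): the additive variance
spread over the pi·K loci expected in the model.  At pi = 1 this reduces to
the ridge-regression variance, which ties the two model families together.
Prior scales are set so prior means equal the supplied variance components
(nu = 4.2 on both the residual and effect variances).  GEBVs are
ghat_i = sum_k x_ik betahat_k with betahat_k the posterior mean of
delta_k·beta_k; the intercept is not part of the breeding value.

Non-mixing is surfaced, never silent: the effective sample size of the
residual-variance trace is estimated from its autocorrelation and a
warning is emitted below 30.

### G-BLUP, P-BLUP and RR-BLUP

The animal model g ~ N(0, K sigma2_a) is solved by dense mixed-model
equations with reliability-weighted residual precision.  K is either the
genomic relationship matrix

    G = sum_k (x_k − 2 p_k 1)(x_k − 2 p_k 1)' / (2 sum_k p_k(1 − p_k))

(allele frequencies observed over the pooled training and validation
bulls by default, overridable) or the pedigree numerator relationship
matrix A built by the tabular method with unknown parents treated as
unrelated non-inbred founders.  Validation bulls enter the system without
phenotypes and receive EBVs through their relationship rows.  With this G,
the animal model is algebraically identical to ridge-regression BLUP on
centered dosages with common effect variance sigma2_a / sum 2pq; the
package carries both routes and the test suite asserts their agreement to
1e-6, which also pins down the centering convention.  G may be numerically
singular; a diagonal ridge starting at 1e-8 (escalated only as far as
needed, and logged) is added purely for solvability.

### Accuracy estimation

Validation EBVs are centered on their replicate's mean EBV, pooled across
replicates of an a_max scenario, and correlated with DYDs.  The accuracy of
the EBVs as predictors of true breeding values is

    rho_hat = corr(ghat, y) / mean_i r_gy(n_i, h2),
    r_gy(n, h2) = sqrt( (n h2/4) / (1 + (n − 1) h2/4) ),

where r_gy is the selection-index (progeny-test) accuracy of a DYD from n
daughter records at daughter-record heritability h2, averaged
arithmetically over the pooled validation bulls.  rho_hat is a ratio
estimator and can exceed 1 under sampling noise; it is reported unclipped
with a warning, because clipping would hide estimator noise.  The simulator
generates DYDs under exactly this model (below), so the estimator is
consistent in simulation and the test suite checks it against the
correlation with simulated true breeding values directly.

### Accuracy due to LD

Across a_max scenarios the relationship information decays while LD
information does not.  P-BLUP uses relationships only, so its relative
accuracy x(a_max) = rho_PBLUP(a_max)/rho_PBLUP(reference) indexes the
relationship decay.  Ordinary least squares of

    rho_GEBV(a_max) = rho_LD + d · x(a_max) + eps

gives the accuracy due to LD as the intercept rho_LD (the accuracy left
when relationship information is extrapolated to zero) and the
relationship component as the slope d.  The reference scenario is the
largest a_max (0.6).  At least three scenarios are required; standard
errors are the OLS ones, and no further uncertainty quantification is
attempted.

## Synthetic population

No public counterpart of the original genotype/pedigree data exists, so
the package simulates a population with the same statistical structure and
treats the generator's defaults as the study conditions.

* **Pedigree** — discrete generations (default 5) from 190 founder pairs;
  64 sires per generation drawn from the two preceding male cohorts, never
  reused, each allotted at least one of the 384 offspring with
  Gamma-weighted (shape 0.35) multinomial counts.  This gives paternal
  half-sib families with mean 6 and a long right tail (max ≈ 60–100),
  full-sib pairs via repeated matings (8% of matings), and genotyped
  father–son chains.  Dams carry at most 4 offspring.  Random mating, no
  selection, no X-specific inheritance.
* **Founder haplotypes** — a neutral coalescent with recombination
  (msprime), constant effective population size Ne = 800, uniform map at
  1 cM/Mb.  Default genome: 5 chromosomes × 25.6 Mb × 400 markers, i.e.
  0.064 Mb marker spacing.  Markers are ascertained one per spacing window
  with probability ∝ MAF², which flattens the site-frequency spectrum to a
  roughly uniform MAF distribution (mean ≈ 0.25) as SNP chips do.  Ne was
  calibrated once so that adjacent-marker founder r² ≈ 0.22 at that
  spacing; the realized decay runs from ≈ 0.29 at 0.02 Mb to ≈ 0.04 at
  1 Mb.  The far tail decays faster than in real cattle (a constant-size
  coalescent lacks the demographic history that props up long-range r²);
  the analysis depends on short-range LD, where the match is good.  An
  `independent` founder model draws alleles in linkage equilibrium for the
  LE control study.
* **Gene dropping** — each non-founder receives one recombined gamete per
  parent (Poisson crossovers on the physical map, random start phase), so
  realized genomic relationships are unbiased for the tabular A entries —
  a property the tests verify against an allele-dropping IBD oracle.
* **Trait architecture** — 100 QTL placed on segregating sites excluded
  from the marker panel (prediction must pass through marker–QTL LD), with
  Gamma(0.25) effect sizes of random sign: a few major QTL atop a
  polygenic background, the architecture inferred for dairy traits.  Effects are
  rescaled so the founder breeding-value variance equals sigma2_a exactly
  (the 10% tolerance contract is met by construction).  Default trait:
  h2 = 0.53 for a daughter record (a milk-yield-like value).
* **DYDs** — y_i = g_i + eps_i with per-bull noise
  Var(eps_i) = sigma2_a (1 − r_i²)/r_i², r_i = r_gy(n_i, h2), so that
  corr(g_i, y_i) = r_i exactly and the regression of y on g has slope 1
  (DYDs are unshrunken).  Daughter counts are log-normal (median 120,
  sigma 0.8) clipped to [30, 5000], spanning recent progeny-tested cohorts
  through old proven sires.  The reliability weight is w_i = r_i².  The
  scalar sigma2_e handed to the predictors is sigma2_a(1 − mean w); the
  per-bull noise is mildly heteroscedastic around it, as real DYD
  variances are around any single dispersion parameter.

What the generator does **not** emulate: selection (real bull cohorts are
selected, which shrinks genetic variance and distorts LD), maternal/herd
effects inside the DYD, genotyping error and missingness patterns,
X-chromosome inheritance, and the long-range LD floor from demographic
history.  Passing tests therefore show the estimators and the design work
as specified under the assumed generating model — not that the specific
accuracy levels transfer to any real population.

## Cross-validation design

A split must satisfy: max pedigree relationship between training and
validation ≤ a_max; at most two validation bulls per paternal half-sib
family; no sire of a training bull in validation (their accuracy is not
representative of future candidates); validation bulls never reused across
replicates.  Bulls that would breach the cap against the chosen validation
set are excluded from the analysis.  The sampler is a randomized greedy —
draw a family-aware validation set, drop conflicting training bulls, retry
(default 30 times), keep the fewest-exclusion assignment, breaking ties in
favour of fewer protected close relatives so that later down-sampling
stays feasible.  Exhaustive enumeration on toy pedigrees bounds the
greedy's optimality gap in the tests.  Training sets are trimmed to a
common size by random removal that never touches bulls related to
validation at ≥ 0.25 (fathers, full and half sibs), and the halved
training sets reuse the same validation sets with the same protection, so
the close-relative count is held constant while the precision of SNP
effect estimates drops.

The default scenario grid at full scale mirrors the reference design
(a_max ∈ {0.6, 0.49, 0.249, 0.1249}, training 2,096/1,048, 15 replicates,
minimum validation 30 or 11).  The bundled experiment runs a desk-scale
version: ~950 genotyped bulls, 2,000 markers, a_max ∈ {0.6, 0.249,
0.1249}, 20 replicates with 12–15 validation bulls each, training 400/200,
BayesB chains of 3,000 iterations (burn-in 1,000).  Validation sets are
proportionally smaller than at full scale because the scaled population is
relatively more interrelated: protected close relatives of a large
validation set would otherwise exceed the halved training size.  a_max
0.49 adds little at this scale (its constraint set differs from 0.6 only
through full sibs and fathers, which are few); three well-separated
scenarios identify the two-parameter regression while keeping 120 MCMC
fits inside a desk-time budget.  The experiment's BayesB uses pi = 0.05 so
that the number of fitted SNPs per training bull (100/400) matches the
full-scale ratio (~400 fitted SNPs for ~2,000 bulls); with the literal
pi = 0.01 on a 2,000-SNP panel BayesB would fit only 40 SNPs and capture
almost no relationship information.  `BayesBConfig` itself defaults to
pi = 0.01 for full-scale panels.

## Numerical choices

* Strict inequalities in QC ("< 5% missing", "> 3% MAF"), as printed in
  the source description of the panel; MAF is computed after X-masking
  over non-missing calls.  `mean_rounded` imputation rounds half to even
  (numpy convention); ties are essentially absent in real dosage means.
* The BayesB chain seeds numba's RNG once per fit; runs are bit-identical
  for a fixed config.  Stage seeds fan out from the master seed by CRC-32
  of the stage label, so adding a scenario never perturbs another stage's
  draws.
* The A-matrix recursion is dense O(N²) and fine to ~20k individuals;
  no sparse-inverse machinery is included by design.
* Degenerate inputs fail loudly: monomorphic panels (zero G denominator),
  all-missing SNPs, constant breeding values (undefined DYD accuracy),
  unidentifiable LD regressions (constant predictor), infeasible split
  constraints (the binding constraint is named).
* `estimate_accuracy` needs ≥ 3 pooled bulls; per-replicate correlations
  are reported alongside the pooled estimate.

## Known limitations

* rho_LD from 3–4 scenario points has wide sampling error; its OLS
  standard error understates it because the scenario accuracies share
  validation noise.
* The greedy split sampler is not an exact optimizer; with very tight
  constraints it may exclude more bulls than necessary (bounded in tests).
* BayesB desk-scale chains (3,000 iterations) show residual-variance ESS
  warnings by design; posterior means of GEBVs are stable long before the
  variance trace mixes well, which is what the oracle test checks.
* Variance components are inputs, not estimates; there is no REML step.
* Accuracy of Mendelian-sampling terms is out of scope.
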