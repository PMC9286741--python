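# Methods

## Model

The package models a cross-sectional slice of the longitudinal body-weight
data — the trend-filtered weight of every mouse at one age — as

    Y = alpha_0 + sum_e Z_e alpha_e + sum_v G_v beta_v
        + sum_{v,e} G_v Z_e gamma_ve + eps,

where `Z` is the binary environment design (generation cohorts throughout;
diet groups additionally from the intervention age of 180 days, giving
E = 12 generation columns before intervention and 17 columns after in the
full design), `G_v` is either the founder-of-origin probability 8-vector of
a genotyped marker or an allele dosage in [0, 2], and the random effects
carry the priors `beta_v ~ N(0, rho^2/V)`, `gamma_v. ~ N(0, Omega/V)` with
diagonal `Omega`, and `eps_n ~ N(0, sum_e Z_ne sigma_e^2)`.  There is no
environment-independent noise term (it would be non-identifiable alongside
the per-environment terms) and off-diagonal `Omega` entries are fixed at
zero.  Marginally `Y ~ N(mu, Lambda)` with
`Lambda = Theta + rho^2 K + sum_e Omega_ee (K o Z_e Z_e')`.

Kinship is `K_mn = (1/V) sum_v G_mv . G_nv` over founder probabilities
(diagonal in [1/8, 1]); a dosage-mode kinship (per-marker centered and
unit-variance-scaled cross product over polymorphic markers) is provided
for the comparison with ordinary GWAS practice.  Genome scans use
leave-one-chromosome-out (LOCO) kinship.

Fitting is by profile maximum likelihood: the fixed effects are solved by
GLS at each candidate parameter vector and the resulting profile
likelihood is maximised over `(sigma_e^2, rho^2, Omega_ee)` directly on the
variance scale by L-BFGS-B with analytic gradients (trace/quadratic-form
identities).  Phenotypes are never standardized, so effects are in grams.
Defaults: non-negativity bounds on all components (relaxable by flag),
three starting points (one method-of-moments heuristic plus seeded random
rescalings), gradient tolerance 1e-6, 500 iterations, Cholesky-based
solves with a 1e-9 floor on the noise variances to keep `Lambda` positive
definite during search.  Non-convergence is flagged on the returned
components, not silently ignored.  EMMA is fit as the E = 1 special case
(single genetic variance, homoscedastic noise, `Omega = 0`).

## Variance decomposition (PVE)

PVE is the expected sample variance of the genetic part of `Y` over the
expected sample variance of `Y`.  The implementation evaluates the exact
trace/sum expressions for the total and conditional-on-environment
decompositions; both split `E[V[Y]]` into fixed-effect, genetic and
residual terms that sum exactly.  In the homoscedastic (EMMA) reduction the
residual term is `tr(theta^2 I)(N-1)/N^2 = N theta^2 (N-1)/N^2`, the form
consistent with the general decomposition; a Monte-Carlo oracle (empirical
`E[V[Y]]` over draws with and without the genetic terms) verifies the
algebra in the test suite.

Standard errors are delta-method: the observed information of
`(sigma^2, rho^2, Omega)` is obtained by central differences of the
analytic gradient, inverted, and propagated through the (numerically
differentiated) PVE algebra.  A parametric-bootstrap alternative sits
behind a flag.  PVE is clipped to [0, 1] only for reporting and only under
the non-negativity constraint; raw values are always available.

The kinship–covariance diagnostic asks, within one diet, whether
phenotypic pair similarity separates by kinship.  The pair statistic is the
product of the two mice's deviations from the diet-mean weight (the paper
of record for this kind of diagnostic does not pin down a pair statistic;
the centered product is the natural pairwise covariance contribution).
Pairs split at kinship 0.2; the two groups are compared by a two-sided
Mann–Whitney U (asymptotic, tie-corrected) and AUC = U/(n1 n2).

## Genome scans and significance

Additive tests put the focal variant's founder probabilities among the
fixed effects under a sum-to-zero (Helmert) contrast — 7 columns, keeping
the intercept identifiable — and compare maximised likelihoods with and
without those columns.  Interaction tests additionally free per-diet
interaction columns (reference diet dropped) with the additive term free
in both models, so the statistic isolates genotype–diet interaction.
`Phi` is the natural-log likelihood ratio; LOD = `Phi`/ln 10.

By default the variance components are estimated once per (age,
chromosome) under the no-focal-variant model and held fixed while the
focal fixed effects are profiled across variants; with the covariance
fixed, each variant costs one small GLS update.  An exact
`refit_per_variant` mode re-maximises all parameters for both models.
Monomorphic variants are flagged with `Phi = 0`.

Sequential permutation p-values: phenotype labels are permuted
(unrestricted by default, matching the exchangeability assumption; a
within-strata scheme is available), the statistic recomputed at the fixed
null covariance, and sampling stops at C = 10 exceedances (ties count) or
M_max permutations.  On early stopping the randomized p-value is drawn
from Beta(C, M−C+1), the exact construction whose null distribution is
uniform under negative-binomial stopping; a draw from the bracketing
interval [C/M, (C+1)/(M+1)] is available as an option but is measurably
non-uniform at fine resolution (its lumpy support fails a KS test against
uniform with ~1000 null variants), which is why the Beta draw is the
default.  Exhausted or fixed-M runs use (C+1)/(M+1).  Two caveats the
calibration tests make explicit: the permutation test is exact only when
the phenotype is exchangeable under the null (a strongly kinship-structured
phenotype makes unrestricted permutation conservative), and the randomized
draw is noisy for non-significant variants — significant variants exhaust
the permutation budget and get the deterministic fixed-M p-value.

Genome-wide thresholds divide the family-wise alpha (default 0.05) by the
effective number of tests: the count of top eigenvalues of the
per-chromosome marker correlation matrices (pooled genome-wide) that
explain 90% (significant tier) or 99.5% (stringent tier) of marker
variance.  The suggestive tier, applied to interaction tests only, is 10x
the significant cutoff.

## Fine-mapping

Untyped founder variants are imputed as expected dosages: the
founder-of-origin probability vector at the variant's position is linearly
interpolated (in physical position) between the flanking typed markers and
dotted with the founders' allele counts; variants outside the typed span
are skipped and counted.  Each significant variant gets a founder allele
pattern (FAP): the subset of founders carrying its minor allele, labelled
in the canonical founder order AJ, B6, 129, NOD, NZO, CAST, PWK, WSB.
Founders must be homozygous at the variant (heterozygous calls exclude it);
on a 4/4 split the side containing AJ is labelled — a deterministic tie
rule.  Variants partition exhaustively and exclusively into FAP groups;
the group LOD is the best member LOD and groups are ranked by it (ties:
larger membership, then label order).  Annotation overlap is
point-in-interval under a single 0-based half-open coordinate convention
(GFF converted at the boundary, BED taken as-is).  Effect profiles extract
the GLS estimate and standard error of a focal-variant fixed effect (per
founder allele, per minor allele, or per diet as `phi + chi_diet`) at each
age on the analysis grid.

## Nonlinearity of effect trends

Per-age effects with standard errors are modelled as
`phi_hat_t ~ N(phi_t, psi_hat_t)` with `psi_hat` treated as known; a cubic
alternative is compared to a linear null by weighted least squares (weights
`1/psi_hat^2`), and twice the log likelihood ratio — the drop in weighted
residual sum of squares — is referred to chi-squared with 2 degrees of
freedom.  Ages are affinely mapped to [−1, 1] before polynomial fitting
for conditioning; the statistic is invariant to this.  The sweep runs one
test per founder allele at each diet-independent locus (8 per locus) and
one per (founder, diet) pair at each diet-dependent locus (40 per locus);
in the full 14 + 19 locus design that is 112 and 760 tests.  Significance
uses the tiered cutoffs 1e-4 and 1e-5 — slightly stricter than exact
Bonferroni at 0.05 (0.05/112 ≈ 4.5e-4, 0.05/760 ≈ 6.6e-5), applied
verbatim as the design's round-number thresholds.

## Synthetic data: what it emulates and what it does not

The generator emulates the structural features the method depends on:
8-founder mosaic genomes with local linkage (a first-order Markov chain
along markers, switch probability 0.05/marker by default — chosen to give
realistic block lengths of ~20 markers at desk scale), one-hot founder
probabilities with biallelic founder alleles (founders homozygous,
patterns non-monomorphic), the implied kinship, a binary environment
design, and phenotypes drawn from the model's exact multivariate normal.
The interaction variances are solved in closed form so that the
conditional PVE in each environment equals its target exactly; the shared
genetic variance `rho^2` is set to zero in protocol mode because the
simulation protocol specifies only environment-specific genetic variance
(a shared-`rho^2` mode exists for general testing).  Desk-scale defaults:
N = 500 mice (the full study had 946), 2 chromosomes x 250 markers.

It does not emulate: founder-probability uncertainty (rows are one-hot,
real posteriors are soft), heterozygous founder mosaics, the empirical DO
kinship spectrum, linkage disequilibrium between founder strains, age
correlation of phenotypes, or survival attrition.  Tests passing on this
generator therefore demonstrate correctness of the estimators and tests
under the model's own assumptions — parameter recovery, calibration,
ranking — not robustness to the ways real DO data violate them.

The simulation study mirrors the two-environment protocol: a 114-setting
grid (per-environment PVE targets 0.05–0.95 in steps of 0.05 crossed with
environment-1 targets {0.2, 0.5, 0.8} and allocations 1:1 and 4:1), noise
variances fixed at 1, 50 replicates per setting, one kinship per study
with environment assignment and phenotypes redrawn per replicate.

## Numerical choices and degenerate inputs

* l1 trend filtering minimises `1/2 ||y−x||^2 + lambda ||D2 x||_1` (second
  differences, giving piecewise-linear fits) by ADMM with a pentadiagonal
  banded solve per iteration, tolerance 1e-8 on primal/dual residuals;
  `lambda = 0` short-circuits to the data and the large-`lambda` solution
  snaps to the analytic OLS line whenever that line attains an equal or
  better objective.  The penalty grid is logarithmic, 30 points over
  1e-2–1e4; holdout selection removes 10% of interior ages per mouse
  (seed-controlled) and minimises pooled squared error.  Series shorter
  than 3 points are rejected; out-of-span queries return missing values.
* Variance-component search treats Cholesky failures as +inf objective;
  collinear fixed-effect designs raise immediately.
* Environment columns with fewer than two members make conditional PVE
  undefined and raise; empty kinship groups skip the covariance diagnostic
  with a warning.
* The component solver for target PVE raises on non-positive genetic
  coefficients (degenerate kinship) and on targets implying negative
  interaction variances.
* All randomized steps (multi-start, holdout, permutations, simulation)
  consume explicit seeds or numpy Generators; results are bit-reproducible
  given a seed.

## Known limitations

* Only diagonal `Omega` is implemented; correlated interaction effects
  across environments are out of scope.
* The scan's default component-reuse approximation slightly misstates
  `Phi` when the focal variant explains appreciable variance; the exact
  refit mode exists but is slow for genome-wide use.
* Delta-method PVE standard errors rely on a quadratic likelihood
  approximation that degrades at boundary estimates (components at zero).
* Survival bias is addressed only as a data filter (restricting to mice
  alive at a given age), not as a model.
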