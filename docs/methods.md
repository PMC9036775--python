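# Methods

## Models

For each trait, four nested univariate linear mixed models are fitted:
fixed effects only; fixed + microbial values `m ~ N(0, M σ²ₘ)`; fixed +
breeding values `a ~ N(0, A σ²ₐ)`; and the full model with both.  Residuals
are iid.  The bivariate versions of the last three replace each scalar
variance by a 2×2 (co)variance matrix (G₀ for genetics, R_m for the
microbiome, R_e for residuals) with Kronecker covariance over animals.
Heritability and microbiability are the per-trait variance ratios against
the sum of included components; genetic/microbial/residual correlations are
the off-diagonal ratios of the 2×2 matrices.

Fixed effects are categorical factors (defaults: pen size, herd of birth,
sex, contemporary group) encoded as intercept + drop-first dummies;
rank-deficient (aliased) columns are detected by pivoted QR and dropped
with a warning naming them.

## Preprocessing

The pipeline order is fixed: rarefy every sample to a common depth
(default 9000 reads; shallower samples are discarded and reported), keep
OTU whose prevalence is *strictly* above the threshold (default 1% of
samples), add a +1 pseudocount, convert to relative abundances P, and
z-score log P per OTU column.  Choices worth knowing:

* Rarefaction is a without-replacement (multivariate hypergeometric)
  subsample, one independent seeded draw per sample, and is idempotent at
  the target depth.
* The column standard deviation uses the sample (n−1) denominator, which
  fixes trace(M) = n−1 exactly.  Because depth is equalized, standardizing
  log(count+1) and standardizing log P give the identical design, so the
  pseudocount-in-denominator question is moot.
* M = Z₃Z₃′/k is always singular: column centering puts the all-ones
  vector in its null space.  Two inverses are provided.  Inside the mixed
  model equations a ridge (10⁻⁶ × mean diagonal, triggered below a
  10⁻⁸ relative eigenvalue floor) keeps the null direction penalized so
  the system is not aliased with the intercept.  For back-solving, an
  eigen pseudo-inverse is used instead, which makes the reconstruction
  `Z₃·ÔTU = m̂` exact for m̂ in the column space of Z₃.

## Gibbs sampler

Blocked Gibbs with exact joint full conditionals for each location block
(fixed effects, all breeding values, all microbial values) followed by the
variance draws.  The implementation hoists all factorizations out of the
chain:

* breeding values are parameterized as `a = LQα` with `L = chol(A)` and Q
  the eigenbasis of `L′Z₁′Z₁L`, making the conditional precision of α
  diagonal and `a′A⁻¹a = α′α`;
* microbial values are parameterized in the rank-retaining eigenbasis of M
  rotated against the observation pattern, which both restricts the prior
  to range(M) (the proper-distribution treatment of a singular M) and
  diagonalizes the conditional.  The rank of M, not n, is the degrees of
  freedom of the σ²ₘ update.

One iteration then costs a handful of matrix-vector products, so the
default desk-scale chain (20,000 iterations, 4,000 burn-in, thinning 10)
fits ~550 animals with a ~900-animal pedigree in ~15–25 s on one core.
Study-scale settings (100,000 / 15,000 / 10) are a config change.

Priors default to improper flat scaled inverse chi-squares (df −2, scale
0) and the analogous flat inverse-Wishart (df −3) for 2×2 blocks, the
common animal-breeding default; both are configurable.  With flat priors
the posterior mean of a weakly identified variance ratio is biased away
from the boundary — visible for h² at small n with shallow pedigrees —
which is a property of the posterior, not the sampler: the sampler was
verified against a brute-force 2-D grid posterior (locations integrated
analytically) to sub-percent agreement.

Bivariate fits sample the trait pairs of each eigen-coordinate from exact
2×2 conditionals (precision `w·R_e⁻¹ + prior⁻¹`), require complete records
on both traits, and draw the 2×2 component matrices from inverse-Wishart
conditionals via Bartlett decomposition.  Correlations whose posterior
mean sits at the boundary (|r| > 0.98) are flagged not-estimable ("NE").

Convergence: split-chain potential scale reduction and an
autocorrelation-based effective sample size are reported per variance
component, with a warning above R̂ = 1.1.

**DIC** uses the conditional (location-given) deviance
`D(θ) = −2 log N(y | Xb+Z₁a+Z₂m, Iσ²ₑ)`: DIC = D̄ + pD with
pD = D̄ − D(posterior means).  Only between-model orderings are
meaningful.

## MWAS

*Single-OTU regression* adds one standardized abundance column (the same
scale as back-solving) as a fixed covariate to the genetic animal model.
The base system is factorized once and each OTU enters through a rank-one
Schur complement, so a scan is O(n²) per OTU.  Variance components are
plug-in values (e.g. posterior means of the genetic model); optional
per-OTU EM-REML refitting is available but changes estimates marginally at
these sizes.

*Back-solving* maps m̂ from the full model to per-OTU effects under the
equal-variance assumption σ²_OTU = σ²ₘ/k, with analytic variances built
from PEV(m̂) = C^mm σ²ₑ.  Note the information direction: raising σ²ₑ at
fixed design *lowers* every back-solved variance, because var(m̂) =
Mσ²ₘ − C^mmσ²ₑ shrinks when the data are noisier.  The analytic variances
were verified against the empirical variance of back-solved effects over
thousands of simulated phenotype replicates.

Both methods convert estimate/SE to a Z-score and a chi-square(1 df)
two-sided p-value.  Thresholds divide the family-wise rate by the
effective number of independent tests: the smallest count of top
eigenvalues of the OTU correlation matrix capturing 99.5% of its total
(computed through the smaller Gram side when k > n; the n vs n−1
denominator cancels).

## Part-whole (LR) cross-validation

Prediction accuracy of m̂ (and â+m̂ under the full model) is the Pearson
correlation, over held-out animals only, between predictions from a
partial fit (their phenotypes set missing; the animals stay in A and M)
and the whole-data fit.  Variance components stay fixed at whole-data
values for every partial refit, isolating prediction from estimation
noise.  Designs: random hold-out subsets (default 50 animals × 20
replicates) or one fold per contemporary group.

A caveat the tests make explicit: the LR correlation is scale-invariant in
σ²ₘ and both predictions share the training records, so it stays well
above zero even for pure-noise phenotypes; it is a *consistency* measure,
optimistic as an absolute accuracy, and is best read comparatively
(between designs or models).

## Synthetic data

The generator emulates a divergent-selection experiment at desk scale:

* a two-line pedigree (founders split into lines, within-line matings,
  litters of 8, two ancestor generations below ~550 phenotyped animals in
  the last generation), breeding values by Mendelian sampling with
  inbreeding-adjusted segregation variances;
* OTU counts from community-level log propensities (spread 2.0) plus ~30
  latent community axes (total factor sd 2.0) plus per-sample log-normal
  noise (sd 1.0), structural zeros at rate 0.5, multinomial sampling at
  N(12000, 1500²) depth — so rarefaction discards a few percent of
  samples, as in real runs.  The latent axes matter: without between-OTU
  covariation M is nearly a centered identity and σ²ₘ is not separable
  from σ²ₑ at any sample size, whereas real gut communities co-vary along
  a few dominant gradients;
* phenotypes y = Xb + a + Z₃u + e with u ~ N(0, σ²ₘ/k), optionally with
  planted large standardized effects; Z₃ comes from the same preprocessing
  the estimation side uses, so var(m) = σ²ₘM exactly.  Fixed-effect level
  values are drawn once from N(0,1); realized h²/m² are therefore defined
  on the fixed-effect-adjusted part a+m+e, which is also what the models
  estimate.  Contemporary groups are birth-order blocks spanning both
  lines (default 14, matching the grouped cross-validation design).

What the generator does *not* emulate: taxonomy and phylogeny, read-level
artifacts (chimeras, primer bias), diet/pen environmental effects on the
microbiome, microbiome heritability (microbiomes are independent of the
pedigree, so genetic–microbial confounding is absent), and
selection-response dynamics of the lines.  Passing tests therefore show
the estimators work when the model's generative assumptions hold; they do
not certify robustness to host-genetic control of the microbiome.

## Known limitations

* Single-regression vs back-solving p-value ranks agree strongly
  (Spearman > 0.8) when OTU are uncorrelated — the regime where the two
  estimands coincide — but drop to ~0.6–0.8 under strong community
  structure, where a marginal and a joint method genuinely differ on null
  OTU; effect estimates still correlate > 0.9 and top hits are shared.
* Bivariate fits require complete records on both traits.
* Posterior means of weakly identified ratios carry flat-prior bias;
  report posterior SDs alongside, as the summaries do.
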