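# Methods

## The observation model and its estimator

The package estimates variance components of the two-level nested mixed
model

    y_ijkl = μ + B_i + S_j + D_k(j) + e_ijkl

for a paternal half-sib design: each sire (pollen donor) mated to several
unique dams, each cross contributing several offspring, offspring split
across field blocks. Sire effects are MVN(0, Σ_S), dam effects
MVN(0, Σ_D), residuals MVN(0, Σ_E); intercept and block are fixed
effects with flat priors. Half-sib theory identifies the additive genetic
covariance as G = 4 Σ_S; the dam component absorbs maternal and dominance
contributions and is not interpreted further.

Estimation is a blocked Gibbs sampler with fully conjugate updates:

1. fixed effects from their matrix-normal conditional
   (vec B ~ N(vec B̂, Σ_E ⊗ (XᵀX)⁻¹));
2. sire effects jointly per sire, u_j ~ N(A_j Σ_E⁻¹ r_j, A_j) with
   A_j = (Σ_S⁻¹ + n_j Σ_E⁻¹)⁻¹ and r_j the summed residuals of the
   sire's offspring (vectorized over sires sharing a group size);
3. dam effects analogously;
4. Σ_S, Σ_D, Σ_E from inverse-Wishart conditionals.

The univariate fit is the same code at p = 1, where the inverse-Wishart
reduces to a scaled inverse chi-squared.

**Priors.** Sire and dam covariances use an inverse-Wishart with degree
of belief ν = p − 0.998 and scale ν·V, where the location V is P/4 by
default (P = observed phenotypic covariance of the rows used);
alternatives `half_P` (V = P/2) and `diagonal` (V = diag(P)/4) support
prior-sensitivity checks. The residual location is P/2. At this small ν
the formal inverse-Wishart mean does not exist; "location" is the prior
parameter in the MCMCglmm sense (scale = V·ν), which is the convention
this class of analyses actually uses. No parameter expansion is
implemented; chains stuck near zero are the user's cue to consult the
diagnostics report (PSRF across independent fits, lag-k autocorrelation,
Geyer initial-monotone ESS). The PSRF is the classic Gelman–Rubin
statistic clipped below at 1, so identical chains report exactly 1.

**Chain schedule.** `MCMCConfig` separates burn-in from post-burn-in
iterations; retained draws are always `post_burn_iterations / thin`. The
defaults mirror a full-scale field analysis (200k/500k burn-in,
5,000,000 post-burn-in iterations thinned by 500 → 10,000 draws); tests
and examples use far shorter schedules (hundreds to thousands of
iterations), which the conjugate sampler's low autocorrelation makes
adequate at the fixture sizes used — those sizes are stated with each
experiment below.

**Missing data.** Default handling is complete-case: trait-wise for
univariate fits, row-wise for multivariate fits. An optional
data-augmentation mode (`missing="augment"`) imputes missing cells each
iteration from their conditional normal given the observed cells of the
same row, grouped by missingness pattern.

**Standardization.** `standardize_traits` divides each trait by its
global (all populations pooled) standard deviation and records the SDs.
Fits on standardized data yield G in SD² units; selection responses are
reported in SD units and back-transformed to trait units by multiplying
by the recorded SDs.

## The synthetic-data generator

`make_design` + `simulate_phenotypes` + `apply_attrition` generate the
exact generative inverse of the model above: per-sire effects from
MVN(0, G/4), per-dam effects from MVN(0, D), per-individual residuals
from MVN(0, E), additive block offsets, then i.i.d. Bernoulli row
attrition and per-trait masking. Defaults describe a six-population,
50-sire × 3-dam × 3-offspring × 3-block field experiment (900 crosses,
2700 plants):

* trait means (12 cm early height, 85 cm final height, 18 branches,
  62 days to flower, 35 cm inflorescence, 2.5 g seed mass) and SDs
  (4, 20, 6, 8, 12, 1) chosen as realistic values for an annual weed;
* one positive, moderate correlation structure C shared by all
  components: P = S·C·S, G = 0.4·P (h² = 0.4 for every trait),
  D = G/4, E = P − G/2, so V_S + V_D + V_E = P exactly;
* all populations share this architecture — the no-divergence scenario —
  unless the caller supplies per-population parameters;
* attrition 0.30 (2700 → ≈1900 survivors, keeping the number of
  families per trait in the observed-study range) and 5% per-trait
  missingness; block offsets ±0.25 phenotypic SD.

What the generator does **not** emulate: spatially structured mortality
(attrition is i.i.d.), genotype-by-environment interaction, non-Gaussian
traits (branch number and flowering date are simulated as continuous),
selection during the experiment, and linkage/pedigree structure beyond
the two-level nesting. Passing tests therefore demonstrate estimator
correctness under the stated model, not robustness to these real-data
features.

Block assignment is a balanced round-robin within each sire-dam family
with the starting block rotated by family index; it is deterministic, and
the `seed` argument exists for interface symmetry.

## Permutation null

Trait records are shuffled jointly (whole rows of trait values move
together) across individuals within each population, preserving every
marginal distribution and the pooled phenotypic covariance exactly while
destroying sire, dam and block associations. Per-trait independent
shuffling is available behind a flag for sensitivity analysis.
`build_null` spawns per-dataset sub-seeds from the master seed with
`SeedSequence`, so any single permutation is replayable in isolation;
failing refits are logged and excluded with a count rather than aborting
the run. Null refits default to chains shortened 10× (same retained-draw
count, shorter schedule), announced with a warning.

HPD intervals are empirical shortest-contiguous intervals (sort, slide a
window of ⌈probability·n⌉ samples, take the narrowest).

## Comparison statistics: numerical choices

* **Eigenvector signs** everywhere follow the largest-|component|-positive
  convention; eigenvalues are sorted descending — identical-matrix
  fixtures hit exact ties, which this ordering resolves reproducibly.
* **Krzanowski**: k defaults to ⌊p/2⌋. H's eigenvalue posterior is
  computed per draw; an eigenvector is called diverged only if its
  posterior-mean eigenvalue is both below the attainable maximum p and
  below the lower bound of the null 95% HPD (per-draw H eigenvalues
  pooled over permuted datasets).
* **Tensor**: G matrices are vectorized over unique elements with √2
  off-diagonal weights (Frobenius-norm preserving); S is the
  across-population covariance of these vectors per draw, ddof = 1. The
  eigenstructure is taken from the posterior-mean S; per-draw alphas are
  quadratic-form projections of each draw's S onto that fixed basis
  (avoiding label switching across draws). The null band is one alpha
  spectrum per randomized dataset, computed from that dataset's
  posterior-mean S — the same estimator as the observed point value;
  an eigentensor is significant when its observed alpha exceeds the null
  HPD's upper bound. Identical populations short-circuit to a
  "no variation" result (all eigenvalues zero) instead of dividing by a
  zero trace. Population coordinates are Frobenius inner products of
  centered posterior-mean G with each eigentensor and sum to zero by
  construction.
* **Breeder's equation**: Δz̄ = Gβ per draw; a posterior β is paired
  index-by-index with the G draws and the counts must match.
* **R metric**: the rate of adaptation is the change in mean fitness
  βᵀGβ (Lande identity), so R = βᵀGβ / βᵀG₀β with G₀ = diag(G) per
  draw; zero-denominator draws are excluded and counted. Summaries are
  the mean and 5th/95th percentiles. R is invariant to positive
  rescaling of both β and G.
* **Skewers**: 1000 skewers by default, drawn uniformly on the unit
  sphere (normalized Gaussians), applied to the posterior-mean G of each
  population; per-draw skewers would multiply cost ~10³ without changing
  the pairwise summaries at the sizes used here. Pair similarity is
  judged against the 95th percentile of correlations between independent
  random unit vectors of the same dimension (Cheverud's criterion);
  permuted-data G matrices are *not* a usable skewer null, because
  prior-dominated null fits are nearly proportional across populations
  and correlate more strongly than the observed matrices.

## Selection gradients

Sire means are pooled globally (one regression, not per population) so
that downstream response differences are attributable to G alone. Raw
fitness proxies are relativized by their grand mean before regression;
the composite fitness score — PC1 of the two proxies on their
correlation matrix, sign-anchored to correlate positively with seed
mass — is centered by construction and therefore enters unrelativized
(the estimators refuse to relativize a ~zero-mean fitness column). The
Bayesian variant is a conjugate Zellner g-prior regression (g = n,
unit-information) sampled directly: σ² from its inverse-gamma marginal,
β from its conditional normal; 10,000 draws by default. Quadratic or
correlational gradients are out of scope.

## Pipeline

`Pipeline` fans a single master seed out to the stages
(simulate, fit, nulls, selection, compare) via `SeedSequence.spawn` in a
fixed order, so adding a stage never perturbs earlier streams; each
stage's effective seed and status land in `manifest.json`, and re-running
with the same config and seed reproduces `summary.json` byte for byte.
Null heritability bands in the pipeline are derived from the diagonals
of the multivariate null fits (h² = 4S_jj/(S_jj+D_jj+E_jj)) rather than
separate univariate null fits, which would triple the refit cost for the
same comparison. Artifacts are plain CSV/JSON plus HDF5 for posterior
draw arrays; no figures are emitted.

## Experiment sizes used by the test suite

Chosen as the package's own desk-scale study conditions:

* generative recovery / oracle equivalence: 200 sires × 5 dams × 10
  offspring, 2500-iteration chains; posterior means agree with the
  balanced nested-ANOVA moment estimator within 10% and with the
  generating values within 3 Monte-Carlo SEs of the realized component
  variances;
* credible-interval coverage: 20 replicates of 100 sires × 3 × 3 with
  1000-iteration chains; ≥ 90% of 95% HPD intervals cover the true G
  elements;
* specificity: 3 replicates of 6 populations × 30 sires sharing one true
  G, 12 permutation null datasets each; all five comparison statistics
  together produce ≥ 90% "no divergence" calls;
* type-I calibration of the permutation null: 50 replicates × 150
  permutations with a moment statistic.

## Known limitations

* No pedigree/animal-model solver beyond the sire/dam nesting; no REML.
* The ANOVA oracle requires balanced complete data and ignores block
  structure — it is a test oracle, not a production estimator.
* Heritability can exceed 1 by construction (V_A = 4V_S); the package
  reports it as computed.
* Tensor significance compares proportion spectra; with very different
  retained-draw counts between observed and null fits the spectra are
  not exchangeable — keep the retained count matched (the default
  null-chain scaling does).
* Non-Gaussian traits (counts, dates) are modelled as Gaussian.
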