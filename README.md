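# gmatkit

Quantitative-genetic estimation and comparison of **additive genetic
covariance matrices (G)** from nested paternal half-sib breeding designs,
with a simulation engine, a Bayesian Gibbs sampler, permutation-based
null distributions, and the standard suite of G-matrix comparison
statistics.

## Who this is for

Evolutionary ecologists running half-sib common-garden experiments —
e.g. comparing the adaptive potential of native and introduced plant
populations — who need to go from an individual-level phenotype table
(population, block, sire, dam, traits) to per-population G matrices and
defensible statements about whether those matrices differ.

## The model

Each offspring *l* of dam *k* nested within sire *j*, grown in block *i*,
is modelled as

```
y_ijkl = μ + B_i + S_j + D_k(j) + e_ijkl
```

with sire effects S ~ MVN(0, Σ_S), dam effects D ~ MVN(0, Σ_D), residuals
e ~ MVN(0, Σ_E) and fixed block effects. Because paternal half-sibs share
a quarter of their additive effects, **G = 4 Σ_S**; univariate narrow-sense
heritability is h² = 4 V_S / (V_S + V_D + V_E), which equals 1 exactly when
the sire fraction of phenotypic variance is 0.25 (and can exceed 1 by
sampling error). All three covariances get conjugate inverse-Wishart priors
(sire/dam location P/4, degree of belief ν = n − 0.998) and are updated by
Gibbs sampling.

Because variance components are bounded below by zero, significance is
assessed against a permutation null: trait records are shuffled across
individuals within each population (destroying family structure, conserving
marginals and the pooled P matrix) and every estimator is re-run on each
permuted dataset.

G matrices are compared five ways:

* **Krzanowski common subspace** — H = Σ_t A_t A_tᵀ over the leading
  k = ⌊n_traits/2⌋ eigenvectors of each population's G; eigenvalues of H
  lie in [0, p] and reach p (the number of populations) only for
  directions shared by all.
* **Fourth-order covariance tensor** — S = cov of vectorized G elements
  across populations, eigendecomposed into eigentensors whose own
  eigenvectors name the trait combinations driving divergence.
* **Multivariate breeder's equation** — Δz̄ = Gβ per posterior draw.
* **R metric** — (βᵀGβ)/(βᵀG₀β) with off-diagonals of G₀ zeroed: R > 1
  means covariances accelerate adaptation, R < 1 means they constrain it.
* **Random skewers** — similarity of responses G·s to random unit
  selection vectors s.

Selection gradients β come from a multiple regression of (relative)
fitness on sire-mean traits — OLS or a conjugate Bayesian regression —
with a composite fitness score available as PC1 of the male (total
inflorescence length) and female (seed mass) proxies.

## Worked example

```python
import numpy as np
import gmatkit as gk

design = gk.make_design(n_populations=2, n_sires=40, n_dams_per_sire=3,
                        n_offspring_per_dam=3, n_blocks=3, seed=0)
params = gk.default_params(attrition_rate=0.1, missing_rate_per_trait=0.02, seed=1)
table = gk.apply_attrition(gk.simulate_phenotypes(design, params),
                           params.attrition_rate, params.missing_rate_per_trait, seed=2)

std, sds = gk.standardize_traits(table)
cfg = gk.MCMCConfig(burn_in=500, post_burn_iterations=2000, thin=4, seed=3)
posts = {p: gk.fit_multivariate(std, p, cfg) for p in ("P1", "P2")}

uni = gk.fit_univariate(std, "final_height", "P1",
                        gk.MCMCConfig(burn_in=500, post_burn_iterations=2000, thin=4, seed=4))
lo, hi = gk.hpd(uni.h2)
print(f"h2(final_height, P1) = {uni.h2.mean():.2f}  95% HPD [{lo:.2f}, {hi:.2f}]")

sub = gk.krzanowski_subspace({p: posts[p].G_draws for p in posts})
print("H eigenvalues:", np.round(sub.eigenvalue_mean, 2))

sm = gk.sire_means(std)
sm["composite_fitness"], _ = gk.composite_fitness(sm)
beta = gk.estimate_beta_point(sm, "composite_fitness", relativize=False).beta
for p in posts:
    sp = posts[p].subset_traits(list(gk.FOCAL_TRAITS))
    r = gk.r_metric(sp.G_draws, beta, population=p)
    print(f"R({p}) = {r.mean:.2f}  [5th, 95th] = [{r.pct5:.2f}, {r.pct95:.2f}]")
```

prints

```
h2(final_height, P1) = 0.40  95% HPD [0.02, 0.76]
H eigenvalues: [1.99 1.89 1.43 0.57 0.11 0.01]
R(P1) = 1.99  [5th, 95th] = [1.40, 2.56]
R(P2) = 1.90  [5th, 95th] = [1.33, 2.47]
```

The heritability posterior straddles the simulated truth (h² = 0.4 by
construction of the default architecture). The leading H eigenvalues sit
near 2 — the number of populations compared — so the subspaces holding
most genetic variance are shared, as expected for two populations
simulated from one G. R ≈ 2 says the (positive) genetic covariances
roughly double the rate of adaptation under the estimated gradient,
because selection on the size traits is concordant with their positive
genetic correlations.

The same analysis runs end-to-end from a YAML config via the CLI:

```sh
gmatkit all config.yaml     # or: simulate / fit / nulls / compare / report
```

writing `phenotypes.csv`, `posteriors.h5`, `heritability*.csv`,
`comparisons.json` and a consolidated `summary.json` plus a stage
manifest with per-stage seeds for exact replay.

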