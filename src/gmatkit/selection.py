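"""Directional selection gradients from sire means and fitness proxies.

Selection is estimated once, globally (sire means pooled across all
populations), so that differences in predicted responses among
populations reflect differences in G alone.  Fitness is relativized by
its grand mean before regression (Lande–Arnold convention), and the
composite fitness score is the first principal component of the two
proxies computed on their correlation matrix (the proxies are in
incommensurable units).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .tables import FITNESS_TRAITS, FOCAL_TRAITS, trait_columns

COMPOSITE_FITNESS = "composite_fitness"


@dataclass
class SelectionGradient:
    """Partial regression coefficients of relative fitness on traits."""

    beta: pd.Series                 # point estimate (posterior mean if Bayesian)
    mode: str                       # "point" | "posterior"
    fitness_metric: str
    draws: pd.DataFrame | None = None   # (n_draws, traits) when mode == "posterior"
    n_sires: int = 0

    @property
    def traits(self) -> list[str]:
        return list(self.beta.index)

    @property
    def n_draws(self) -> int:
        return 0 if self.draws is None else len(self.draws)


def sire_means(table: pd.DataFrame, traits: list[str] | None = None) -> pd.DataFrame:
    """Per-sire arithmetic trait means over non-missing offspring values.

    One row per sire with its population label, per-trait means, and
    offspring count.  A sire with no scored offspring for a trait gets a
    missing mean but keeps its row.
    """
    if table.empty:
        raise ValueError("cannot compute sire means of an empty table")
    traits = traits or trait_columns(table)
    grp = table.groupby(["population", "sire"], sort=True)
    means = grp[traits].mean()
    means["n_offspring"] = grp.size()
    return means.reset_index()


def composite_fitness(
    sire_mean_table: pd.DataFrame,
    proxies: tuple[str, str] = tuple(FITNESS_TRAITS),
) -> tuple[pd.Series, float]:
    """First principal component of the two fitness proxies, per sire.

    The PCA is computed on the correlation matrix (unit-variance scores),
    and the sign is fixed so the score correlates positively with the
    second proxy (seed mass, the female-fitness proxy) — and in practice
    with both, since the leading component of a 2x2 correlation matrix
    with positive correlation loads positively on both variables.
    Returns (scores aligned to the input rows, proportion of variance
    explained by the component).
    """
    a, b = proxies
    complete = sire_mean_table[[a, b]].dropna()
    if len(complete) < 3:
        raise ValueError("composite fitness needs both proxies for >= 3 sires")
    sd = complete.std(ddof=1)
    if (sd == 0).any():
        zero = sd.index[sd == 0].tolist()
        raise ValueError(f"zero variance in fitness proxy: {zero}")
    z = (complete - complete.mean()) / sd
    corr = np.corrcoef(z[a], z[b])
    w, v = np.linalg.eigh(corr)
    pc1 = v[:, -1]
    score = z.to_numpy() @ pc1
    if np.corrcoef(score, complete[b])[0, 1] < 0:
        score = -score
    explained = float(w[-1] / w.sum())
    out = pd.Series(np.nan, index=sire_mean_table.index, name=COMPOSITE_FITNESS)
    out.loc[complete.index] = score
    return out, explained


def _design(sire_mean_table, fitness_column, traits, relativize):
    cols = list(traits) + [fitness_column]
    data = sire_mean_table[cols].dropna()
    n = len(data)
    if n <= len(traits) + 1:
        raise ValueError(
            f"need more sires ({n}) than traits + 1 ({len(traits) + 1}) for the regression"
        )
    w = data[fitness_column].to_numpy(dtype=float)
    if relativize:
        wbar = w.mean()
        if abs(wbar) < 1e-9 * max(1.0, float(np.std(w))):
            raise ValueError(
                "mean fitness is ~zero; relativization is only meaningful for "
                "positive fitness components (use relativize=False for "
                "centered scores such as the composite PC1)"
            )
        w = w / wbar
    X = sm.add_constant(data[list(traits)].to_numpy(dtype=float))
    return X, w, n


_CONDITION_LIMIT = 1e8


def estimate_beta_point(
    sire_mean_table: pd.DataFrame,
    fitness_column: str,
    traits: list[str] | None = None,
    relativize: bool = True,
) -> SelectionGradient:
    """OLS multiple regression of relative fitness on the focal traits.

    Returns the partial regression coefficients (the directional
    selection gradient); the intercept is fitted but not reported.  A
    badly conditioned design triggers a warning, not an error.
    """
    traits = traits or [t for t in FOCAL_TRAITS if t in sire_mean_table.columns]
    X, w, n = _design(sire_mean_table, fitness_column, traits, relativize)
    if np.linalg.cond(X) > _CONDITION_LIMIT:
        warnings.warn("selection-gradient design is nearly collinear", stacklevel=2)
    fit = sm.OLS(w, X).fit()
    beta = pd.Series(fit.params[1:], index=traits, name="beta")
    return SelectionGradient(beta=beta, mode="point",
                             fitness_metric=fitness_column, n_sires=n)


def estimate_beta_bayes(
    sire_mean_table: pd.DataFrame,
    fitness_column: str,
    n_draws: int = 10_000,
    seed: int = 0,
    traits: list[str] | None = None,
    relativize: bool = True,
    g: float | None = None,
) -> SelectionGradient:
    """Bayesian regression posterior for the selection gradient.

    Conjugate normal–inverse-gamma setup with a Zellner g-prior
    (beta | sigma^2 ~ N(0, g sigma^2 (X'X)^-1), p(sigma^2) ∝ 1/sigma^2;
    g defaults to n, the unit-information prior), sampled directly:
    sigma^2 from its inverse-gamma marginal, then beta from its
    conditional normal.  With this weak prior the posterior mean is the
    OLS estimate shrunk by g/(1+g).
    """
    traits = traits or [t for t in FOCAL_TRAITS if t in sire_mean_table.columns]
    X, w, n = _design(sire_mean_table, fitness_column, traits, relativize)
    if np.linalg.cond(X) > _CONDITION_LIMIT:
        warnings.warn("selection-gradient design is nearly collinear", stacklevel=2)
    if g is None:
        g = float(n)
    rng = np.random.default_rng(seed)

    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    bhat = XtX_inv @ (X.T @ w)
    resid = w - X @ bhat
    ssr = float(resid @ resid)
    quad = float(bhat @ XtX @ bhat)
    shrink = g / (1.0 + g)

    a_post = n / 2.0
    b_post = 0.5 * (ssr + quad / (1.0 + g))
    sigma2 = stats.invgamma.rvs(a_post, scale=b_post, size=n_draws, random_state=rng)
    L = np.linalg.cholesky(shrink * XtX_inv)
    z = rng.standard_normal((n_draws, X.shape[1]))
    draws_all = shrink * bhat + np.sqrt(sigma2)[:, None] * (z @ L.T)
    draws = pd.DataFrame(draws_all[:, 1:], columns=traits)
    beta = pd.Series(draws.mean().to_numpy(), index=traits, name="beta")
    return SelectionGradient(beta=beta, mode="posterior",
                             fitness_metric=fitness_column,
                             draws=draws, n_sires=n)
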