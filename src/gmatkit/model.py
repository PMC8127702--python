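"""Bayesian variance-component estimation for nested half-sib designs.

The observation model for individual *l* of dam *k* nested in sire *j*,
grown in block *i*, is

    y_ijkl = mu + B_i + S_j + D_k(j) + e_ijkl

with S_j ~ MVN(0, Sigma_S), D_k ~ MVN(0, Sigma_D), e ~ MVN(0, Sigma_E)
and flat priors on the fixed effects (intercept and block).  All three
covariance components receive conjugate inverse-Wishart priors and are
updated by Gibbs sampling; the additive genetic covariance matrix is
G = 4 Sigma_S (half-sib theory).  A method-of-moments nested-ANOVA
estimator is provided as an independent oracle for balanced designs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import h5py
import numpy as np
import pandas as pd
from scipy import stats

from .tables import DESIGN_COLUMNS, trait_columns


class DegenerateDesignError(ValueError):
    """Raised when the grouping structure cannot identify the components."""


# ---------------------------------------------------------------------------
# configuration


@dataclass
class MCMCConfig:
    """Chain schedule and prior for the Gibbs sampler.

    ``post_burn_iterations`` are the iterations run after burn-in; every
    ``thin``-th of them is retained, so the retained draw count is always
    ``post_burn_iterations / thin``.  ``prior_scale_mode`` selects the
    inverse-Wishart prior location for the sire and dam covariances
    relative to the observed phenotypic covariance P (``quarter_P``,
    ``half_P`` or ``diagonal`` = diag(P)/4); the residual prior location
    is P/2 throughout.  The degree of belief is
    nu = n_traits - prior_df_offset, and the prior scale matrix is
    nu * location (the parameterization used by MCMCglmm-style priors,
    where the location is the prior "expectation" in the software sense;
    the formal inverse-Wishart mean does not exist at this small nu).
    """

    burn_in: int = 500_000
    post_burn_iterations: int = 5_000_000
    thin: int = 500
    prior_scale_mode: str = "quarter_P"
    prior_df_offset: float = 0.998
    seed: int = 0

    _MODES = ("quarter_P", "half_P", "diagonal")

    def __post_init__(self) -> None:
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if self.thin < 1 or self.post_burn_iterations < 1:
            raise ValueError("thin and post_burn_iterations must be >= 1")
        if self.post_burn_iterations % self.thin:
            raise ValueError("thin must divide post_burn_iterations")
        if self.prior_scale_mode not in self._MODES:
            raise ValueError(f"prior_scale_mode must be one of {self._MODES}")

    @property
    def n_retained(self) -> int:
        return self.post_burn_iterations // self.thin

    @classmethod
    def univariate_default(cls, **kw) -> "MCMCConfig":
        kw.setdefault("burn_in", 200_000)
        return cls(**kw)

    @classmethod
    def multivariate_default(cls, **kw) -> "MCMCConfig":
        return cls(**kw)

    def scaled(self, factor: float) -> "MCMCConfig":
        """A schedule shortened by *factor* (used for permutation-null refits)."""
        thin = max(1, int(round(self.thin / factor)))
        post = max(thin, int(round(self.post_burn_iterations / factor)))
        post -= post % thin
        return MCMCConfig(
            burn_in=max(1, int(round(self.burn_in / factor))),
            post_burn_iterations=post, thin=thin,
            prior_scale_mode=self.prior_scale_mode,
            prior_df_offset=self.prior_df_offset, seed=self.seed,
        )


# ---------------------------------------------------------------------------
# posterior containers


def heritability(v_s, v_d, v_e):
    """Narrow-sense heritability h² = 4 V_S / (V_S + V_D + V_E).

    The factor 4 is the half-sib relationship: V_A = 4 V_S.  Values above
    1 are possible (and returned) whenever V_S exceeds a quarter of the
    phenotypic variance.  Vectorized over posterior draws.
    """
    v_s, v_d, v_e = (np.asarray(v, dtype=float) for v in (v_s, v_d, v_e))
    v_p = v_s + v_d + v_e
    if np.any(v_p <= 0):
        raise ValueError("phenotypic variance must be positive")
    return 4.0 * v_s / v_p


@dataclass
class VarianceComponents:
    """Point estimates of the univariate components (oracle output)."""

    V_S: float
    V_D: float
    V_E: float
    truncated: bool = False

    @property
    def V_A(self) -> float:
        return 4.0 * self.V_S

    @property
    def V_P(self) -> float:
        return self.V_S + self.V_D + self.V_E

    @property
    def h2(self) -> float:
        return float(heritability(self.V_S, self.V_D, self.V_E))


@dataclass
class UnivariatePosterior:
    """Retained Gibbs draws of (V_S, V_D, V_E) for one trait/population."""

    population: str
    trait: str
    V_S: np.ndarray
    V_D: np.ndarray
    V_E: np.ndarray

    @property
    def V_A(self) -> np.ndarray:
        return 4.0 * self.V_S

    @property
    def h2(self) -> np.ndarray:
        return heritability(self.V_S, self.V_D, self.V_E)

    @property
    def n_draws(self) -> int:
        return self.V_S.size

    def posterior_mean(self) -> VarianceComponents:
        return VarianceComponents(float(self.V_S.mean()), float(self.V_D.mean()),
                                  float(self.V_E.mean()))


@dataclass
class GMatrixPosterior:
    """Retained draws of the sire/dam/residual covariances for one population.

    ``G_draws`` is derived as 4x the sire covariance draws.  When the fit
    was run on standardized traits, ``standardization`` records the
    per-trait global SDs that were divided out (else ``None``).
    """

    population: str
    traits: list[str]
    S_draws: np.ndarray  # (n_draws, p, p)
    D_draws: np.ndarray
    E_draws: np.ndarray
    standardization: dict[str, float] | None = None

    @property
    def n_draws(self) -> int:
        return self.S_draws.shape[0]

    @property
    def n_traits(self) -> int:
        return self.S_draws.shape[1]

    @property
    def G_draws(self) -> np.ndarray:
        return 4.0 * self.S_draws

    @property
    def P_draws(self) -> np.ndarray:
        return self.S_draws + self.D_draws + self.E_draws

    def mean_G(self) -> np.ndarray:
        return self.G_draws.mean(axis=0)

    def subset_traits(self, traits: list[str]) -> "GMatrixPosterior":
        idx = [self.traits.index(t) for t in traits]
        ix = np.ix_(idx, idx)
        std = None
        if self.standardization is not None:
            std = {t: self.standardization[t] for t in traits}
        return GMatrixPosterior(
            self.population, list(traits),
            self.S_draws[:, *ix], self.D_draws[:, *ix], self.E_draws[:, *ix],
            standardization=std,
        )

    def flat_params(self) -> tuple[np.ndarray, list[str]]:
        """Unique G elements as an (n_draws, p(p+1)/2) array, for diagnostics."""
        p = self.n_traits
        iu = np.triu_indices(p)
        names = [f"G[{self.traits[i]},{self.traits[j]}]" for i, j in zip(*iu)]
        return self.G_draws[:, iu[0], iu[1]], names

    def summary(self, probability: float = 0.95) -> pd.DataFrame:
        from .permutation import hpd
        rows = []
        iu = np.triu_indices(self.n_traits)
        for i, j in zip(*iu):
            draws = self.G_draws[:, i, j]
            lo, hi = hpd(draws, probability)
            rows.append({
                "population": self.population,
                "trait_i": self.traits[i], "trait_j": self.traits[j],
                "mean": draws.mean(), "hpd_low": lo, "hpd_high": hi,
            })
        return pd.DataFrame(rows)


def save_posteriors(posteriors: Iterable[GMatrixPosterior], path: str | Path) -> None:
    """Serialize per-population G posteriors to HDF5 (one group per population)."""
    with h5py.File(path, "w") as f:
        for post in posteriors:
            g = f.create_group(post.population)
            g.attrs["traits"] = post.traits
            for name in ("S_draws", "D_draws", "E_draws"):
                g.create_dataset(name, data=getattr(post, name))
            if post.standardization is not None:
                g.attrs["sd_traits"] = list(post.standardization)
                g.attrs["sd_values"] = [post.standardization[t] for t in post.standardization]


def load_posteriors(path: str | Path) -> dict[str, GMatrixPosterior]:
    out = {}
    with h5py.File(path, "r") as f:
        for pop in f:
            g = f[pop]
            std = None
            if "sd_traits" in g.attrs:
                std = dict(zip([str(t) for t in g.attrs["sd_traits"]],
                               [float(v) for v in g.attrs["sd_values"]]))
            out[pop] = GMatrixPosterior(
                pop, [str(t) for t in g.attrs["traits"]],
                g["S_draws"][()], g["D_draws"][()], g["E_draws"][()],
                standardization=std,
            )
    return out


# ---------------------------------------------------------------------------
# trait standardization


def standardize_traits(
    table: pd.DataFrame, traits: list[str] | None = None
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Divide each trait by its global (all populations pooled) SD.

    Returns the rescaled table and the SD record needed to back-transform
    derived quantities (e.g. selection responses) to trait units.
    """
    traits = traits or trait_columns(table)
    out = table.copy()
    sds: dict[str, float] = {}
    for t in traits:
        x = out[t].dropna()
        if len(x) < 2:
            raise ValueError(f"trait {t!r} has fewer than 2 non-missing values")
        sd = float(x.std(ddof=1))
        if sd == 0:
            raise ValueError(f"trait {t!r} has zero variance; cannot standardize")
        out[t] = out[t] / sd
        sds[t] = sd
    return out, sds


# ---------------------------------------------------------------------------
# Gibbs sampler core


def _prior_scales(P: np.ndarray, config: MCMCConfig) -> tuple[float, np.ndarray, np.ndarray]:
    p = P.shape[0]
    nu = p - config.prior_df_offset
    if nu <= p - 1:
        raise ValueError("prior degree of belief too small for a proper inverse-Wishart")
    if config.prior_scale_mode == "quarter_P":
        V_sd = P / 4.0
    elif config.prior_scale_mode == "half_P":
        V_sd = P / 2.0
    else:  # diagonal
        V_sd = np.diag(np.diag(P)) / 4.0
    return nu, nu * V_sd, nu * (P / 2.0)


def _group_bounds(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start offsets and sizes of contiguous groups in sorted *codes*."""
    starts = np.flatnonzero(np.r_[True, codes[1:] != codes[:-1]])
    sizes = np.diff(np.r_[starts, codes.size])
    return starts, sizes


def _draw_effects(rng, sums, sizes, Sigma_inv, E_inv):
    """Draw group effects u_g ~ N(A_g E_inv sum_g, A_g), A_g = (Sigma_inv + n_g E_inv)^-1.

    Vectorized over groups sharing the same size.
    """
    p = E_inv.shape[0]
    out = np.empty((sums.shape[0], p))
    z = rng.standard_normal(out.shape)
    for n in np.unique(sizes):
        A = np.linalg.inv(Sigma_inv + n * E_inv)
        A = (A + A.T) / 2.0
        L = np.linalg.cholesky(A)
        sel = sizes == n
        out[sel] = sums[sel] @ (A @ E_inv).T + z[sel] @ L.T
    return out


def _impute_missing(rng, Y, miss, mu_rows, Sigma_E):
    """Conditional-normal draw of missing cells given observed cells per row."""
    patterns = {}
    for r in np.flatnonzero(miss.any(axis=1)):
        patterns.setdefault(tuple(miss[r]), []).append(r)
    for pat, rows in patterns.items():
        rows = np.asarray(rows)
        m = np.asarray(pat)
        o = ~m
        S_oo = Sigma_E[np.ix_(o, o)]
        S_mo = Sigma_E[np.ix_(m, o)]
        S_mm = Sigma_E[np.ix_(m, m)]
        if o.any():
            K = np.linalg.solve(S_oo, S_mo.T).T
            cond_cov = S_mm - K @ S_mo.T
            resid_o = Y[np.ix_(rows, np.flatnonzero(o))] - mu_rows[np.ix_(rows, np.flatnonzero(o))]
            cond_mean = mu_rows[np.ix_(rows, np.flatnonzero(m))] + resid_o @ K.T
        else:
            cond_cov = S_mm
            cond_mean = mu_rows[np.ix_(rows, np.flatnonzero(m))]
        cond_cov = (cond_cov + cond_cov.T) / 2.0
        L = np.linalg.cholesky(cond_cov + 1e-12 * np.eye(m.sum()))
        draws = cond_mean + rng.standard_normal(cond_mean.shape) @ L.T
        Y[np.ix_(rows, np.flatnonzero(m))] = draws


def _invwishart_rvs(rng, df: float, scale: np.ndarray) -> np.ndarray:
    S = stats.invwishart.rvs(df=df, scale=scale, random_state=rng)
    S = np.atleast_2d(S)
    return (S + S.T) / 2.0


def _gibbs_nested(Y, X, sire_codes, dam_codes, config: MCMCConfig,
                  miss: np.ndarray | None = None):
    """Run the Gibbs sampler on pre-sorted data; returns retained draws.

    Rows must be sorted so sire and dam groups are contiguous (dams nested
    within sires).  ``miss`` marks cells to be data-augmented; if None the
    data are treated as complete.
    """
    rng = np.random.default_rng(config.seed)
    n, p = Y.shape
    Y = Y.copy()

    s_starts, s_sizes = _group_bounds(sire_codes)
    d_starts, d_sizes = _group_bounds(dam_codes)
    n_sires, n_dams = s_sizes.size, d_sizes.size
    dam_sire = sire_codes[d_starts]  # sire index of each dam

    if miss is not None and miss.any():
        # initialize missing cells at trait means of observed cells
        col_means = np.nanmean(np.where(miss, np.nan, Y), axis=0)
        Y[miss] = np.broadcast_to(col_means, Y.shape)[miss]
    else:
        miss = None

    P = np.cov(Y, rowvar=False, ddof=1).reshape(p, p)
    nu, Psi_sd, Psi_e = _prior_scales(P, config)

    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    Lx = np.linalg.cholesky((XtX_inv + XtX_inv.T) / 2.0)
    q = X.shape[1]

    if config.prior_scale_mode == "diagonal":
        Sigma_S = np.diag(np.diag(P)) / 4.0
        Sigma_D = Sigma_S.copy()
    else:
        Sigma_S = P / 4.0
        Sigma_D = P / 4.0
    Sigma_E = P / 2.0
    U_s = np.zeros((n_sires, p))
    U_d = np.zeros((n_dams, p))
    B = XtX_inv @ (X.T @ Y)

    m = config.n_retained
    S_out = np.empty((m, p, p))
    D_out = np.empty((m, p, p))
    E_out = np.empty((m, p, p))

    total = config.burn_in + config.post_burn_iterations
    rec = 0
    for it in range(1, total + 1):
        E_inv = np.linalg.inv(Sigma_E)

        # fixed effects (flat prior): matrix-normal conditional
        R = Y - U_s[sire_codes] - U_d[dam_codes]
        B_hat = XtX_inv @ (X.T @ R)
        L_E = np.linalg.cholesky(Sigma_E)
        B = B_hat + Lx @ rng.standard_normal((q, p)) @ L_E.T
        XB = X @ B

        # sire effects
        R = Y - XB - U_d[dam_codes]
        sums = np.add.reduceat(R, s_starts, axis=0)
        U_s = _draw_effects(rng, sums, s_sizes, np.linalg.inv(Sigma_S), E_inv)

        # dam effects
        R = Y - XB - U_s[sire_codes]
        sums = np.add.reduceat(R, d_starts, axis=0)
        U_d = _draw_effects(rng, sums, d_sizes, np.linalg.inv(Sigma_D), E_inv)

        # covariance components
        Sigma_S = _invwishart_rvs(rng, nu + n_sires, Psi_sd + U_s.T @ U_s)
        Sigma_D = _invwishart_rvs(rng, nu + n_dams, Psi_sd + U_d.T @ U_d)
        resid = Y - XB - U_s[sire_codes] - U_d[dam_codes]
        Sigma_E = _invwishart_rvs(rng, nu + n, Psi_e + resid.T @ resid)

        if miss is not None:
            mu_rows = XB + U_s[sire_codes] + U_d[dam_codes]
            _impute_missing(rng, Y, miss, mu_rows, Sigma_E)

        if it > config.burn_in and (it - config.burn_in) % config.thin == 0:
            S_out[rec] = Sigma_S
            D_out[rec] = Sigma_D
            E_out[rec] = Sigma_E
            rec += 1

    return S_out, D_out, E_out


def _prepare(table: pd.DataFrame, traits: list[str], population: str | None,
             missing: str):
    if population is not None:
        table = table[table["population"] == population]
    if table.empty:
        raise DegenerateDesignError(f"no rows for population {population!r}")
    sub = table[DESIGN_COLUMNS + traits].copy()
    Yfull = sub[traits].to_numpy(dtype=float)
    if missing == "complete":
        keep = ~np.isnan(Yfull).any(axis=1)
        sub = sub.loc[keep]
        miss = None
    elif missing == "augment":
        keep = ~np.isnan(Yfull).all(axis=1)
        sub = sub.loc[keep]
        miss = np.isnan(sub[traits].to_numpy(dtype=float))
        if not miss.any():
            miss = None
    else:
        raise ValueError("missing must be 'complete' or 'augment'")
    if sub.empty:
        raise DegenerateDesignError("no usable rows after missing-data handling")

    sire_codes = pd.factorize(sub["sire"])[0]
    dam_codes = pd.factorize(sub["sire"].str.cat(sub["dam"], sep="\x00"))[0]
    order = np.lexsort((dam_codes, sire_codes))
    sub = sub.iloc[order]
    sire_codes = pd.factorize(sub["sire"])[0]
    dam_codes = pd.factorize(sub["sire"].str.cat(sub["dam"], sep="\x00"))[0]
    if miss is not None:
        miss = miss[order]

    n_sires = sire_codes.max() + 1
    if n_sires < 2:
        raise DegenerateDesignError("need at least 2 sires to separate V_S")
    dams_per_sire = pd.Series(sire_codes[np.r_[
        _group_bounds(dam_codes)[0]]]).value_counts()
    if (dams_per_sire >= 2).sum() < 2:
        raise DegenerateDesignError("need >= 2 sires with >= 2 dams each")

    Y = sub[traits].to_numpy(dtype=float)
    blocks = pd.Categorical(sub["block"])
    if len(blocks.categories) > 1:
        Xb = pd.get_dummies(blocks, drop_first=True).to_numpy(dtype=float)
        X = np.c_[np.ones(len(sub)), Xb]
    else:
        X = np.ones((len(sub), 1))
    if len(sub) < len(traits) + X.shape[1]:
        raise DegenerateDesignError(
            f"only {len(sub)} complete rows for {len(traits)} traits and "
            f"{X.shape[1]} fixed-effect columns"
        )
    return Y, X, sire_codes, dam_codes, miss


def fit_univariate(
    table: pd.DataFrame,
    trait: str,
    population: str | None,
    config: MCMCConfig | None = None,
    missing: str = "complete",
) -> UnivariatePosterior:
    """Gibbs sampler for one trait in one population.

    Partitions variance among sires, dams within sires and residual with
    block as a fixed effect; the conjugate updates are scaled-inverse-
    chi-squared (one-dimensional inverse-Wishart).
    """
    config = config or MCMCConfig.univariate_default()
    if table[trait].dropna().empty:
        raise DegenerateDesignError(f"trait {trait!r} is entirely missing")
    Y, X, sc, dc, miss = _prepare(table, [trait], population, missing)
    S, D, E = _gibbs_nested(Y, X, sc, dc, config, miss)
    return UnivariatePosterior(
        population if population is not None else "all", trait,
        S[:, 0, 0], D[:, 0, 0], E[:, 0, 0],
    )


def fit_multivariate(
    table: pd.DataFrame,
    population: str | None,
    config: MCMCConfig | None = None,
    traits: list[str] | None = None,
    missing: str = "complete",
    standardization: dict[str, float] | None = None,
) -> GMatrixPosterior:
    """Gibbs sampler for the full trait vector in one population.

    Returns the retained posterior draws of the sire, dam and residual
    covariance matrices; G = 4 x sire covariance per draw.  Pass the SD
    record from :func:`standardize_traits` as ``standardization`` when the
    table was standardized, so downstream results can be back-transformed.
    """
    config = config or MCMCConfig.multivariate_default()
    traits = traits or trait_columns(table)
    if len(traits) < 2:
        raise ValueError("multivariate fit needs >= 2 traits")
    Y, X, sc, dc, miss = _prepare(table, traits, population, missing)
    S, D, E = _gibbs_nested(Y, X, sc, dc, config, miss)
    return GMatrixPosterior(
        population if population is not None else "all", list(traits),
        S, D, E, standardization=standardization,
    )


# ---------------------------------------------------------------------------
# method-of-moments oracle


def anova_oracle(
    table: pd.DataFrame, trait: str, population: str | None = None
) -> VarianceComponents:
    """Nested-ANOVA moment estimator for balanced complete designs.

    With s sires, d dams/sire and n offspring/dam the expected mean
    squares give V_E = MS_W, V_D = (MS_D - MS_W)/n and
    V_S = (MS_S - MS_D)/(d n).  Negative estimates are truncated at zero
    and flagged.  Block structure is ignored, so fixtures for this oracle
    should be simulated without block effects.  Unbalanced or incomplete
    data are rejected: this is a test oracle, not a general estimator.
    """
    if population is not None:
        table = table[table["population"] == population]
    sub = table[["sire", "dam", trait]].copy()
    if sub[trait].isna().any():
        raise ValueError("anova_oracle requires complete data for the trait")
    dams_per_sire = sub.groupby("sire")["dam"].nunique()
    off_per_dam = sub.groupby(["sire", "dam"]).size()
    if dams_per_sire.nunique() != 1 or off_per_dam.nunique() != 1:
        raise ValueError("anova_oracle requires a balanced design")
    s = sub["sire"].nunique()
    d = int(dams_per_sire.iloc[0])
    n = int(off_per_dam.iloc[0])
    if s < 2 or d < 2 or n < 2:
        raise DegenerateDesignError("balanced oracle needs s, d, n all >= 2")

    y = sub[trait].to_numpy(dtype=float)
    grand = y.mean()
    sire_means = sub.groupby("sire")[trait].mean()
    dam_means = sub.groupby(["sire", "dam"])[trait].mean()

    ss_sire = d * n * float(((sire_means - grand) ** 2).sum())
    ss_dam = n * float(((dam_means - dam_means.index.get_level_values("sire").map(sire_means)) ** 2).sum())
    cell = sub.set_index(["sire", "dam"])[trait]
    ss_within = float(((cell - cell.index.map(dam_means)) ** 2).sum())

    ms_sire = ss_sire / (s - 1)
    ms_dam = ss_dam / (s * (d - 1))
    ms_within = ss_within / (s * d * (n - 1))

    v_e = ms_within
    v_d = (ms_dam - ms_within) / n
    v_s = (ms_sire - ms_dam) / (d * n)
    truncated = bool(v_d < 0 or v_s < 0)
    return VarianceComponents(max(v_s, 0.0), max(v_d, 0.0), v_e, truncated=truncated)


def anova_ss_decomposition(table: pd.DataFrame, trait: str) -> dict[str, float]:
    """Total/between-sire/between-dam/within sums of squares (identity check)."""
    sub = table[["sire", "dam", trait]].dropna()
    y = sub[trait].to_numpy(dtype=float)
    grand = y.mean()
    sire_means = sub.groupby("sire")[trait].transform("mean").to_numpy()
    dam_means = sub.groupby(["sire", "dam"])[trait].transform("mean").to_numpy()
    return {
        "total": float(((y - grand) ** 2).sum()),
        "sire": float(((sire_means - grand) ** 2).sum()),
        "dam": float(((dam_means - sire_means) ** 2).sum()),
        "within": float(((y - dam_means) ** 2).sum()),
    }
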