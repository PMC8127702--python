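"""G-matrix comparison statistics.

Five complementary views of a set of per-population G posteriors:

* Krzanowski common subspace — do the leading eigenvectors of the
  matrices span a shared subspace?  H = sum_t A_t A_t' with A_t the first
  k unit eigenvectors of population t's G; eigenvalues of H lie in
  [0, p] and reach p (the number of populations) only for directions
  common to all.
* Fourth-order genetic covariance tensor — the covariance of the G
  elements across populations, eigendecomposed into second-order
  eigentensors describing the directions of among-population divergence.
* Multivariate breeder's equation — delta_zbar = G beta per posterior draw.
* R metric — beta' G beta / beta' G0 beta with G0 the diagonal-zeroed G:
  the factor by which trait covariances speed (R > 1) or slow (R < 1)
  the rate of adaptation under gradient beta.
* Random skewers — similarity of the response vectors G s of pairs of
  populations over many random unit selection vectors s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .permutation import hpd


def _fix_sign(v: np.ndarray) -> np.ndarray:
    """Make the largest-|component| of each column positive (reproducible sign)."""
    v = np.array(v, copy=True)
    if v.ndim == 1:
        v = v[:, None]
        return _fix_sign(v)[:, 0]
    idx = np.argmax(np.abs(v), axis=0)
    signs = np.sign(v[idx, np.arange(v.shape[1])])
    signs[signs == 0] = 1.0
    return v * signs


def _as_draw_stack(G_draws_by_population: dict[str, np.ndarray]):
    pops = list(G_draws_by_population)
    arrs = [np.asarray(G_draws_by_population[p], dtype=float) for p in pops]
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    shapes = {a.shape for a in arrs}
    if len(shapes) != 1:
        raise ValueError(f"populations disagree in draw count or dimension: {shapes}")
    stack = np.stack(arrs)  # (n_pops, n_draws, p, p)
    return pops, stack


# ---------------------------------------------------------------------------
# Krzanowski common subspace


@dataclass
class SubspaceResult:
    populations: list[str]
    k: int
    H_mean: np.ndarray
    eigenvalue_draws: np.ndarray        # (n_draws, n_traits), descending
    eigenvalue_mean: np.ndarray
    eigenvalue_hpd: np.ndarray          # (n_traits, 2)
    eigenvectors: np.ndarray            # of mean H, columns, sign-fixed
    null_eigenvalue_hpd: np.ndarray | None = None
    diverged: np.ndarray | None = None  # bool per eigenvector

    @property
    def n_populations(self) -> int:
        return len(self.populations)


def _h_eigvals(stack: np.ndarray, k: int):
    """Per-draw eigenvalues of H plus the accumulated mean H."""
    n_pops, n_draws, p, _ = stack.shape
    vals = np.empty((n_draws, p))
    H_sum = np.zeros((p, p))
    for m in range(n_draws):
        H = np.zeros((p, p))
        for t in range(n_pops):
            w, v = np.linalg.eigh(stack[t, m])
            A = v[:, -k:]  # top-k eigenvectors
            H += A @ A.T
        vals[m] = np.linalg.eigvalsh(H)[::-1]
        H_sum += H
    return vals, H_sum / n_draws


def krzanowski_subspace(
    G_draws_by_population: dict[str, np.ndarray],
    k: int | None = None,
    null_G_draws_by_population: dict[str, np.ndarray] | None = None,
    probability: float = 0.95,
) -> SubspaceResult:
    """Common-subspace summary of per-population G posteriors.

    ``k`` defaults to floor(n_traits / 2) (half the traits, e.g. three
    eigenvectors for six traits).  An eigenvector of H is flagged as
    diverged only under the dual criterion: its posterior-mean eigenvalue
    is below p (the attainable maximum) *and* below the lower bound of
    the null HPD computed from permuted-data G posteriors.
    """
    pops, stack = _as_draw_stack(G_draws_by_population)
    p_traits = stack.shape[-1]
    if k is None:
        k = p_traits // 2
    if not 1 <= k <= p_traits:
        raise ValueError(f"k must be in [1, {p_traits}], got {k}")

    vals, H_mean = _h_eigvals(stack, k)
    mean = vals.mean(axis=0)
    bounds = np.array([hpd(vals[:, j], probability) for j in range(p_traits)])
    w, v = np.linalg.eigh(H_mean)
    order = np.argsort(w)[::-1]
    vecs = _fix_sign(v[:, order])

    null_hpd = None
    diverged = None
    if null_G_draws_by_population is not None:
        _, null_stack = _as_draw_stack(null_G_draws_by_population)
        null_vals, _ = _h_eigvals(null_stack, k)
        null_hpd = np.array([hpd(null_vals[:, j], probability) for j in range(p_traits)])
        n_pops = len(pops)
        diverged = (mean < n_pops - 1e-9) & (mean < null_hpd[:, 0])

    return SubspaceResult(
        populations=pops, k=k, H_mean=H_mean,
        eigenvalue_draws=vals, eigenvalue_mean=mean, eigenvalue_hpd=bounds,
        eigenvectors=vecs, null_eigenvalue_hpd=null_hpd, diverged=diverged,
    )


# ---------------------------------------------------------------------------
# genetic covariance tensor


@dataclass
class TensorResult:
    populations: list[str]
    traits_dim: int
    S_mean: np.ndarray                 # (m, m), m = p(p+1)/2
    eigentensors: np.ndarray           # (m, p, p), unit Frobenius norm
    alpha: np.ndarray                  # variance proportion per eigentensor
    alpha_draws: np.ndarray            # (n_draws, m) fixed-basis projections
    alpha_hpd: np.ndarray              # (m, 2)
    eigentensor_eigenvalues: np.ndarray    # (m, p)
    eigentensor_eigenvectors: np.ndarray   # (m, p, p) columns
    eigenvector_variance_share: np.ndarray  # (m, p), squared eigenvalues
    coordinates: pd.DataFrame          # population x eigentensor
    no_variation: bool = False
    null_alpha_hpd: np.ndarray | None = None
    significant: np.ndarray | None = None


def _vech_sqrt2(M: np.ndarray, iu) -> np.ndarray:
    w = np.where(iu[0] == iu[1], 1.0, math.sqrt(2.0))
    return M[..., iu[0], iu[1]] * w


def _unvech_sqrt2(v: np.ndarray, p: int, iu) -> np.ndarray:
    E = np.zeros((p, p))
    w = np.where(iu[0] == iu[1], 1.0, 1.0 / math.sqrt(2.0))
    E[iu[0], iu[1]] = v * w
    E[iu[1], iu[0]] = v * w
    return E


def _per_draw_S(stack: np.ndarray, iu) -> np.ndarray:
    """S (covariance of vectorized G across populations) for every draw."""
    n_pops, n_draws = stack.shape[:2]
    V = _vech_sqrt2(stack, iu)              # (n_pops, n_draws, m)
    Vc = V - V.mean(axis=0, keepdims=True)
    # einsum: per-draw (m, m) covariance over populations, ddof = 1
    return np.einsum("tdi,tdj->dij", Vc, Vc) / (n_pops - 1)


def covariance_tensor(
    G_draws_by_population: dict[str, np.ndarray],
    null_G_draw_sets: list[dict[str, np.ndarray]] | None = None,
    probability: float = 0.95,
) -> TensorResult:
    """Eigentensor decomposition of among-population variation in G.

    Each draw's G matrices are vectorized over their p(p+1)/2 unique
    elements with off-diagonals weighted by sqrt(2) (norm-preserving), S
    is their covariance across populations, and the posterior-mean S is
    eigendecomposed into eigentensors.  Per-draw variance proportions
    (alpha) are obtained by projecting each draw's S onto the fixed
    posterior-mean eigentensor basis, which avoids label switching.
    Population coordinates are Frobenius inner products of the centered
    posterior-mean G with each eigentensor (they sum to zero).

    ``null_G_draw_sets`` is a list of randomized-data G posteriors (one
    dict per permuted dataset).  Each dataset yields one null alpha
    spectrum from its own posterior-mean S — the same estimator applied
    to the observed data — and the HPD across datasets is the null band;
    an eigentensor is flagged significant when its observed alpha
    exceeds the null HPD's upper bound.
    """
    pops, stack = _as_draw_stack(G_draws_by_population)
    n_pops, n_draws, p, _ = stack.shape
    if n_draws < 2:
        raise ValueError("need >= 2 posterior draws per population")
    iu = np.triu_indices(p)
    m = iu[0].size

    S_draws = _per_draw_S(stack, iu)
    S_mean = S_draws.mean(axis=0)
    scale = float(np.trace(S_mean))
    w, v = np.linalg.eigh(S_mean)
    order = np.argsort(w)[::-1]
    w, v = np.clip(w[order], 0.0, None), _fix_sign(v[:, order])

    no_variation = scale <= 1e-12 * max(1.0, float(np.abs(stack).max()) ** 2)
    if no_variation:
        alpha = np.zeros(m)
        alpha_draws = np.zeros((n_draws, m))
        alpha_hpd = np.zeros((m, 2))
    else:
        alpha = w / w.sum()
        traces = np.trace(S_draws, axis1=1, axis2=2)
        traces = np.where(traces > 0, traces, np.inf)
        proj = np.einsum("im,dij,jm->dm", v, S_draws, v)
        alpha_draws = np.clip(proj, 0.0, None) / traces[:, None]
        alpha_hpd = np.array([hpd(alpha_draws[:, j], probability) for j in range(m)])

    eigentensors = np.stack([_unvech_sqrt2(v[:, j], p, iu) for j in range(m)])
    et_vals = np.empty((m, p))
    et_vecs = np.empty((m, p, p))
    for j in range(m):
        ew, ev = np.linalg.eigh(eigentensors[j])
        o = np.argsort(np.abs(ew))[::-1]
        et_vals[j] = ew[o]
        et_vecs[j] = _fix_sign(ev[:, o])
    denom = (et_vals ** 2).sum(axis=1, keepdims=True)
    share = np.divide(et_vals ** 2, denom, out=np.zeros_like(et_vals), where=denom > 0)

    G_mean = stack.mean(axis=1)                      # (n_pops, p, p)
    centered = G_mean - G_mean.mean(axis=0)
    coords = np.einsum("tij,mij->tm", centered, eigentensors)
    coordinates = pd.DataFrame(
        coords, index=pops, columns=[f"E{j + 1}" for j in range(m)]
    )

    null_hpd = None
    significant = None
    if null_G_draw_sets is not None and not no_variation:
        spectra = []
        for dataset in null_G_draw_sets:
            _, null_stack = _as_draw_stack(dataset)
            null_S = _per_draw_S(null_stack, iu).mean(axis=0)
            null_w = np.clip(np.linalg.eigvalsh(null_S)[::-1], 0.0, None)
            total = null_w.sum()
            spectra.append(null_w / total if total > 0 else null_w)
        null_alpha = np.stack(spectra)
        null_hpd = np.array([hpd(null_alpha[:, j], probability) for j in range(m)])
        significant = alpha > null_hpd[:, 1]

    return TensorResult(
        populations=pops, traits_dim=p, S_mean=S_mean,
        eigentensors=eigentensors, alpha=alpha, alpha_draws=alpha_draws,
        alpha_hpd=alpha_hpd, eigentensor_eigenvalues=et_vals,
        eigentensor_eigenvectors=et_vecs, eigenvector_variance_share=share,
        coordinates=coordinates, no_variation=no_variation,
        null_alpha_hpd=null_hpd, significant=significant,
    )


# ---------------------------------------------------------------------------
# breeder's equation and R metric


@dataclass
class ResponsePrediction:
    population: str
    traits: list[str]
    delta_z_draws: np.ndarray            # (n_draws, p), trait units
    delta_z_sd_draws: np.ndarray | None  # in global-SD units, if SDs known
    hpd: np.ndarray                      # (p, 2), trait units

    def mean(self) -> np.ndarray:
        return self.delta_z_draws.mean(axis=0)


def _beta_draws(beta, n_draws: int, p: int) -> np.ndarray:
    b = np.asarray(getattr(beta, "values", beta), dtype=float)
    if b.ndim == 1:
        if b.size != p:
            raise ValueError(f"beta has {b.size} elements for {p} traits")
        return np.broadcast_to(b, (n_draws, p))
    if b.shape != (n_draws, p):
        raise ValueError(
            f"posterior beta shape {b.shape} does not pair with "
            f"{n_draws} G draws of dimension {p}"
        )
    return b


def predict_response(
    G_draws: np.ndarray,
    beta,
    sds: np.ndarray | None = None,
    population: str = "",
    traits: list[str] | None = None,
    probability: float = 0.95,
) -> ResponsePrediction:
    """Multivariate breeder's equation delta_zbar = G beta per posterior draw.

    ``beta`` is either a point gradient (length p) applied to every draw
    or a posterior draw matrix (n_draws, p) paired one-to-one with the G
    draws.  If per-trait global SDs are supplied the response is also
    returned in SD units (delta_z / sd).
    """
    G = np.asarray(G_draws, dtype=float)
    n_draws, p = G.shape[0], G.shape[1]
    B = _beta_draws(beta, n_draws, p)
    dz = np.einsum("dij,dj->di", G, B)
    dz_sd = None
    if sds is not None:
        dz_sd = dz / np.asarray(sds, dtype=float)[None, :]
    bounds = np.array([hpd(dz[:, j], probability) for j in range(p)])
    return ResponsePrediction(
        population=population, traits=traits or [f"trait{i}" for i in range(p)],
        delta_z_draws=dz, delta_z_sd_draws=dz_sd, hpd=bounds,
    )


@dataclass
class RMetricResult:
    population: str
    R_draws: np.ndarray
    mean: float
    pct5: float
    pct95: float
    n_excluded: int = 0


def r_metric(G_draws: np.ndarray, beta, population: str = "") -> RMetricResult:
    """Effect of genetic covariances on the rate of adaptation.

    Per draw, R = (beta' G beta) / (beta' G0 beta), where G0 is G with
    every off-diagonal zeroed and beta' G beta is the rate of adaptation
    (the change in mean fitness under gradient beta).  R = 1 means the
    covariances have no net effect; draws with a zero denominator are
    excluded and counted.  Summaries are the mean and the 5th/95th
    percentiles.
    """
    G = np.asarray(G_draws, dtype=float)
    n_draws, p = G.shape[0], G.shape[1]
    B = _beta_draws(beta, n_draws, p)
    num = np.einsum("di,dij,dj->d", B, G, B)
    den = np.einsum("dj,dj->d", B ** 2, np.diagonal(G, axis1=1, axis2=2))
    ok = den > 1e-300
    R = num[ok] / den[ok]
    if R.size == 0:
        raise ValueError("all draws had zero denominator (diagonal of G vanishes)")
    return RMetricResult(
        population=population, R_draws=R, mean=float(R.mean()),
        pct5=float(np.percentile(R, 5)), pct95=float(np.percentile(R, 95)),
        n_excluded=int((~ok).sum()),
    )


# ---------------------------------------------------------------------------
# random skewers


@dataclass
class SkewerResult:
    pairs: pd.DataFrame   # population_1, population_2, mean_correlation, mean_angle_deg, similar
    n_skewers: int
    random_vector_q95: float = float("nan")

    def lookup(self, pop1: str, pop2: str) -> tuple[float, float]:
        df = self.pairs
        row = df[((df.population_1 == pop1) & (df.population_2 == pop2))
                 | ((df.population_1 == pop2) & (df.population_2 == pop1))]
        r = row.iloc[0]
        return float(r.mean_correlation), float(r.mean_angle_deg)


def random_skewers(
    G_draws_by_population: dict[str, np.ndarray],
    n_skewers: int = 1000,
    seed: int = 0,
) -> SkewerResult:
    """Pairwise response similarity under random unit selection vectors.

    Skewers are drawn uniformly on the unit sphere (normalized Gaussian
    draws) and applied to each population's posterior-mean G; for every
    pair of populations the mean vector correlation (cosine) and mean
    angle between responses are reported.  Each pair also gets a
    ``similar`` call: the mean correlation exceeds the 95th percentile
    of correlations between independent random unit vectors of the same
    dimension (Cheverud's criterion for significant matrix similarity).
    """
    if n_skewers < 1:
        raise ValueError("n_skewers must be >= 1")
    pops, stack = _as_draw_stack(G_draws_by_population)
    p = stack.shape[-1]
    rng = np.random.default_rng(seed)
    s = rng.standard_normal((n_skewers, p))
    s /= np.linalg.norm(s, axis=1, keepdims=True)
    G_mean = stack.mean(axis=1)                  # (n_pops, p, p)
    resp = np.einsum("tij,sj->tsi", G_mean, s)   # (n_pops, n_skewers, p)
    norms = np.linalg.norm(resp, axis=2)

    # random-vector similarity threshold (Cheverud): correlations between
    # independent uniform unit vectors of the same dimension
    u = rng.standard_normal((max(n_skewers, 1000), 2, p))
    u /= np.linalg.norm(u, axis=2, keepdims=True)
    rand_corr = np.sum(u[:, 0] * u[:, 1], axis=1)
    q95 = float(np.percentile(rand_corr, 95))

    rows = []
    for a in range(len(pops)):
        for b in range(a + 1, len(pops)):
            cos = np.sum(resp[a] * resp[b], axis=1) / (norms[a] * norms[b])
            cos = np.clip(cos, -1.0, 1.0)
            mean_corr = float(cos.mean())
            rows.append({
                "population_1": pops[a], "population_2": pops[b],
                "mean_correlation": mean_corr,
                "mean_angle_deg": float(np.degrees(np.arccos(cos)).mean()),
                "similar": bool(mean_corr > q95),
            })
    return SkewerResult(pairs=pd.DataFrame(rows), n_skewers=n_skewers,
                        random_vector_q95=q95)
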