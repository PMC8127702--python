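"""Convergence diagnostics: PSRF, effective sample size, autocorrelation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class DiagnosticsReport:
    """Per-parameter chain diagnostics.

    ``psrf`` is the Gelman–Rubin potential scale reduction factor (None
    with a single chain); ``ess`` the effective sample size pooled over
    chains; ``autocorr`` the per-parameter lag-k autocorrelation averaged
    over chains, shape (n_params, max_lag + 1).
    """

    psrf: np.ndarray | None
    ess: np.ndarray
    autocorr: np.ndarray
    param_names: list[str]

    def to_frame(self):
        import pandas as pd
        d = {"parameter": self.param_names, "ess": self.ess,
             "lag1_autocorr": self.autocorr[:, 1] if self.autocorr.shape[1] > 1 else np.nan}
        if self.psrf is not None:
            d["psrf"] = self.psrf
        return pd.DataFrame(d)


def autocorrelation(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Sample autocorrelation of a 1-D chain at lags 0..max_lag."""
    x = np.asarray(x, dtype=float)
    n = x.size
    xc = x - x.mean()
    denom = float(xc @ xc)
    out = np.empty(min(max_lag, n - 1) + 1)
    if denom == 0:
        out[:] = 0.0
        out[0] = 1.0
        return out
    for k in range(out.size):
        out[k] = float(xc[: n - k] @ xc[k:]) / denom
    return out


def gelman_rubin(chains: np.ndarray) -> np.ndarray:
    """Classic PSRF per parameter from (m, n, k) stacked chains.

    Computed as sqrt(((n-1)/n W + B/n) / W) and clipped below at 1, so
    identical chains yield exactly 1 and the estimate never drops below
    the no-shrinkage point.
    """
    m, n, k = chains.shape
    means = chains.mean(axis=1)                      # (m, k)
    W = chains.var(axis=1, ddof=1).mean(axis=0)      # (k,)
    B_over_n = means.var(axis=0, ddof=1)             # (k,)
    psrf = np.ones(k)
    ok = W > 0
    vhat = (n - 1) / n * W[ok] + B_over_n[ok]
    psrf[ok] = np.sqrt(vhat / W[ok])
    psrf[~ok & (B_over_n > 0)] = np.inf
    return np.maximum(psrf, 1.0)


def _ess_one(acf: np.ndarray, n_total: int) -> float:
    """Geyer initial-monotone-positive-sequence ESS from an ACF."""
    pair = acf[1:-1:2] + acf[2::2] if acf.size > 2 else np.array([])
    tau = 1.0
    running_min = np.inf
    for s in pair:
        if s <= 0:
            break
        running_min = min(running_min, s)
        tau += 2.0 * running_min
    return float(min(n_total, n_total / tau))


def diagnostics(
    chains, param_names: list[str] | None = None, max_lag: int = 50
) -> DiagnosticsReport:
    """Diagnose one or more chains of posterior draws.

    ``chains`` is a sequence of equal-length arrays, each (n_draws,) or
    (n_draws, n_params).  With a single chain the PSRF is unavailable but
    autocorrelation and ESS are still reported.
    """
    arrs = [np.atleast_2d(np.asarray(c, dtype=float).T).T for c in chains]
    if not arrs:
        raise ValueError("need at least one chain")
    n = arrs[0].shape[0]
    if any(a.shape != arrs[0].shape for a in arrs):
        raise ValueError("chains must have identical shapes")
    if n < 10:
        raise ValueError("chains must have length >= 10")
    stacked = np.stack(arrs)  # (m, n, k)
    m, _, k = stacked.shape
    if param_names is None:
        param_names = [f"param{i}" for i in range(k)]

    acf = np.zeros((k, min(max_lag, n - 1) + 1))
    ess = np.empty(k)
    for j in range(k):
        per_chain = np.stack([autocorrelation(stacked[c, :, j], max_lag) for c in range(m)])
        acf[j] = per_chain.mean(axis=0)
        ess[j] = _ess_one(acf[j], m * n)

    psrf = gelman_rubin(stacked) if m >= 2 else None
    return DiagnosticsReport(psrf=psrf, ess=ess, autocorr=acf, param_names=list(param_names))
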