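"""Permutation null distributions and HPD intervals.

Variance components are bounded below by zero, so their posteriors never
cover zero and classical significance logic does not apply.  The null
used throughout the package is generated by shuffling trait records
across individuals within each population — destroying the sire/dam
family structure while conserving every trait's marginal distribution —
and re-running the estimator of interest on each permuted dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .tables import trait_columns

logger = logging.getLogger(__name__)


def hpd(samples, probability: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval holding *probability* of the samples.

    Empirical highest-density interval: sort, slide a window containing
    ceil(probability * n) points, return the narrowest.
    """
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n < 2:
        raise ValueError("hpd needs at least 2 samples")
    if not 0.0 < probability < 1.0:
        raise ValueError("probability must be in (0, 1)")
    m = max(2, int(np.ceil(probability * n)))
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


@dataclass
class NullDistribution:
    """Null samples of a statistic with its HPD bounds."""

    statistic_label: str
    samples: np.ndarray           # (n_ok,) or (n_ok, k)
    hpd_low: float | np.ndarray
    hpd_high: float | np.ndarray
    n_datasets: int
    n_failed: int = 0
    probability: float = 0.95


def permute_within_population(
    table: pd.DataFrame,
    seed: int | np.random.SeedSequence,
    per_trait: bool = False,
    traits: list[str] | None = None,
) -> pd.DataFrame:
    """Shuffle trait values across individuals within each population.

    By default whole trait records move together (joint shuffle), which
    conserves the pooled phenotypic covariance exactly while severing any
    association with sires, dams and blocks.  With ``per_trait=True``
    each trait column is permuted independently (conserving marginals but
    not the covariance).  Design columns are never touched.
    """
    if table.empty:
        raise ValueError("cannot permute an empty table")
    traits = traits or trait_columns(table)
    rng = np.random.default_rng(seed)
    out = table.reset_index(drop=True).copy()
    for _, idx in out.groupby("population").indices.items():
        if per_trait:
            for t in traits:
                out.loc[idx, t] = out.loc[idx, t].to_numpy()[rng.permutation(len(idx))]
        else:
            perm = rng.permutation(len(idx))
            out.loc[idx, traits] = out.loc[idx, traits].to_numpy()[perm]
    return out


def build_null(
    table: pd.DataFrame,
    fit_and_statistic: Callable[[pd.DataFrame, int], float | np.ndarray],
    n_datasets: int = 1000,
    seed: int = 0,
    statistic_label: str = "statistic",
    probability: float = 0.95,
    per_trait: bool = False,
) -> NullDistribution:
    """Permute -> refit -> evaluate, *n_datasets* times.

    ``fit_and_statistic(permuted_table, seed)`` returns a scalar or 1-D
    array statistic; its seed argument makes any internal sampler
    reproducible.  Sub-seeds are spawned deterministically from the
    master seed, so permutation *i* is reproducible in isolation.
    Failing permutations are logged and excluded (their count is kept).
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_datasets)
    values = []
    n_failed = 0
    for i, child in enumerate(children):
        perm_seed, fit_seed = child.generate_state(2)
        try:
            perm = permute_within_population(table, int(perm_seed), per_trait=per_trait)
            values.append(np.asarray(fit_and_statistic(perm, int(fit_seed % 2**31)), dtype=float))
        except Exception:
            n_failed += 1
            logger.warning("null dataset %d failed; excluded", i, exc_info=True)
    if not values:
        raise RuntimeError("every null dataset failed")
    samples = np.stack(values)
    if samples.ndim == 1 or samples.shape[1] == 1:
        samples = samples.ravel()
        lo, hi = hpd(samples, probability)
    else:
        bounds = np.array([hpd(samples[:, j], probability) for j in range(samples.shape[1])])
        lo, hi = bounds[:, 0], bounds[:, 1]
    return NullDistribution(
        statistic_label=statistic_label, samples=samples,
        hpd_low=lo, hpd_high=hi, n_datasets=n_datasets,
        n_failed=n_failed, probability=probability,
    )
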