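"""Generative model for half-sib phenotype data with known architecture.

The observation model is the nested mixed model

    y = mu + block + sire + dam + residual,

with sire effects drawn once per sire from MVN(0, G/4) (half-sib theory:
a sire transmits half his breeding value, so the among-sire covariance is
one quarter of the additive covariance G), dam effects once per dam from
MVN(0, D), and residuals per individual from MVN(0, E).  Attrition and
per-trait missingness emulate field mortality and unscored plants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .tables import DESIGN_COLUMNS, TRAITS, validate_phenotypes

_PSD_TOL = 1e-8


def _check_psd(M: np.ndarray, name: str) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{name} must be a square matrix, got shape {M.shape}")
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    w = np.linalg.eigvalsh(M)
    if w.min() < -_PSD_TOL * max(1.0, w.max()):
        raise ValueError(f"{name} is not positive semi-definite (min eigenvalue {w.min():.3g})")
    return M


@dataclass
class SimulationParams:
    """Known genetic architecture driving a simulation.

    G, D and E are the additive, dam (maternal/dominance) and residual
    covariance matrices in squared trait units; ``block_effects`` is an
    (n_blocks, n_traits) array of additive offsets.
    """

    mu: np.ndarray
    G: np.ndarray
    D: np.ndarray
    E: np.ndarray
    block_effects: np.ndarray | None = None
    attrition_rate: float = 0.0
    missing_rate_per_trait: np.ndarray | float = 0.0
    seed: int = 0
    traits: list[str] = field(default_factory=lambda: list(TRAITS))

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        p = self.mu.size
        self.G = _check_psd(self.G, "G")
        self.D = _check_psd(self.D, "D")
        self.E = _check_psd(self.E, "E")
        for name, M in (("G", self.G), ("D", self.D), ("E", self.E)):
            if M.shape != (p, p):
                raise ValueError(f"{name} has shape {M.shape}, expected ({p}, {p})")
        if len(self.traits) != p:
            raise ValueError(f"{len(self.traits)} trait names for {p}-dimensional mu")
        if self.block_effects is not None:
            self.block_effects = np.asarray(self.block_effects, dtype=float)
            if self.block_effects.ndim != 2 or self.block_effects.shape[1] != p:
                raise ValueError("block_effects must be (n_blocks, n_traits)")
        self.missing_rate_per_trait = np.broadcast_to(
            np.asarray(self.missing_rate_per_trait, dtype=float), (p,)
        ).copy()
        for name, r in [("attrition_rate", np.atleast_1d(self.attrition_rate)),
                        ("missing_rate_per_trait", self.missing_rate_per_trait)]:
            if np.any((r < 0) | (r > 1)):
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def n_traits(self) -> int:
        return self.mu.size

    def to_json(self, path: str | Path) -> None:
        payload = {
            "traits": self.traits,
            "mu": self.mu.tolist(),
            "G": self.G.tolist(),
            "D": self.D.tolist(),
            "E": self.E.tolist(),
            "block_effects": None if self.block_effects is None else self.block_effects.tolist(),
            "attrition_rate": float(self.attrition_rate),
            "missing_rate_per_trait": self.missing_rate_per_trait.tolist(),
            "seed": int(self.seed),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationParams":
        d = json.loads(Path(path).read_text())
        return cls(
            mu=d["mu"], G=d["G"], D=d["D"], E=d["E"],
            block_effects=d["block_effects"],
            attrition_rate=d["attrition_rate"],
            missing_rate_per_trait=d["missing_rate_per_trait"],
            seed=d["seed"], traits=d["traits"],
        )


# Default architecture: six traits, one phenotypic correlation structure C,
# P = S·C·S with realistic trait SDs, and G = 0.4 P, D = G/4, E = P - G/2,
# so every trait has h² = 0.4 and V_S + V_D + V_E = P exactly.  All six
# populations share this architecture by default, mirroring a scenario of
# no among-population divergence in G.
_DEFAULT_MU = np.array([12.0, 85.0, 18.0, 62.0, 35.0, 2.5])
_DEFAULT_SD = np.array([4.0, 20.0, 6.0, 8.0, 12.0, 1.0])
_DEFAULT_CORR = np.array([
    [1.0, 0.6, 0.3, 0.2, 0.3, 0.2],
    [0.6, 1.0, 0.4, 0.3, 0.4, 0.3],
    [0.3, 0.4, 1.0, 0.2, 0.4, 0.3],
    [0.2, 0.3, 0.2, 1.0, 0.3, 0.1],
    [0.3, 0.4, 0.4, 0.3, 1.0, 0.4],
    [0.2, 0.3, 0.3, 0.1, 0.4, 1.0],
])


def default_params(
    heritability: float = 0.4,
    attrition_rate: float = 0.30,
    missing_rate_per_trait: float = 0.05,
    n_blocks: int = 3,
    seed: int = 0,
) -> SimulationParams:
    """Study-scale default parameters for the six-trait field experiment."""
    P = _DEFAULT_SD[:, None] * _DEFAULT_CORR * _DEFAULT_SD[None, :]
    G = heritability * P
    D = G / 4.0
    E = P - G / 2.0
    offsets = np.linspace(-0.25, 0.25, n_blocks)[:, None] * _DEFAULT_SD[None, :]
    return SimulationParams(
        mu=_DEFAULT_MU, G=G, D=D, E=E, block_effects=offsets,
        attrition_rate=attrition_rate,
        missing_rate_per_trait=missing_rate_per_trait, seed=seed,
    )


def _mvn(rng: np.random.Generator, cov: np.ndarray, n: int) -> np.ndarray:
    # svd factorization tolerates exactly-singular (e.g. zero) covariances
    return rng.multivariate_normal(np.zeros(cov.shape[0]), cov, size=n, method="svd")


def simulate_phenotypes(design: pd.DataFrame, params: SimulationParams) -> pd.DataFrame:
    """Draw phenotypes for every individual in *design* under *params*.

    Effects are drawn population by population in design order: one sire
    effect per sire from MVN(0, G/4), one dam effect per dam from
    MVN(0, D), one residual per individual from MVN(0, E).  Reproducible
    bitwise for a fixed ``params.seed``.
    """
    p = params.n_traits
    rng = np.random.default_rng(params.seed)
    table = design.reset_index(drop=True).copy()

    sires, sire_idx = np.unique(table["sire"], return_inverse=True)
    dams, dam_idx = np.unique(table["dam"], return_inverse=True)
    sire_eff = _mvn(rng, params.G / 4.0, len(sires))
    dam_eff = _mvn(rng, params.D, len(dams))
    resid = _mvn(rng, params.E, len(table))

    values = params.mu[None, :] + sire_eff[sire_idx] + dam_eff[dam_idx] + resid
    if params.block_effects is not None:
        blocks = np.sort(table["block"].unique())
        if len(blocks) > params.block_effects.shape[0]:
            raise ValueError(
                f"design has {len(blocks)} blocks but block_effects has "
                f"{params.block_effects.shape[0]} rows"
            )
        block_map = {b: i for i, b in enumerate(blocks)}
        values = values + params.block_effects[table["block"].map(block_map).to_numpy()]

    for j, t in enumerate(params.traits):
        table[t] = values[:, j]
    validate_phenotypes(table, params.traits)
    return table


def apply_attrition(
    table: pd.DataFrame,
    attrition_rate: float,
    missing_rate_per_trait: np.ndarray | float,
    seed: int,
    traits: list[str] | None = None,
) -> pd.DataFrame:
    """Drop rows (plant death) and mask trait cells (unscored) i.i.d.

    Each row survives with probability ``1 - attrition_rate``; each trait
    of a surviving row is masked independently with its missing rate.
    """
    if not 0.0 <= attrition_rate <= 1.0:
        raise ValueError(f"attrition_rate must be in [0, 1], got {attrition_rate}")
    traits = traits or [c for c in table.columns if c not in DESIGN_COLUMNS]
    rates = np.broadcast_to(
        np.asarray(missing_rate_per_trait, dtype=float), (len(traits),)
    )
    if np.any((rates < 0) | (rates > 1)):
        raise ValueError("missing_rate_per_trait must be in [0, 1]")

    rng = np.random.default_rng(seed)
    keep = rng.random(len(table)) >= attrition_rate
    out = table.loc[keep].reset_index(drop=True).copy()
    for t, r in zip(traits, rates):
        if r > 0:
            mask = rng.random(len(out)) < r
            out.loc[mask, t] = np.nan
    return out
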