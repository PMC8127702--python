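"""End-to-end orchestration: simulate -> fit -> nulls -> compare -> report.

Every stage writes plain artifacts (CSV/JSON/HDF5) into the output
directory and records its effective seed in a manifest, so any stage can
be replayed in isolation.  A single master seed fans out to per-stage
seed sequences in a fixed order; re-running with the same configuration
and seed reproduces every artifact bitwise.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import compare as cmp
from .design import make_design
from .model import (
    MCMCConfig, fit_multivariate, fit_univariate, heritability,
    load_posteriors, save_posteriors, standardize_traits,
)
from .permutation import hpd, permute_within_population
from .selection import (
    COMPOSITE_FITNESS, composite_fitness, estimate_beta_bayes,
    estimate_beta_point, sire_means,
)
from .simulate import SimulationParams, apply_attrition, default_params, simulate_phenotypes
from .tables import FOCAL_TRAITS, TRAITS, read_phenotypes, write_phenotypes

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "fit", "nulls", "selection", "compare")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Declarative description of a full analysis run."""

    output_dir: str
    seed: int
    input_table: str | None = None          # CSV path; None -> simulate
    simulation: dict = field(default_factory=dict)   # make_design kwargs (+ heritability etc.)
    traits: list[str] = field(default_factory=lambda: list(TRAITS))
    populations: list[str] | None = None
    mcmc: dict = field(default_factory=dict)          # MCMCConfig overrides
    n_null_datasets: int = 1000
    null_chain_scale: float = 10.0
    permute_per_trait: bool = False
    k_subspace: int | None = None
    n_skewers: int = 1000
    beta_mode: str = "point"                 # "point" | "posterior"
    fitness_metric: str = "composite"        # "composite" | trait name
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def mcmc_config(self, seed: int) -> MCMCConfig:
        kw = dict(self.mcmc)
        kw["seed"] = seed
        return MCMCConfig(**kw)


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


class Pipeline:
    """Stage runner bound to a config and output directory."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.outdir = Path(config.output_dir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        # fixed fan-out order; appending stages never perturbs earlier streams
        ss = np.random.SeedSequence(config.seed)
        children = ss.spawn(len(_STAGES))
        self.stage_seeds = {
            s: int(c.generate_state(1)[0] % 2**31) for s, c in zip(_STAGES, children)
        }
        self._manifest_path = self.outdir / "manifest.json"

    # -- manifest ----------------------------------------------------------
    def _manifest(self) -> dict:
        if self._manifest_path.exists():
            return json.loads(self._manifest_path.read_text())
        return {"master_seed": self.config.seed, "stage_seeds": self.stage_seeds,
                "stages": {}}

    def _mark(self, stage: str, status: str) -> None:
        m = self._manifest()
        m["stages"][stage] = {"status": status, "seed": self.stage_seeds.get(stage)}
        _dump_json(m, self._manifest_path)

    def _run_stage(self, stage: str, fn):
        self._mark(stage, "running")
        try:
            result = fn()
        except Exception as exc:  # partial artifacts retained, marked incomplete
            self._mark(stage, "failed")
            raise PipelineError(stage, exc) from exc
        self._mark(stage, "done")
        return result

    # -- stage: simulate / load -------------------------------------------
    def stage_simulate(self) -> pd.DataFrame:
        def run():
            cfg = self.config
            if cfg.input_table is not None:
                table = read_phenotypes(cfg.input_table)
            else:
                sim = dict(cfg.simulation)
                seed = self.stage_seeds["simulate"]
                design = make_design(
                    n_populations=sim.pop("n_populations", 6),
                    n_sires=sim.pop("n_sires", 50),
                    n_dams_per_sire=sim.pop("n_dams_per_sire", 3),
                    n_offspring_per_dam=sim.pop("n_offspring_per_dam", 3),
                    n_blocks=sim.pop("n_blocks", 3),
                    seed=seed,
                )
                params = default_params(seed=seed, **sim)
                table = simulate_phenotypes(design, params)
                table = apply_attrition(
                    table, params.attrition_rate, params.missing_rate_per_trait,
                    seed=seed + 1, traits=params.traits,
                )
                params.to_json(self.outdir / "simulation_params.json")
            missing = [t for t in cfg.traits if t not in table.columns]
            if missing:
                raise ValueError(f"configured traits not in input: {missing}")
            if cfg.populations:
                table = table[table["population"].isin(cfg.populations)].reset_index(drop=True)
            write_phenotypes(table, self.outdir / "phenotypes.csv")
            return table

        return self._run_stage("simulate", run)

    def _load_table(self) -> pd.DataFrame:
        return read_phenotypes(self.outdir / "phenotypes.csv")

    # -- stage: fit --------------------------------------------------------
    def stage_fit(self):
        def run():
            cfg = self.config
            table = self._load_table()
            std_table, sds = standardize_traits(table, cfg.traits)
            _dump_json({t: sds[t] for t in cfg.traits}, self.outdir / "standardization.json")
            pops = sorted(std_table["population"].unique())
            seed = self.stage_seeds["fit"]

            posteriors = []
            h2_rows = []
            for i, pop in enumerate(pops):
                mcfg = cfg.mcmc_config(seed + i)
                post = fit_multivariate(std_table, pop, mcfg, traits=cfg.traits,
                                        standardization=sds)
                posteriors.append(post)
                for j, trait in enumerate(cfg.traits):
                    ucfg = cfg.mcmc_config(seed + 1000 + i * len(cfg.traits) + j)
                    upost = fit_univariate(std_table, trait, pop, ucfg)
                    lo, hi = hpd(upost.h2)
                    h2_rows.append({
                        "population": pop, "trait": trait,
                        "h2_mean": float(upost.h2.mean()),
                        "h2_hpd_low": lo, "h2_hpd_high": hi,
                    })
            save_posteriors(posteriors, self.outdir / "posteriors.h5")
            pd.concat([p.summary() for p in posteriors]).to_csv(
                self.outdir / "g_summary.csv", index=False)
            pd.DataFrame(h2_rows).to_csv(self.outdir / "heritability.csv", index=False)

        return self._run_stage("fit", run)

    # -- stage: nulls ------------------------------------------------------
    def stage_nulls(self):
        def run():
            cfg = self.config
            table = self._load_table()
            std_table, _ = standardize_traits(table, cfg.traits)
            pops = sorted(std_table["population"].unique())
            base = cfg.mcmc_config(0)
            null_cfg = base.scaled(cfg.null_chain_scale)
            if cfg.null_chain_scale > 1:
                logger.warning(
                    "null refits use chains scaled down %gx (%d iterations post burn-in)",
                    cfg.null_chain_scale, null_cfg.post_burn_iterations)

            ss = np.random.SeedSequence(self.stage_seeds["nulls"])
            children = ss.spawn(cfg.n_null_datasets)
            # draws kept per permuted dataset: the subspace null pools them,
            # the tensor null needs one alpha spectrum per dataset
            null_draws: dict[str, list[np.ndarray]] = {p: [] for p in pops}
            h2_null: dict[tuple, list[np.ndarray]] = {}
            for child in children:
                perm_seed, fit_seed = (int(v % 2**31) for v in child.generate_state(2))
                perm = permute_within_population(
                    std_table, perm_seed, per_trait=cfg.permute_per_trait,
                    traits=cfg.traits)
                for i, pop in enumerate(pops):
                    c = MCMCConfig(**{**null_cfg.__dict__, "seed": fit_seed + i})
                    post = fit_multivariate(perm, pop, c, traits=cfg.traits)
                    null_draws[pop].append(post.G_draws)
                    # null heritability from the multivariate diagonal
                    for j, t in enumerate(cfg.traits):
                        h2 = heritability(post.S_draws[:, j, j],
                                          post.D_draws[:, j, j],
                                          post.E_draws[:, j, j])
                        h2_null.setdefault((pop, t), []).append(h2)

            np.savez_compressed(
                self.outdir / "null_g_draws.npz",
                **{f"{p}__{d}": arr
                   for p in pops for d, arr in enumerate(null_draws[p])})
            rows = []
            for (pop, t), chunks in h2_null.items():
                samples = np.concatenate(chunks)
                lo, hi = hpd(samples)
                rows.append({"population": pop, "trait": t,
                             "null_h2_mean": float(samples.mean()),
                             "null_h2_hpd_low": lo, "null_h2_hpd_high": hi})
            pd.DataFrame(rows).to_csv(self.outdir / "heritability_null.csv", index=False)

        return self._run_stage("nulls", run)

    # -- stage: selection --------------------------------------------------
    def stage_selection(self):
        def run():
            cfg = self.config
            table = self._load_table()
            std_table, _ = standardize_traits(table, cfg.traits)
            sm_table = sire_means(std_table, cfg.traits)
            if cfg.fitness_metric == "composite":
                scores, explained = composite_fitness(sm_table)
                sm_table[COMPOSITE_FITNESS] = scores
                fitness_col = COMPOSITE_FITNESS
            else:
                fitness_col = cfg.fitness_metric
            focal = [t for t in FOCAL_TRAITS if t in cfg.traits]
            seed = self.stage_seeds["selection"]
            # the composite PC1 score is centered, so it enters unrelativized
            rel = cfg.fitness_metric != "composite"
            if cfg.beta_mode == "posterior":
                grad = estimate_beta_bayes(sm_table, fitness_col, seed=seed,
                                           traits=focal, relativize=rel)
                grad.draws.to_csv(self.outdir / "beta_draws.csv", index=False)
            else:
                grad = estimate_beta_point(sm_table, fitness_col, traits=focal,
                                           relativize=rel)
            _dump_json({"mode": grad.mode, "fitness_metric": grad.fitness_metric,
                        "n_sires": grad.n_sires,
                        "beta": {t: float(v) for t, v in grad.beta.items()}},
                       self.outdir / "beta.json")

        return self._run_stage("selection", run)

    def _load_beta(self, focal):
        meta = json.loads((self.outdir / "beta.json").read_text())
        beta = pd.Series({t: meta["beta"][t] for t in focal})
        draws_path = self.outdir / "beta_draws.csv"
        draws = pd.read_csv(draws_path)[focal] if draws_path.exists() else None
        return beta, draws, meta

    # -- stage: compare ----------------------------------------------------
    def stage_compare(self):
        def run():
            cfg = self.config
            posteriors = load_posteriors(self.outdir / "posteriors.h5")
            pops = sorted(posteriors)
            sds = json.loads((self.outdir / "standardization.json").read_text())
            G_by_pop = {p: posteriors[p].G_draws for p in pops}
            null_npz = np.load(self.outdir / "null_g_draws.npz")
            n_sets = max(int(k.rsplit("__", 1)[1]) for k in null_npz.files) + 1
            null_sets = [{p: null_npz[f"{p}__{d}"] for p in pops}
                         for d in range(n_sets)]
            null_pooled = {p: np.concatenate([s[p] for s in null_sets]) for p in pops}

            sub = cmp.krzanowski_subspace(G_by_pop, k=cfg.k_subspace,
                                          null_G_draws_by_population=null_pooled)
            tensor = cmp.covariance_tensor(G_by_pop, null_G_draw_sets=null_sets)
            skew = cmp.random_skewers(G_by_pop, n_skewers=cfg.n_skewers,
                                      seed=self.stage_seeds["compare"])

            focal = [t for t in FOCAL_TRAITS if t in cfg.traits]
            beta, beta_draws, _ = self._load_beta(focal)
            focal_sds = np.array([sds[t] for t in focal])
            responses = {}
            rvals = {}
            for p in pops:
                sub_post = posteriors[p].subset_traits(focal)
                b = beta_draws.to_numpy() if beta_draws is not None else beta
                if beta_draws is not None and len(beta_draws) != sub_post.n_draws:
                    b = beta  # draw counts must pair; fall back to the point estimate
                # fits ran on standardized traits: responses are already in
                # global-SD units; multiply by SD for trait units
                resp = cmp.predict_response(sub_post.G_draws, b, population=p,
                                            traits=focal)
                responses[p] = resp
                rvals[p] = cmp.r_metric(sub_post.G_draws, b, population=p)

            result = {
                "krzanowski": {
                    "k": sub.k,
                    "n_populations": sub.n_populations,
                    "eigenvalue_mean": sub.eigenvalue_mean.tolist(),
                    "eigenvalue_hpd": sub.eigenvalue_hpd.tolist(),
                    "null_eigenvalue_hpd": sub.null_eigenvalue_hpd.tolist(),
                    "diverged": [bool(x) for x in sub.diverged],
                },
                "tensor": {
                    "alpha": tensor.alpha.tolist(),
                    "alpha_hpd": tensor.alpha_hpd.tolist(),
                    "null_alpha_hpd": None if tensor.null_alpha_hpd is None
                    else tensor.null_alpha_hpd.tolist(),
                    "significant": None if tensor.significant is None
                    else [bool(x) for x in tensor.significant],
                    "no_variation": tensor.no_variation,
                    "coordinates": {p: tensor.coordinates.loc[p].tolist() for p in pops},
                },
                "response": {
                    p: {
                        "traits": focal,
                        "delta_z_sd_units": responses[p].mean().tolist(),
                        "delta_z_trait_units": (responses[p].mean() * focal_sds).tolist(),
                        "hpd_sd_units": responses[p].hpd.tolist(),
                    } for p in pops
                },
                "r_metric": {
                    p: {"mean": rvals[p].mean, "pct5": rvals[p].pct5,
                        "pct95": rvals[p].pct95} for p in pops
                },
                "skewers": {
                    "n_skewers": skew.n_skewers,
                    "pairs": skew.pairs.to_dict(orient="records"),
                },
            }
            _dump_json(result, self.outdir / "comparisons.json")

        return self._run_stage("compare", run)

    # -- stage: report -----------------------------------------------------
    def stage_report(self) -> dict:
        h2 = pd.read_csv(self.outdir / "heritability.csv")
        h2_null = pd.read_csv(self.outdir / "heritability_null.csv")
        comparisons = json.loads((self.outdir / "comparisons.json").read_text())
        merged = h2.merge(h2_null, on=["population", "trait"], how="left")
        summary = {
            "heritability": merged.to_dict(orient="records"),
            **comparisons,
        }
        _dump_json(summary, self.outdir / "summary.json")
        return summary

    def run_all(self) -> dict:
        self.stage_simulate()
        self.stage_fit()
        self.stage_nulls()
        self.stage_selection()
        self.stage_compare()
        return self.stage_report()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order; returns the machine-readable summary."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    return Pipeline(config).run_all()
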