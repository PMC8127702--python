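import numpy as np
import pandas as pd
import pytest

import gmatkit as gk
from gmatkit.selection import (
    COMPOSITE_FITNESS,
    composite_fitness,
    estimate_beta_bayes,
    estimate_beta_point,
    sire_means,
)

FOUR = list(gk.FOCAL_TRAITS)


def _sire_frame(n, seed=0, beta=(0.3, -0.2, 0.1, 0.0), noise=0.0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, 4))
    w = 1.0 + X @ np.asarray(beta) + noise * rng.standard_normal(n)
    df = pd.DataFrame(X, columns=FOUR)
    df.insert(0, "population", "P1")
    df.insert(1, "sire", [f"S{i}" for i in range(n)])
    df["fitness"] = w
    return df


class TestSireMeans:
    def test_single_offspring_means_equal_values(self, small_table):
        one = small_table.groupby("sire").head(1)
        sm = sire_means(one)
        merged = sm.merge(one, on=["population", "sire"], suffixes=("_m", ""))
        for t in gk.TRAITS:
            np.testing.assert_allclose(merged[f"{t}_m"], merged[t])
        assert (sm["n_offspring"] == 1).all()

    def test_duplicating_rows_leaves_means_unchanged(self, small_table):
        doubled = pd.concat([small_table, small_table])
        a = sire_means(small_table)
        b = sire_means(doubled)
        for t in gk.TRAITS:
            np.testing.assert_allclose(a[t], b[t])

    def test_hand_computed_three_sire_fixture(self):
        t = pd.DataFrame({
            "population": ["P1"] * 6,
            "block": ["1"] * 6,
            "sire": ["A", "A", "B", "B", "C", "C"],
            "dam": ["A1", "A2", "B1", "B2", "C1", "C2"],
            "individual": [f"i{k}" for k in range(6)],
            "early_height": [1.0, 3.0, 4.0, np.nan, 10.0, 20.0],
        })
        sm = sire_means(t, ["early_height"])
        np.testing.assert_allclose(sm["early_height"], [2.0, 4.0, 15.0])

    def test_all_missing_trait_keeps_row_with_missing_mean(self):
        t = pd.DataFrame({
            "population": ["P1"] * 4, "block": ["1"] * 4,
            "sire": ["A", "A", "B", "B"], "dam": list("abcd"),
            "individual": list("wxyz"),
            "early_height": [np.nan, np.nan, 1.0, 2.0],
        })
        sm = sire_means(t, ["early_height"])
        assert len(sm) == 2
        assert np.isnan(sm.loc[sm["sire"] == "A", "early_height"]).all()


class TestCompositeFitness:
    def _frame(self, il, sm_):
        return pd.DataFrame({"inflorescence_length": il, "seed_mass": sm_})

    def test_perfectly_correlated_proxies_rank_one(self):
        x = np.linspace(0, 5, 10)
        scores, explained = composite_fitness(self._frame(x, 2 * x + 1))
        assert explained == pytest.approx(1.0)

    def test_uncorrelated_equal_variance_splits_fifty_fifty(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(2000)
        b = rng.standard_normal(2000)
        # center, then orthogonalize exactly so PC1 explains exactly half
        a = a - a.mean()
        b = b - b.mean()
        b = b - a * (a @ b) / (a @ a)
        _, explained = composite_fitness(self._frame(a, b))
        assert explained == pytest.approx(0.5, abs=1e-12)

    def test_sign_convention_positive_with_seed_mass(self):
        rng = np.random.default_rng(1)
        il = rng.standard_normal(50)
        seed_mass = 0.8 * il + 0.3 * rng.standard_normal(50)
        scores, _ = composite_fitness(self._frame(il, seed_mass))
        assert np.corrcoef(scores, seed_mass)[0, 1] > 0
        assert np.corrcoef(scores, il)[0, 1] > 0

    def test_invariant_to_proxy_rescaling(self):
        rng = np.random.default_rng(2)
        il = rng.standard_normal(40)
        sm_ = il + rng.standard_normal(40)
        s1, _ = composite_fitness(self._frame(il, sm_))
        s2, _ = composite_fitness(self._frame(1000 * il, 0.001 * sm_))
        np.testing.assert_allclose(s1, s2, atol=1e-10)

    def test_zero_variance_proxy_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            composite_fitness(self._frame(np.ones(5), np.arange(5.0)))


class TestBetaPoint:
    def test_exact_linear_fitness_recovered_to_machine_precision(self):
        df = _sire_frame(30, beta=(0.3, -0.2, 0.0, 0.0), noise=0.0)
        grad = estimate_beta_point(df, "fitness", relativize=False)
        np.testing.assert_allclose(grad.beta, [0.3, -0.2, 0.0, 0.0], atol=1e-12)

    def test_orthogonal_traits_match_simple_slopes(self):
        rng = np.random.default_rng(3)
        raw = rng.standard_normal((40, 4))
        raw = raw - raw.mean(axis=0)
        X = np.linalg.qr(raw)[0]  # orthonormal columns, still centered
        w = 1 + X @ np.array([0.5, -0.3, 0.2, 0.1]) + 0.1 * rng.standard_normal(40)
        df = pd.DataFrame(X, columns=FOUR)
        df["population"] = "P1"
        df["sire"] = [f"S{i}" for i in range(40)]
        df["fitness"] = w
        grad = estimate_beta_point(df, "fitness", relativize=False)
        for j, t in enumerate(FOUR):
            xc = X[:, j]
            slope = (xc @ (w - w.mean())) / (xc @ xc)
            assert grad.beta[t] == pytest.approx(slope, abs=1e-8)

    def test_noisy_recovery_within_three_standard_errors(self):
        truth = np.array([0.3, -0.2, 0.1, 0.0])
        df = _sire_frame(300, seed=4, beta=tuple(truth), noise=0.5)
        grad = estimate_beta_point(df, "fitness", relativize=False)
        # homoskedastic OLS SE ~ sigma / sqrt(n) for standard-normal regressors
        se = 0.5 / np.sqrt(300)
        assert np.all(np.abs(grad.beta.to_numpy() - truth) < 3.5 * se)

    def test_relative_fitness_scaling_invariance(self):
        df = _sire_frame(100, seed=5, noise=0.3)
        a = estimate_beta_point(df, "fitness")
        df2 = df.assign(fitness=df["fitness"] * 37.0)
        b = estimate_beta_point(df2, "fitness")
        np.testing.assert_allclose(a.beta, b.beta, rtol=1e-10)

    def test_collinear_design_warns_but_returns(self):
        df = _sire_frame(50, seed=6, noise=0.1)
        df[FOUR[1]] = 2.0 * df[FOUR[0]] + 1e-9 * df[FOUR[1]]
        with pytest.warns(UserWarning, match="collinear"):
            grad = estimate_beta_point(df, "fitness")
        assert np.isfinite(grad.beta).all()

    def test_too_few_sires_rejected(self):
        with pytest.raises(ValueError, match="more sires"):
            estimate_beta_point(_sire_frame(5), "fitness")

    def test_centered_fitness_score_cannot_be_relativized(self):
        df = _sire_frame(40, seed=11, noise=0.3)
        df["fitness"] = df["fitness"] - df["fitness"].mean()
        with pytest.raises(ValueError, match="relativize"):
            estimate_beta_point(df, "fitness", relativize=True)
        grad = estimate_beta_point(df, "fitness", relativize=False)
        assert np.isfinite(grad.beta).all()


class TestBetaBayes:
    def test_default_draw_count_is_10000(self):
        df = _sire_frame(60, seed=7, noise=0.4)
        grad = estimate_beta_bayes(df, "fitness", seed=0)
        assert grad.n_draws == 10_000
        assert grad.mode == "posterior"

    def test_posterior_mean_close_to_ols_under_weak_prior(self):
        df = _sire_frame(80, seed=8, noise=0.4)
        ols = estimate_beta_point(df, "fitness")
        bay = estimate_beta_bayes(df, "fitness", seed=1)
        sd = bay.draws.std()
        assert np.all(np.abs(bay.beta - ols.beta) < 2 * sd)

    def test_posterior_concentrates_on_truth_with_big_clean_data(self):
        truth = np.array([0.3, -0.2, 0.1, 0.0])
        df = _sire_frame(10_000, seed=9, beta=tuple(truth), noise=0.01)
        bay = estimate_beta_bayes(df, "fitness", n_draws=2000, seed=2,
                                  relativize=False)
        np.testing.assert_allclose(bay.beta.to_numpy(), truth, atol=0.005)
        assert np.all(bay.draws.std() < 0.005)

    def test_seeded_reproducibility(self):
        df = _sire_frame(60, seed=10, noise=0.4)
        a = estimate_beta_bayes(df, "fitness", n_draws=500, seed=3)
        b = estimate_beta_bayes(df, "fitness", n_draws=500, seed=3)
        pd.testing.assert_frame_equal(a.draws, b.draws)
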