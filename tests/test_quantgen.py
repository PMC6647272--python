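"""Variance components, heritability and correlations, checked against
independent oracles (statsmodels ANOVA; direct REML likelihood maximization).
"""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from peagain.quantgen import (
    BalanceError,
    PhenotypeTable,
    blup_line_means,
    cv_g,
    estimate_vc_multi_env,
    estimate_vc_single_env,
    genetic_correlation,
    h2_multi_env,
    h2_single_env,
    trait_correlations,
)
from peagain.simdata import SimConfig, simulate_study


def _balanced_table(n_lines=8, n_envs=2, n_blocks=3, s_g=1.0, s_ge=0.5, s_e=0.8, seed=0):
    rng = np.random.default_rng(seed)
    g = rng.normal(0, s_g, n_lines)
    ge = rng.normal(0, s_ge, (n_lines, n_envs))
    rows = []
    for j in range(n_envs):
        e_eff = rng.normal(0, 1)
        for r in range(n_blocks):
            b_eff = rng.normal(0, 0.3)
            for i in range(n_lines):
                rows.append(
                    (f"l{i}", "p1", f"e{j}", f"b{r}",
                     10 + e_eff + g[i] + ge[i, j] + b_eff + rng.normal(0, s_e))
                )
    return PhenotypeTable(pd.DataFrame(rows, columns=["line", "population", "environment", "block", "y"]))


def _reml_single_env_oracle(df, trait="y"):
    """Direct restricted-likelihood maximization: y = blocks(fixed) + g + e."""
    lines = sorted(df["line"].unique())
    blocks = sorted(df["block"].unique())
    z = pd.get_dummies(df["line"]).loc[:, lines].to_numpy(float)
    x = np.column_stack([np.ones(len(df)), pd.get_dummies(df["block"]).loc[:, blocks[1:]].to_numpy(float)])
    y = df[trait].to_numpy(float)
    n, q = x.shape

    def neg_reml(theta):
        s_g2, s_e2 = np.exp(theta)
        v = s_g2 * z @ z.T + s_e2 * np.eye(n)
        vinv = np.linalg.inv(v)
        xtvx = x.T @ vinv @ x
        beta = np.linalg.solve(xtvx, x.T @ vinv @ y)
        r = y - x @ beta
        _, ld_v = np.linalg.slogdet(v)
        _, ld_x = np.linalg.slogdet(xtvx)
        return 0.5 * (ld_v + ld_x + r @ vinv @ r)

    res = optimize.minimize(neg_reml, np.log([0.5, 0.5]), method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
    return np.exp(res.x)


class TestSingleEnv:
    def test_null_case(self):
        rng = np.random.default_rng(1)
        rows = [
            (f"l{i}", "p1", "e1", f"b{r}", 5 + rng.normal(0, 0.5))
            for i in range(10)
            for r in range(3)
        ]
        ph = PhenotypeTable(pd.DataFrame(rows, columns=["line", "population", "environment", "block", "y"]))
        vc = estimate_vc_single_env(ph, "e1", "y")
        assert vc.S_G2 < 0.1

    def test_equals_reml_oracle(self):
        ph = _balanced_table(n_envs=1, seed=3)
        vc = estimate_vc_single_env(ph, "e0", "y")
        s_g2, s_e2 = _reml_single_env_oracle(ph.data)
        assert vc.S_G2 == pytest.approx(s_g2, rel=1e-3, abs=1e-4)
        assert vc.S_e2 == pytest.approx(s_e2, rel=1e-3, abs=1e-4)

    def test_statsmodels_anova_oracle(self):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        ph = _balanced_table(n_envs=1, seed=4)
        model = ols("y ~ C(line) + C(block)", data=ph.data).fit()
        table = sm.stats.anova_lm(model, typ=1)
        ms_g = table.loc["C(line)", "sum_sq"] / table.loc["C(line)", "df"]
        ms_e = table.loc["Residual", "sum_sq"] / table.loc["Residual", "df"]
        vc = estimate_vc_single_env(ph, "e0", "y")
        assert vc.S_e2 == pytest.approx(ms_e, rel=1e-10)
        assert vc.S_G2 == pytest.approx((ms_g - ms_e) / 3, rel=1e-10)

    def test_unbalanced_rejected(self):
        ph = _balanced_table(n_envs=1)
        broken = PhenotypeTable(ph.data.iloc[:-1].copy())
        with pytest.raises(BalanceError):
            estimate_vc_single_env(broken, "e0", "y")

    def test_h2_recovery(self):
        cfg = SimConfig(seed=21, n_markers=150, lines_per_pop=100, n_qtl=40,
                        h2_per_env={"env1": 0.6, "env2": 0.6, "env3": 0.6})
        _, ph, _ = simulate_study(cfg)
        vc = estimate_vc_single_env(ph, "env1", "trait")
        assert h2_single_env(vc.S_G2, vc.S_e2, vc.n_reps) == pytest.approx(0.6, abs=0.1)


class TestMultiEnv:
    def test_sum_of_squares_partition(self):
        from peagain.quantgen import _pooled_multi_env_ss

        ph = _balanced_table(n_envs=3, seed=5)
        a = _pooled_multi_env_ss(ph.data, "y")
        y = ph.data["y"].to_numpy()
        ss_tot = ((y - y.mean()) ** 2).sum()
        assert sum(a["ss"].values()) == pytest.approx(ss_tot, rel=1e-10)

    def test_duplicated_environment_kills_gei(self):
        ph = _balanced_table(n_envs=1, s_e=0.01, seed=6)
        dup = ph.data.copy()
        dup["environment"] = "e1"
        both = PhenotypeTable(pd.concat([ph.data, dup], ignore_index=True))
        vc = estimate_vc_multi_env(both, "y")
        assert vc.S_GE2 < 0.01

    def test_null_gei_not_significant(self):
        cfg = SimConfig(seed=22, n_markers=100, lines_per_pop=40, gei_sd_ratio=0.0)
        _, ph, _ = simulate_study(cfg)
        vc = estimate_vc_multi_env(ph, "trait")
        assert vc.p_values["S_GE2"] > 0.05

    def test_ratio_recovery_table3_preset(self):
        # variance-ratio target 0.39 -> gei_sd_ratio = sqrt(1/0.39)
        target = 0.39
        s_g, s_ge = [], []
        for seed in range(5):
            cfg = SimConfig(seed=40 + seed, n_markers=150, lines_per_pop=100,
                            n_qtl=40, gei_sd_ratio=float(np.sqrt(1 / target)))
            _, ph, _ = simulate_study(cfg)
            vc = estimate_vc_multi_env(ph, "trait")
            s_g.append(vc.S_G2)
            s_ge.append(vc.S_GE2)
        assert np.mean(s_g) / np.mean(s_ge) == pytest.approx(target, rel=0.25)

    def test_population_factor_components(self, small_pheno):
        vc = estimate_vc_multi_env(small_pheno, "trait", with_population_factor=True)
        for name in ("S_R2", "S_GR2", "S_RE2", "S_GRE2"):
            assert getattr(vc, name) is not None and getattr(vc, name) >= 0
        assert vc.S_G2 is None

    def test_single_env_rejected(self):
        ph = _balanced_table(n_envs=1)
        with pytest.raises(BalanceError):
            estimate_vc_multi_env(ph, "y")


class TestFormulas:
    def test_cv_g(self):
        assert cv_g(0.0, 5.0) == 0.0
        assert cv_g(1.0, 10.0) == pytest.approx(10.0)

    def test_cv_g_scale_invariance(self):
        assert cv_g(4.0, 10.0) == pytest.approx(cv_g(16.0, 20.0))

    def test_cv_g_zero_mean(self):
        with pytest.raises(ValueError):
            cv_g(1.0, 0.0)

    def test_h2_single(self):
        assert h2_single_env(1.0, 0.0, 3) == 1.0
        assert h2_single_env(1.0, 2.0, 3) == pytest.approx(0.6)

    def test_h2_single_monotone_in_reps(self):
        values = [h2_single_env(1.0, 2.0, n) for n in (1, 2, 5, 10)]
        assert values == sorted(values)

    def test_h2_multi(self):
        assert h2_multi_env(1.0, 0.0, 0.0, 3, 3) == 1.0
        assert h2_multi_env(2.0, 3.0, 6.0, 3, 3) == pytest.approx(0.5455, abs=1e-4)

    def test_h2_multi_reduces_to_single(self):
        assert h2_multi_env(1.5, 0.0, 2.0, 1, 3) == pytest.approx(h2_single_env(1.5, 2.0, 3))

    def test_h2_degenerate(self):
        with pytest.raises(ValueError):
            h2_single_env(0.0, 0.0, 3)

    def test_genetic_correlation(self):
        r_g, flag = genetic_correlation(0.3, 0.8, 0.75)
        assert r_g == pytest.approx(0.5) and not flag

    def test_genetic_correlation_identity(self):
        assert genetic_correlation(0.4, 1.0, 1.0)[0] == pytest.approx(0.4)
        assert genetic_correlation(0.0, 0.5, 0.5)[0] == 0.0

    def test_genetic_correlation_flag(self):
        r_g, flag = genetic_correlation(0.9, 0.5, 0.5)
        assert flag and r_g > 1


class TestBlup:
    def test_shrinkage_contraction(self, small_pheno):
        blups = blup_line_means(small_pheno, "env1", "trait")
        means = small_pheno.line_means("trait", environment="env1")
        assert blups.var() <= means.var()

    def test_limits(self):
        # near-noiseless data -> BLUP ~ line mean
        ph = _balanced_table(n_envs=1, s_e=1e-4, seed=7)
        blups = blup_line_means(ph, "e0", "y")
        means = ph.line_means("y", environment="e0")
        np.testing.assert_allclose(blups, means, rtol=1e-3)

    def test_full_shrinkage(self):
        rng = np.random.default_rng(8)
        rows = [
            (f"l{i}", "p1", "e1", f"b{r}", rng.normal())
            for i in range(20)
            for r in range(3)
        ]
        ph = PhenotypeTable(pd.DataFrame(rows, columns=["line", "population", "environment", "block", "y"]))
        blups = blup_line_means(ph, "e1", "y")
        # pure noise: H2 near 0, all BLUPs near the grand mean
        assert blups.std() < ph.line_means("y").std()


class TestTraitCorrelations:
    def test_self_and_negation(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=30)})
        df["b"] = -df["a"]
        r, p = trait_correlations(df)["pooled"]
        assert r.loc["a", "a"] == 1.0
        assert r.loc["a", "b"] == pytest.approx(-1.0)

    def test_null_correlations_small(self, rng):
        hits = 0
        for seed in range(20):
            local = np.random.default_rng(seed)
            df = pd.DataFrame(local.normal(size=(300, 2)), columns=["a", "b"])
            r, _ = trait_correlations(df)["pooled"]
            if abs(r.loc["a", "b"]) < 0.2:
                hits += 1
        assert hits >= 19

    def test_constant_column_flagged(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=10), "b": np.ones(10)})
        r, p = trait_correlations(df)["pooled"]
        assert np.isnan(r.loc["a", "b"])
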