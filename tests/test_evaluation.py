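import numpy as np
import pandas as pd
import pytest
from scipy import stats

from peagain.evaluation import (
    inter_environment_cv,
    inter_population_prediction,
    predictive_ability,
    rmsd_model_selection,
    run_cv,
    stratified_kfold,
)
from peagain.quantgen import blup_line_means
from peagain.simdata import SimConfig, simulate_study


@pytest.fixture(scope="module")
def study():
    cfg = SimConfig(seed=51, n_markers=200, lines_per_pop=40, n_qtl=30,
                    gei_sd_ratio=0.4,
                    h2_per_env={"env1": 0.6, "env2": 0.6, "env3": 0.6})
    g, ph, _ = simulate_study(cfg)
    blups = {env: blup_line_means(ph, env, "trait") for env in ph.environments}
    return g, ph, blups


class TestStratifiedKFold:
    def test_partition(self, study):
        g, _, _ = study
        folds = stratified_kfold(g.line_ids, g.populations, 10, seed=1)
        assert len(folds) == g.n_lines
        assert set(folds) == set(range(10))

    def test_proportional_counts(self):
        # 306 lines split 102/100/104 as in a three-cross panel
        ids, pops = [], {}
        for pop, n in (("A", 102), ("B", 100), ("C", 104)):
            for i in range(n):
                lid = f"{pop}{i}"
                ids.append(lid)
                pops[lid] = pop
        folds = stratified_kfold(ids, pops, 10, seed=2)
        df = pd.DataFrame({"fold": folds, "pop": [pops[l] for l in ids]})
        counts = df.groupby(["pop", "fold"]).size()
        for pop in "ABC":
            per_fold = counts[pop]
            assert per_fold.min() >= 10 and per_fold.max() <= 11

    def test_leave_one_out_boundary(self):
        ids = [f"l{i}" for i in range(8)]
        pops = {l: "p" for l in ids}
        folds = stratified_kfold(ids, pops, 8, seed=3)
        assert sorted(folds) == list(range(8))

    def test_small_population_rejected(self):
        ids = ["a", "b"]
        with pytest.raises(ValueError, match="lines < k"):
            stratified_kfold(ids, {l: "p" for l in ids}, 5)

    def test_deterministic(self, study):
        g, _, _ = study
        f1 = stratified_kfold(g.line_ids, g.populations, 10, seed=9)
        f2 = stratified_kfold(g.line_ids, g.populations, 10, seed=9)
        np.testing.assert_array_equal(f1, f2)


class TestPredictiveAbility:
    def test_perfect(self, study):
        g, _, blups = study
        y = blups["env1"]
        assert predictive_ability(y, y, g.populations) == pytest.approx(1.0)

    def test_mean_of_population_correlations(self, rng, study):
        g, _, _ = study
        obs = pd.Series(rng.normal(size=g.n_lines), index=g.line_ids)
        pred = pd.Series(rng.normal(size=g.n_lines), index=g.line_ids)
        expected = np.mean([
            stats.pearsonr(
                obs[[l for l in g.line_ids if g.populations[l] == p]],
                pred[[l for l in g.line_ids if g.populations[l] == p]],
            ).statistic
            for p in sorted(set(g.populations.values()))
        ])
        assert predictive_ability(obs, pred, g.populations) == pytest.approx(expected)

    def test_per_population_offset_invariance(self, rng, study):
        g, _, blups = study
        obs = blups["env1"]
        pred = obs + pd.Series(rng.normal(size=g.n_lines), index=g.line_ids)
        shifted = pred.copy()
        pop0 = sorted(set(g.populations.values()))[0]
        members = [l for l in g.line_ids if g.populations[l] == pop0]
        shifted.loc[members] += 7.5
        assert predictive_ability(obs, shifted, g.populations) == pytest.approx(
            predictive_ability(obs, pred, g.populations)
        )

    def test_constant_population_excluded_with_warning(self, rng):
        ids = [f"l{i}" for i in range(20)]
        pops = {l: ("A" if i < 10 else "B") for i, l in enumerate(ids)}
        obs = pd.Series(rng.normal(size=20), index=ids)
        pred = obs.copy()
        pred.iloc[:10] = 1.0  # constant within A
        with pytest.warns(UserWarning, match="'A'"):
            r = predictive_ability(obs, pred, pops)
        assert r == pytest.approx(1.0)  # only B contributes


class TestRunCV:
    def test_deterministic(self, study):
        g, _, blups = study
        a = run_cv({"kind": "rrblup"}, g, blups["env1"], k=5, repetitions=2, seed=3)
        b = run_cv({"kind": "rrblup"}, g, blups["env1"], k=5, repetitions=2, seed=3)
        assert a.predictive_ability == b.predictive_ability
        assert a.records.equals(b.records)

    def test_population_first_averaging(self, study):
        g, _, blups = study
        res = run_cv({"kind": "rrblup"}, g, blups["env1"], k=5, repetitions=2, seed=4)
        manual = res.records.groupby("repetition")["r"].mean().mean()
        assert res.predictive_ability == pytest.approx(manual)

    def test_null_heritability_gives_null_ability(self):
        cfg = SimConfig(seed=52, n_markers=150, lines_per_pop=100, n_qtl=30,
                        h2_per_env={"env1": 0.01, "env2": 0.01, "env3": 0.01})
        g, ph, _ = simulate_study(cfg)
        y = blup_line_means(ph, "env1", "trait")
        res = run_cv({"kind": "rrblup"}, g, y, k=5, repetitions=2, seed=5)
        # near-zero heritability: either no signal, or (fully shrunk model)
        # constant predictions in every population and no defined correlation
        assert np.isnan(res.predictive_ability) or abs(res.predictive_ability) < 0.15

    def test_repetitions_reduce_variance(self, study):
        g, _, blups = study
        singles = [
            run_cv({"kind": "rrblup"}, g, blups["env1"], k=5, repetitions=1, seed=s).predictive_ability
            for s in range(8)
        ]
        multis = [
            run_cv({"kind": "rrblup"}, g, blups["env1"], k=5, repetitions=8, seed=100 + s).predictive_ability
            for s in range(4)
        ]
        assert np.std(multis) < np.std(singles) + 0.02


class TestInterEnvironment:
    def test_duplicated_environment_equals_intra(self, study):
        g, _, blups = study
        dup = {"env1": blups["env1"], "copy": blups["env1"].copy()}
        intra = run_cv({"kind": "rrblup"}, g, blups["env1"], k=5, repetitions=2, seed=6)
        inter = inter_environment_cv({"kind": "rrblup"}, g, dup, "env1",
                                     k=5, repetitions=2, seed=6)
        assert inter["copy"].predictive_ability == pytest.approx(
            intra.predictive_ability, abs=1e-12
        )

    def test_strong_gei_degrades_inter_env(self):
        worse = 0
        for seed in range(5):
            cfg = SimConfig(seed=60 + seed, n_markers=150, lines_per_pop=50,
                            n_qtl=30, gei_sd_ratio=2.0,
                            h2_per_env={"env1": 0.7, "env2": 0.7, "env3": 0.7})
            g, ph, _ = simulate_study(cfg)
            blups = {env: blup_line_means(ph, env, "trait") for env in ph.environments}
            intra = run_cv({"kind": "rrblup"}, g, blups["env1"], k=5, repetitions=1,
                           seed=seed).predictive_ability
            inter = inter_environment_cv({"kind": "rrblup"}, g, blups, "env1",
                                         k=5, repetitions=1, seed=seed)
            mean_inter = np.mean([r.predictive_ability for r in inter.values()])
            if mean_inter < intra:
                worse += 1
        assert worse >= 4


class TestInterPopulation:
    def test_degenerate_control(self, study):
        g, _, blups = study
        pops = sorted(set(g.populations.values()))
        res = inter_population_prediction(
            {"kind": "rrblup"}, g, blups, pops[0], "env1", validation_scope="same_env"
        )
        assert res.scenario == "intra_env_inter_pop"
        assert set(res.validation_pops) == set(pops[1:])
        assert -1 <= res.predictive_ability <= 1

    def test_unknown_population(self, study):
        g, _, blups = study
        with pytest.raises(ValueError, match="unknown population"):
            inter_population_prediction({"kind": "rrblup"}, g, blups, "nope", "env1")

    def test_intra_beats_inter_on_average(self, study):
        g, _, blups = study
        pops = sorted(set(g.populations.values()))
        intra = run_cv({"kind": "rrblup"}, g, blups["env1"], k=5, repetitions=3,
                       seed=7).predictive_ability
        inter = np.mean([
            inter_population_prediction({"kind": "rrblup"}, g, blups, p, "env1").predictive_ability
            for p in pops
        ])
        assert intra > inter


class TestRMSDSelection:
    def _table(self):
        return pd.DataFrame(
            {
                "model": ["a", "a", "b", "b"],
                "threshold": [0.01, 0.01, 0.01, 0.01],
                "trait": ["t1", "t2", "t1", "t2"],
                "pa": [0.50, 0.70, 0.48, 0.66],
            }
        )

    def test_best_config_rank1(self):
        out = rmsd_model_selection(self._table())
        assert out.iloc[0]["model"] == "a"
        assert out.iloc[0]["rmsd"] == pytest.approx(0.0)

    def test_hand_rmsd(self):
        out = rmsd_model_selection(self._table())
        row_b = out[out["model"] == "b"].iloc[0]
        assert row_b["rmsd"] == pytest.approx(np.sqrt((0.02**2 + 0.04**2) / 2), abs=1e-6)
        assert row_b["rmsd"] == pytest.approx(0.03162, abs=1e-4)

    def test_trait_order_invariance(self):
        t = self._table()
        shuffled = t.iloc[[3, 1, 0, 2]].reset_index(drop=True)
        a = rmsd_model_selection(t)
        b = rmsd_model_selection(shuffled)
        pd.testing.assert_frame_equal(a, b)

    def test_incomplete_grid_rejected(self):
        t = self._table().iloc[:-1]
        with pytest.raises(ValueError, match="incomplete"):
            rmsd_model_selection(t)
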