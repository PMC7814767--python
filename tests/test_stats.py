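import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
import statsmodels.api as sm

import envconn as ec
from envconn.stats import (
    StatsError,
    beta_contrast_matrix,
    effect_size_ratio,
    max_stat_test,
    residualize,
    score_beta_matrix,
    welch_contrast_matrix,
    welch_t_stat,
)


class TestResidualize:
    def test_perfect_fit_gives_zero_residuals(self, rng):
        x = rng.standard_normal(50)
        r = residualize(x, x)
        assert np.max(np.abs(r)) < 1e-10

    def test_all_zero_regressor_rejected(self, rng):
        with pytest.raises(StatsError, match="rank"):
            residualize(rng.standard_normal(50), np.zeros(50))

    def test_residuals_orthogonal_to_regressor(self, rng):
        age = rng.uniform(20, 70, size=80)
        y = 2 * age + rng.standard_normal(80)
        r = residualize(y, age)
        assert abs(np.corrcoef(r, age)[0, 1]) < 1e-10

    def test_matches_statsmodels_ols_residuals(self, rng):
        X = rng.standard_normal((60, 4))
        y = rng.standard_normal(60)
        ours = residualize(y, X)
        theirs = sm.OLS(y, sm.add_constant(X)).fit().resid
        np.testing.assert_allclose(ours, theirs, atol=1e-10)

    def test_keep_mean_preserves_sample_mean(self, rng):
        X = rng.standard_normal((60, 3))
        y = rng.standard_normal(60) + 5.0
        r = residualize(y, X, keep_mean=True)
        assert r.mean() == pytest.approx(y.mean(), abs=1e-10)
        # confound variance still removed
        full = residualize(y, X)
        np.testing.assert_allclose(r - r.mean(), full, atol=1e-10)


class TestWelch:
    def test_matches_scipy_on_random_samples(self, rng):
        a = rng.standard_normal(5) + 0.3
        b = rng.standard_normal(5)
        t, df = welch_t_stat(a, b)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert df == pytest.approx(ref.df, abs=1e-10)

    def test_identical_groups_give_zero_t(self, rng):
        x = rng.standard_normal(10)
        t, _ = welch_t_stat(x, x.copy())
        assert t == pytest.approx(0.0, abs=1e-12)

    def test_behavioral_contrast_family_and_nulls(self, toy6):
        spec = ec.CohortSpec(conn=toy6, n_group_a=15, n_group_b=15,
                             duration=10.0, seed=31)
        _, table, _ = ec.generate_cohort(spec)
        df = ec.behavioral_contrast(table)
        assert (df["family_size"] == 8).all()
        assert set(df["score"]) == set(ec.BEHAVIORAL_SCORES)
        assert ((df["p"] >= 0) & (df["p"] <= 1)).all()

    def test_behavioral_contrast_matches_direct_formula(self, rng):
        n = 12
        rows = []
        for g in ("patient", "control"):
            for i in range(n):
                rows.append(dict(group=g, age=rng.uniform(30, 60),
                                 sex=int(rng.integers(0, 2)),
                                 education=rng.uniform(10, 20),
                                 benzodiazepine=int(rng.integers(0, 2)),
                                 SDMT=rng.standard_normal() + (g == "patient")))
        table = pd.DataFrame(rows)
        out = ec.behavioral_contrast(table, scores=("SDMT",))
        # independent route: residualize then scipy Welch
        res = []
        for g, extra in (("patient", ["benzodiazepine"]), ("control", [])):
            sub = table[table.group == g]
            X = sub[["age", "sex", "education"] + extra].to_numpy(float)
            res.append(residualize(sub["SDMT"].to_numpy(), X, keep_mean=True))
        ref = sps.ttest_ind(res[0], res[1], equal_var=False)
        assert out.loc[0, "t"] == pytest.approx(ref.statistic, abs=1e-10)
        assert out.loc[0, "p"] == pytest.approx(ref.pvalue, abs=1e-10)


class TestStatMatrices:
    def test_welch_matrix_single_entry_equals_direct(self, rng):
        a = rng.standard_normal((8, 1))
        b = rng.standard_normal((9, 1))
        sm_ = welch_contrast_matrix(a, b)
        ref = sps.ttest_ind(a[:, 0], b[:, 0], equal_var=False)
        assert sm_.values[0] == pytest.approx(ref.statistic, abs=1e-12)

    def test_beta_exact_linear_recovery(self, rng):
        score = rng.standard_normal(30)
        values = 3.0 * score[:, None]  # rsFC entry exactly linear in score
        beta = score_beta_matrix(values - values.mean(0),
                                 score - score.mean()).values
        assert beta[0] == pytest.approx(3.0, abs=1e-10)

    def test_beta_matches_statsmodels_multiple_regression(self, rng):
        n = 60
        conf = rng.standard_normal((n, 3))
        score = rng.standard_normal(n)
        values = (0.8 * score + conf @ [0.5, -0.2, 0.1]
                  + 0.3 * rng.standard_normal(n))[:, None]
        rv = residualize(values, conf)
        rs = residualize(score, conf)
        ours = score_beta_matrix(rv, rs).values[0]
        X = sm.add_constant(np.column_stack([score, conf]))
        theirs = sm.OLS(values[:, 0], X).fit().params[1]
        assert ours == pytest.approx(theirs, abs=1e-10)

    def test_beta_recovery_within_monte_carlo_band(self, rng):
        # independent oracle: statsmodels refits on fresh replicates define
        # the sampling band; our estimator must live inside it
        betas_ours, betas_ref = [], []
        for _ in range(200):
            score = rng.standard_normal(60)
            values = (0.8 * score + 0.6 * rng.standard_normal(60))[:, None]
            betas_ours.append(
                score_beta_matrix(values - values.mean(0),
                                  score - score.mean()).values[0])
            betas_ref.append(
                sm.OLS(values[:, 0], sm.add_constant(score)).fit().params[1])
        lo, hi = np.percentile(betas_ref, [2.5, 97.5])
        assert lo < np.mean(betas_ours) < hi
        assert np.mean(betas_ours) == pytest.approx(0.8, abs=0.05)

    def test_delta_beta_sign_tracks_planted_coupling(self, rng):
        """With a score-connectivity coupling planted only in group A, the
        sign of the beta contrast matches the planted weight's sign in
        nearly all replicates."""
        hits = 0
        for _ in range(100):
            sa = rng.standard_normal(30)
            va = (0.7 * sa + 0.5 * rng.standard_normal(30))[:, None]
            sb = rng.standard_normal(30)
            vb = 0.5 * rng.standard_normal((30, 1))
            d = beta_contrast_matrix(va - va.mean(0), sa - sa.mean(),
                                     vb - vb.mean(0), sb - sb.mean()).values
            hits += d[0] > 0
        assert hits >= 90

    def test_delta_beta_antisymmetric_under_group_swap(self, rng):
        va, vb = rng.standard_normal((10, 4)), rng.standard_normal((12, 4))
        sa, sb = rng.standard_normal(10), rng.standard_normal(12)
        d1 = beta_contrast_matrix(va, sa, vb, sb).values
        d2 = beta_contrast_matrix(vb, sb, va, sa).values
        np.testing.assert_allclose(d1, -d2, atol=1e-12)


class TestMaxStatTest:
    def _null_data(self, rng, n=15, m=20):
        return rng.standard_normal((n, m)), rng.standard_normal((n, m))

    def test_observed_below_all_nulls_gives_p_one(self, rng):
        a, b = self._null_data(rng)
        obs = ec.StatMatrix(np.zeros(20), "welch_t")
        res = max_stat_test(obs, values_a=a, values_b=b, n_perm=200, seed=1)
        assert res.p_max == 1.0

    def test_p_max_within_attainable_grid(self, rng):
        a, b = self._null_data(rng)
        obs = welch_contrast_matrix(a, b)
        res = max_stat_test(obs, values_a=a, values_b=b, n_perm=250, seed=2)
        assert 1 / 251 <= res.p_max <= 1.0

    def test_threshold_monotone_in_family_size(self, rng):
        a, b = self._null_data(rng)
        obs = welch_contrast_matrix(a, b)
        r1 = max_stat_test(obs, values_a=a, values_b=b, n_perm=300, seed=3,
                           family_size=1)
        r38 = max_stat_test(obs, values_a=a, values_b=b, n_perm=300, seed=3,
                            family_size=38)
        assert r38.threshold >= r1.threshold

    def test_fixed_seed_reproducible(self, rng):
        a, b = self._null_data(rng)
        obs = welch_contrast_matrix(a, b)
        r1 = max_stat_test(obs, values_a=a, values_b=b, n_perm=200, seed=4)
        r2 = max_stat_test(obs, values_a=a, values_b=b, n_perm=200, seed=4)
        np.testing.assert_array_equal(r1.null_max, r2.null_max)

    def test_n_perm_minimum_enforced(self, rng):
        a, b = self._null_data(rng)
        obs = welch_contrast_matrix(a, b)
        with pytest.raises(StatsError, match="n_perm"):
            max_stat_test(obs, values_a=a, values_b=b, n_perm=50)

    def test_score_shuffle_scheme_calibrated(self, rng):
        """Permutation p of the observed max beta is uniform when the score
        is independent of the data."""
        pv = []
        for _ in range(120):
            v = rng.standard_normal((25, 10))
            s = rng.standard_normal(25)
            vc, sc = v - v.mean(0), s - s.mean()
            obs = score_beta_matrix(vc, sc)
            pv.append(max_stat_test(obs, values=vc, score=sc, n_perm=200,
                                    rng=rng).p_max)
        assert sps.kstest(pv, "uniform").pvalue > 0.01

    def test_planted_group_effect_detected(self, toy6):
        """The planted connectivity reduction wins the max statistic,
        carries the right sign, and survives correction in the majority
        of replicate cohorts."""
        wins = supra = 0
        n_rep = 6
        for r in range(n_rep):
            ge = ec.GroupEffect(0, 0, 1, 0, -0.35)
            spec = ec.CohortSpec(conn=toy6, n_group_a=25, n_group_b=25,
                                 duration=60.0, group_effects=[ge],
                                 seed=77 + r)
            sig, tab, _ = ec.generate_cohort(spec)
            res, es = ec.run_group_contrast(sig, tab, toy6, n_perm=400,
                                            seed=177 + r)
            k = int(np.nanargmax(np.abs(res.observed.values)))
            meta = es.meta.iloc[k]
            if ({meta["i"], meta["j"]}, {meta["a"], meta["b"]}) == ({0, 1},
                                                                   {0}):
                wins += res.observed.values[k] < 0
            supra += bool(res.supra[k]) and res.observed.values[k] < 0
        assert wins >= n_rep - 1
        assert supra > n_rep / 2


class TestEffectSizeRatio:
    def test_identical_connections_ratio_one(self):
        conn = ec.toy_connectome(4, 1)
        from envconn.stats import EntrySet
        # all connections share one subject profile -> no averaging gain
        n_subj = 40
        rngl = np.random.default_rng(5)
        base = rngl.standard_normal(n_subj) * 0.2 + 1.0
        pairs = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        nw = np.tile(base[:, None], (1, len(pairs)))
        meta = pd.DataFrame([dict(i=i, a=0, j=j, b=0) for i, j in pairs])
        nset = EntrySet([(i, j) for i, j in pairs], meta, "nodewise")
        nets = conn.networks
        node_net = [nets.index(nd.network) for nd in conn.nodes]
        mn_meta = pd.DataFrame([dict(u=0, a=0, v=1, b=0)])
        mset = EntrySet([(0, 1)], mn_meta, "mean_network")
        sel = [k for k, (i, j) in enumerate(pairs)
               if {node_net[i], node_net[j]} == {0, 1}]
        mn_vals = nw[:, sel].mean(axis=1, keepdims=True)
        ratio = effect_size_ratio(mn_vals, nw, mset, nset, conn)
        assert ratio[0] == pytest.approx(1.0, abs=1e-10)

    def test_independent_connections_gain_sqrt_k(self):
        """k independent same-mean connections: averaging boosts the
        effect size by ~sqrt(k)."""
        from envconn.stats import EntrySet
        rngl = np.random.default_rng(6)
        # 2 networks x 4 nodes -> k = 16 cross-network pairs
        from envconn.parcellation import ConnectomeDef, NodeDef, default_bands
        nodes = tuple(NodeDef(f"N{i}", "DMN" if i < 4 else "DAN", "L")
                      for i in range(8))
        conn = ConnectomeDef(nodes, default_bands()[:1])
        pairs = [(i, j) for i in range(8) for j in range(i + 1, 8)]
        cross = [(i, j) for i, j in pairs if (i < 4) != (j < 4)]
        n_subj = 800
        nw = 1.0 + rngl.standard_normal((n_subj, len(pairs)))
        meta = pd.DataFrame([dict(i=i, a=0, j=j, b=0) for i, j in pairs])
        nset = EntrySet(pairs, meta, "nodewise")
        mset = EntrySet([(0, 1)], pd.DataFrame([dict(u=0, a=0, v=1, b=0)]),
                        "mean_network")
        sel = [k for k, (i, j) in enumerate(pairs) if (i, j) in cross]
        mn_vals = nw[:, sel].mean(axis=1, keepdims=True)
        ratio = effect_size_ratio(mn_vals, nw, mset, nset, conn)
        assert ratio[0] == pytest.approx(np.sqrt(16), rel=0.15)

    def test_zero_sd_rejected(self):
        from envconn.stats import EntrySet
        conn = ec.toy_connectome(2, 1)
        nw = np.ones((5, 1))
        nset = EntrySet([(0, 1)], pd.DataFrame([dict(i=0, a=0, j=1, b=0)]),
                        "nodewise")
        mset = EntrySet([(0, 1)], pd.DataFrame([dict(u=0, a=0, v=1, b=0)]),
                        "mean_network")
        with pytest.raises(StatsError, match="zero standard deviation"):
            effect_size_ratio(nw, nw, mset, nset, conn)


class TestAnalysisPlan:
    def test_registered_families(self):
        plan = ec.AnalysisPlan()
        assert plan.rsfc_family == 38
        assert plan.behavioral_family == 8

    def test_desk_scale_plan_scales_down(self):
        plan = ec.AnalysisPlan(n_contrasts=1, n_patient_scores=1,
                               n_control_scores=0, levels=1)
        assert plan.rsfc_family == 2
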