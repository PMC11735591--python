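"""Association battery: domain scores, correlations, ANCOVA, stepwise, LRT, FDR."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from jointica.simulate import DOMAIN_TESTS, DOMAINS, SimConfig, generate_dataset
from jointica.stats import (
    ancova_tukey,
    cognitive_domain_scores,
    compare_models_lrt,
    encode_sex,
    fdr_bh,
    partial_pearson,
    spearman_assoc,
    stepwise_regression,
)


class TestCognitiveDomainScores:
    def test_zscore_worked_case(self):
        raw = pd.DataFrame({"t1": [1.0, 2.0, 3.0], "t2": [3.0, 2.0, 1.0]})
        out = cognitive_domain_scores(raw, {"d": ["t1"]})
        np.testing.assert_allclose(out["d"], [-1, 0, 1])

    def test_domain_is_mean_of_test_zscores(self):
        raw = pd.DataFrame({"t1": [1.0, 2.0, 3.0], "t2": [3.0, 2.0, 1.0]})
        out = cognitive_domain_scores(raw, {"d": ["t1", "t2"]})
        np.testing.assert_allclose(out["d"], [0, 0, 0], atol=1e-12)

    def test_generator_domains_match_regenerated_scores(self, small_data):
        """Scores rebuilt from raw tests correlate near-perfectly with the
        generator's latent domain scores (tests are noisy affine copies)."""
        ds, gt = small_data
        out = cognitive_domain_scores(ds.subjects.set_index("id"), DOMAIN_TESTS)
        for d, dom in enumerate(DOMAINS):
            r = np.corrcoef(out[dom], gt.domain_scores[:, d])[0, 1]
            assert r > 0.95

    def test_constant_test_rejected(self):
        raw = pd.DataFrame({"t1": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="constant"):
            cognitive_domain_scores(raw, {"d": ["t1"]})

    def test_cohort_zscores_have_unit_sample_sd(self, small_data):
        ds, _ = small_data
        raw = ds.subjects.set_index("id")
        out = cognitive_domain_scores(raw, {"d": ["sdmt"]})
        assert out["d"].mean() == pytest.approx(0, abs=1e-10)
        assert out["d"].std(ddof=1) == pytest.approx(1, abs=1e-10)


class TestSpearmanAssoc:
    def _frames(self, rng, n=50):
        idx = pd.Index([f"s{i}" for i in range(n)])
        loadings = pd.DataFrame(rng.normal(size=(n, 3)), index=idx,
                                columns=["c1", "c2", "c3"])
        summaries = pd.DataFrame(rng.normal(size=(n, 2)), index=idx,
                                 columns=["cgm_volume", "mean_fa"])
        return loadings, summaries

    def test_identity_and_monotone_invariance(self, rng):
        loadings, summaries = self._frames(rng)
        summaries["cgm_volume"] = loadings["c1"]
        summaries["mean_fa"] = np.exp(loadings["c2"])
        df = spearman_assoc(loadings, summaries).set_index(["component", "target"])
        assert df.loc[("c1", "cgm_volume"), "r"] == pytest.approx(1.0)
        assert df.loc[("c2", "mean_fa"), "r"] == pytest.approx(1.0)

    def test_matches_brute_force_rank_correlation(self, rng):
        loadings, summaries = self._frames(rng)
        df = spearman_assoc(loadings, summaries)
        for _, row in df.iterrows():
            x = loadings[row.component].rank().to_numpy()
            y = summaries[row.target].rank().to_numpy()
            assert row.r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_fdr_family_is_per_summary_column(self, rng):
        loadings, summaries = self._frames(rng)
        df = spearman_assoc(loadings, summaries, fdr_family="per_summary")
        for target, grp in df.groupby("target"):
            np.testing.assert_allclose(grp["p_fdr"], fdr_bh(grp["p"].to_numpy()))
        assert (df["p_fdr"] >= df["p"] - 1e-15).all()


class TestPartialPearson:
    def test_identity_gives_r_one(self, rng):
        x = rng.normal(size=50)
        cov = rng.normal(size=(50, 2))
        r, p = partial_pearson(x, x, cov)
        assert r == pytest.approx(1.0)

    def test_outcome_explained_by_covariates_is_degenerate(self, rng):
        cov = rng.normal(size=(50, 2))
        y = cov @ [1.0, -2.0] + 3
        x = rng.normal(size=50)
        with pytest.raises(ValueError, match="residual variance"):
            partial_pearson(y, x, cov)

    def test_empty_covariates_equal_plain_pearson(self, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        r, _ = partial_pearson(y, x)
        assert r == pytest.approx(stats.pearsonr(x, y)[0], abs=1e-12)

    def test_matches_recursive_correlation_formula(self, rng):
        """Two-covariate partial correlation via the recursion
        r_xy.z = (r_xy - r_xz r_yz) / sqrt((1-r_xz^2)(1-r_yz^2)), applied
        twice — an independent closed-form path."""
        n = 50
        x, y = rng.normal(size=n), rng.normal(size=n)
        z1, z2 = rng.normal(size=n), rng.normal(size=n)

        def r_(a, b):
            return np.corrcoef(a, b)[0, 1]

        def partial1(rab, raz, rbz):
            return (rab - raz * rbz) / np.sqrt((1 - raz ** 2) * (1 - rbz ** 2))

        # first remove z1 from every pairwise correlation, then remove z2
        rxy_1 = partial1(r_(x, y), r_(x, z1), r_(y, z1))
        rxz2_1 = partial1(r_(x, z2), r_(x, z1), r_(z2, z1))
        ryz2_1 = partial1(r_(y, z2), r_(y, z1), r_(z2, z1))
        expected = partial1(rxy_1, rxz2_1, ryz2_1)
        r, _ = partial_pearson(y, x, np.column_stack([z1, z2]))
        assert r == pytest.approx(expected, abs=1e-12)

    def test_matches_pingouin_cross_check(self, rng):
        pingouin = pytest.importorskip("pingouin")
        n = 60
        df = pd.DataFrame(rng.normal(size=(n, 4)), columns=["x", "y", "a", "b"])
        r, p = partial_pearson(df["y"], df["x"], df[["a", "b"]].to_numpy())
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["a", "b"])
        assert r == pytest.approx(ref["r"].item(), abs=1e-10)
        assert p == pytest.approx(ref["p_val"].item(), abs=1e-10)


class TestAncovaTukey:
    def test_no_group_effect_gives_small_f(self, rng):
        n = 60
        group = np.repeat(["a", "b", "c"], 20)
        cov = pd.DataFrame({"age": rng.normal(45, 10, n)})
        y = 0.5 * cov["age"].to_numpy()  # depends only on the covariate
        res = ancova_tukey(y, group, cov)
        assert res["F"] == pytest.approx(0.0, abs=1e-18)
        assert res["p"] > 0.999

    def test_two_groups_reduce_to_t_test_oracle(self, rng):
        """With k=2 the Tukey p equals the two-sided t-test p of the
        adjusted contrast: P(Q_{2,df} > sqrt(2)|t|) = P(|T_df| > |t|)."""
        n = 40
        group = np.repeat(["a", "b"], 20)
        cov = pd.DataFrame({"age": rng.normal(size=n)})
        y = (group == "b") * 0.7 + 0.3 * cov["age"].to_numpy() + rng.normal(size=n)
        res = ancova_tukey(y, group, cov)
        X = sm.add_constant(np.column_stack([(group == "b").astype(float), cov]))
        fit = sm.OLS(y, X).fit()
        t_p = fit.pvalues[1]
        assert res["tukey"]["p_tukey"].iloc[0] == pytest.approx(t_p, abs=1e-8)

    def test_group_shift_power_simulation(self):
        """1-SD group shift at n=30/group rejects at alpha=.05 nearly always."""
        rejections = 0
        n_sims = 200
        for i in range(n_sims):
            r = np.random.default_rng(i)
            group = np.repeat(["a", "b"], 30)
            cov = pd.DataFrame({"age": r.normal(45, 10, 60),
                                "sex": r.integers(0, 2, 60).astype(float)})
            y = (group == "b") * 1.0 + r.normal(size=60)
            rejections += ancova_tukey(y, group, cov)["p"] < 0.05
        assert rejections / n_sims >= 0.90

    def test_singular_design_rejected(self):
        group = np.repeat(["a", "b"], 10)
        cov = pd.DataFrame({"dup": (group == "b").astype(float)})
        with pytest.raises(ValueError, match="singular"):
            ancova_tukey(np.arange(20, dtype=float), group, cov)


class TestStepwiseRegression:
    def test_no_candidates_returns_covariate_model(self, rng):
        n = 40
        forced = pd.DataFrame({"age": rng.normal(size=n)})
        y = forced["age"].to_numpy() + rng.normal(size=n)
        res = stepwise_regression(y, pd.DataFrame(index=forced.index), forced)
        assert res.selected == []
        assert res.forced == ["age"]

    def test_true_driver_selected_among_twenty(self, rng):
        n = 80
        cands = pd.DataFrame(rng.normal(size=(n, 20)),
                             columns=[f"comp{i}" for i in range(20)])
        forced = pd.DataFrame({"age": rng.normal(size=n)})
        y = 2.0 * cands["comp3"].to_numpy() + 0.05 * rng.normal(size=n)
        res = stepwise_regression(y, cands, forced)
        assert "comp3" in res.selected
        # oracle: exhaustive best subset of size <= 2 also picks comp3
        best = None
        for size in (1, 2):
            for combo in itertools.combinations(cands.columns, size):
                X = sm.add_constant(pd.concat([forced, cands[list(combo)]], axis=1))
                aic = sm.OLS(y, X).fit().aic
                if best is None or aic < best[0]:
                    best = (aic, combo)
        assert "comp3" in best[1]

    def test_aic_never_worse_than_covariates_only(self, rng):
        n = 50
        cands = pd.DataFrame(rng.normal(size=(n, 10)),
                             columns=[f"c{i}" for i in range(10)])
        forced = pd.DataFrame({"age": rng.normal(size=n)})
        y = rng.normal(size=n)
        res = stepwise_regression(y, cands, forced)
        base = sm.OLS(y, sm.add_constant(forced)).fit()
        assert res.aic <= base.aic + 1e-9

    def test_collinear_candidate_skipped_with_warning(self, rng):
        n = 40
        forced = pd.DataFrame({"age": rng.normal(size=n)})
        cands = pd.DataFrame({"c0": rng.normal(size=n)})
        cands["c1"] = cands["c0"]  # exact duplicate
        y = 3 * cands["c0"].to_numpy() + 0.1 * rng.normal(size=n)
        with pytest.warns(UserWarning, match="collinear"):
            res = stepwise_regression(y, cands, forced)
        assert res.selected == ["c0"]

    def test_forced_covariates_never_dropped(self, rng):
        n = 60
        forced = pd.DataFrame({"age": rng.normal(size=n), "sex": rng.integers(0, 2, n)})
        cands = pd.DataFrame(rng.normal(size=(n, 5)), columns=[f"c{i}" for i in range(5)])
        y = rng.normal(size=n)  # covariates useless — must still stay
        res = stepwise_regression(y, cands, forced)
        assert res.forced == ["age", "sex"]
        assert {"age", "sex"} <= set(res.params.index)


class TestCompareModelsLrt:
    def test_identical_models_give_zero_statistic(self, rng):
        n = 30
        x = rng.normal(size=(n, 2))
        y = x @ [1.0, 0.5] + rng.normal(size=n)
        m = sm.OLS(y, sm.add_constant(x)).fit()
        res = compare_models_lrt(m, m)
        assert res["statistic"] == 0.0
        assert res["p"] == 1.0

    def test_closed_form_oracle_rss_halving(self):
        """Nested OLS with n=10 and RSS 20 -> 10 gives 2*dll = 10 ln 2 and the
        chi-square(1) upper tail at that value."""
        n = 10

        def ll(rss):
            return -n / 2 * (np.log(2 * np.pi * rss / n) + 1)

        class Fake:
            def __init__(self, rss, k):
                self.llf = ll(rss)
                self.df_model = k
                self.nobs = n

        res = compare_models_lrt(Fake(20.0, 1), Fake(10.0, 2))
        expected = 10 * np.log(2)
        assert res["statistic"] == pytest.approx(expected, rel=1e-12)
        assert res["p"] == pytest.approx(stats.chi2.sf(expected, 1), rel=1e-12)
        assert res["p"] == pytest.approx(0.00847, abs=2e-4)

    def test_different_n_rejected(self, rng):
        y1 = rng.normal(size=20)
        y2 = rng.normal(size=25)
        m1 = sm.OLS(y1, np.ones((20, 1))).fit()
        m2 = sm.OLS(y2, np.ones((25, 1))).fit()
        with pytest.raises(ValueError, match="different n"):
            compare_models_lrt(m1, m2)

    def test_null_p_values_uniform(self):
        """Adding a pure-noise regressor yields uniform LRT p-values
        (KS test at alpha=0.01 over 500 simulated fits)."""
        ps = []
        n = 100
        for i in range(500):
            r = np.random.default_rng(i)
            x = r.normal(size=(n, 2))
            y = x @ [0.5, -0.3] + r.normal(size=n)
            noise = r.normal(size=n)
            m0 = sm.OLS(y, sm.add_constant(x)).fit()
            m1 = sm.OLS(y, sm.add_constant(np.column_stack([x, noise]))).fit()
            ps.append(compare_models_lrt(m0, m1)["p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_non_nested_flagged(self, rng):
        n = 40
        cands = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("abcd"))
        y = cands["a"].to_numpy() + rng.normal(size=n)
        y2 = cands["b"].to_numpy() + rng.normal(size=n)
        ra = stepwise_regression(y, cands[["a"]], None)
        rb = stepwise_regression(y, cands[["b"]], None)
        res = compare_models_lrt(ra, rb)
        assert res["non_nested"] in (True, False)
        if set(ra.selected) != set(rb.selected) and ra.selected and rb.selected:
            assert res["non_nested"] is True


class TestFdrBh:
    def test_hand_computed_vectors(self):
        np.testing.assert_allclose(fdr_bh([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])
        np.testing.assert_allclose(fdr_bh([0.005, 0.04, 0.5]),
                                   [0.015, 0.06, 0.5])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(fdr_bh([0.123]), [0.123])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.5])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20),
           st.randoms(use_true_random=False))
    def test_permutation_invariance(self, ps, rnd):
        ps = np.asarray(ps)
        perm = list(range(len(ps)))
        rnd.shuffle(perm)
        adj = fdr_bh(ps)
        adj_perm = fdr_bh(ps[perm])
        inv = np.empty_like(adj_perm)
        inv[perm] = adj_perm
        np.testing.assert_allclose(inv, adj, atol=1e-12)

    def test_adjusted_at_least_raw_and_capped(self, rng):
        p = rng.uniform(size=25)
        adj = fdr_bh(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)


def test_encode_sex_binary():
    np.testing.assert_array_equal(encode_sex(["M", "F", "M"]), [1.0, 0.0, 1.0])
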