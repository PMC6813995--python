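import numpy as np
import pandas as pd
import pytest

import osteorate as ost
from osteorate.comparative import pca, phylo_anova, screen_genes, size_residuals
from osteorate.errors import FitError, InvalidInputError
from osteorate.phylo import covariance
from osteorate.simulate import SimulationConfig, gen_branch_rates, gen_traits, gen_tree


def series(vals, tips):
    return pd.Series(list(vals), index=list(tips))


class TestPglsFit:
    def test_star_tree_equals_ols(self, star_tree_factory, rng):
        from scipy import stats as st

        t = star_tree_factory(12)
        x = rng.normal(size=12)
        y = 0.5 * x + rng.normal(size=12)
        fit = ost.pgls_fit(series(y, t.tip_labels),
                           pd.DataFrame({"x": x}, index=t.tip_labels), t, lam=0.0)
        ols = st.linregress(x, y)
        assert fit.coefficients["x"] == pytest.approx(ols.slope, abs=1e-8)
        assert fit.coefficients["intercept"] == pytest.approx(ols.intercept, abs=1e-8)
        assert fit.p_values["x"] == pytest.approx(ols.pvalue, abs=1e-8)
        assert fit.r2 == pytest.approx(ols.rvalue**2, abs=1e-8)

    def test_matches_brute_force_gls_oracle(self, five_tip_tree, gls_oracle, rng):
        t = five_tip_tree
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        fit = ost.pgls_fit(series(y, t.tip_labels),
                           pd.DataFrame({"x": x}, index=t.tip_labels), t, lam=1.0)
        beta, se, tv, p, r2 = gls_oracle(y, x, covariance(t, 1.0))
        np.testing.assert_allclose(fit.coefficients.values, beta, atol=1e-8)
        np.testing.assert_allclose(fit.se.values, se, atol=1e-8)
        np.testing.assert_allclose(fit.p_values.values, p, atol=1e-8)
        assert fit.r2 == pytest.approx(r2, abs=1e-8)

    def test_lambda_profile_dominates_grid(self, rng):
        """ML lambda's likelihood is no worse than at 0, 0.5 and 1."""
        t = gen_tree(20, seed=4)
        for lam_true in (0.0, 0.7, 1.0):
            y = pd.Series(ost.simulate_bm(t, 1.0, lam=lam_true, seed=rng.integers(2**31)))
            x = pd.DataFrame({"x": rng.normal(size=20)}, index=t.tip_labels)
            fit = ost.pgls_fit(y, x, t)
            for lam in (0.0, 0.5, 1.0):
                fixed = ost.pgls_fit(y, x, t, lam=lam)
                assert fit.loglik >= fixed.loglik - 1e-6

    def test_singular_design_names_columns(self, star_tree_factory, rng):
        t = star_tree_factory(10)
        x = rng.normal(size=10)
        X = pd.DataFrame({"a": x, "b": 2 * x}, index=t.tip_labels)
        y = series(rng.normal(size=10), t.tip_labels)
        with pytest.raises(FitError, match="collinear"):
            ost.pgls_fit(y, X, t)

    def test_too_few_cases(self, three_tip_tree):
        y = series([1.0, 2.0, 3.0], three_tip_tree.tip_labels)
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0]}, index=three_tip_tree.tip_labels)
        with pytest.raises(FitError, match="complete cases"):
            ost.pgls_fit(y, X, three_tip_tree)

    def test_listwise_deletion_prunes_tree(self, rng):
        t = gen_tree(10, seed=6)
        y = series(rng.normal(size=10), t.tip_labels)
        y.iloc[3] = np.nan
        X = pd.DataFrame({"x": rng.normal(size=10)}, index=t.tip_labels)
        fit = ost.pgls_fit(y, X, t)
        assert fit.n == 9
        assert t.tip_labels[3] not in fit.species


class TestTwoStep:
    def test_noise_free_linear_data_survives_every_deletion(self, star_tree_factory):
        t = star_tree_factory(10)
        x = np.linspace(0, 1, 10)
        y = 2.0 * x + 1.0
        res = ost.two_step_verification(
            series(y, t.tip_labels), pd.DataFrame({"x": x}, index=t.tip_labels), t
        )
        assert res.p_all < 1e-6
        assert res.p_robust < 1e-6
        assert res.p_max < 1e-6

    def test_planted_outlier_flagged_fragile(self, star_tree_factory, rng):
        t = star_tree_factory(10)
        x = np.r_[rng.normal(size=9) * 0.1, 10.0]
        y = np.r_[rng.normal(size=9) * 0.1, 10.0]
        res = ost.two_step_verification(
            series(y, t.tip_labels), pd.DataFrame({"x": x}, index=t.tip_labels), t
        )
        assert res.p_all < 0.05
        assert res.p_max > 0.05

    def test_minimal_n5_matches_manual_loo(self, star_tree_factory, rng):
        t = star_tree_factory(5)
        x = rng.normal(size=5)
        y = 0.8 * x + rng.normal(size=5) * 0.5
        ys = series(y, t.tip_labels)
        X = pd.DataFrame({"x": x}, index=t.tip_labels)
        res = ost.two_step_verification(ys, X, t)
        loo = []
        for drop in t.tip_labels:
            keep = [s for s in t.tip_labels if s != drop]
            loo.append(float(ost.pgls_fit(ys[keep], X.loc[keep], t).p_values["x"]))
        assert len(loo) == 5
        assert res.p_max == pytest.approx(max(loo))

    def test_order_invariance_of_p_max(self, star_tree_factory, rng):
        t = star_tree_factory(8)
        x = rng.normal(size=8)
        y = 0.5 * x + rng.normal(size=8)
        perm = list(np.random.default_rng(1).permutation(t.tip_labels))
        a = ost.two_step_verification(
            series(y, t.tip_labels), pd.DataFrame({"x": x}, index=t.tip_labels), t
        )
        b = ost.two_step_verification(
            series(y, t.tip_labels)[perm],
            pd.DataFrame({"x": x}, index=t.tip_labels).loc[perm], t,
        )
        assert a.p_max == pytest.approx(b.p_max)
        assert a.p_all == pytest.approx(b.p_all)


class TestSizeResiduals:
    def test_uncorrelated_size_returns_centered_y(self, star_tree_factory, rng):
        t = star_tree_factory(40)
        y = rng.normal(size=40)
        md = rng.normal(size=40)
        res = size_residuals(series(y, t.tip_labels), series(md, t.tip_labels), t)
        assert np.corrcoef(res.values, (y - y.mean())[
            [t.tip_labels.index(s) for s in res.index]
        ])[0, 1] > 0.95

    def test_exact_size_dependence_vanishes(self, star_tree_factory, rng):
        t = star_tree_factory(10)
        md = rng.normal(size=10)
        res = size_residuals(series(2 * md, t.tip_labels), series(md, t.tip_labels), t)
        assert np.abs(res.values).max() < 1e-10

    def test_gene_rate_slope_recovered_after_size_correction(self, rng):
        """Response = size effect + independent rate effect; regressing the
        phylogenetic size residuals on the rate recovers the rate slope."""
        t = gen_tree(27, seed=12)
        slopes = []
        for rep in range(60):
            md = np.asarray(ost.simulate_bm_matrix(t, 1.0, seed=rng, n_rep=1))[0]
            rate = rng.normal(size=27)
            noise = np.asarray(ost.simulate_bm_matrix(t, 0.25, seed=rng, n_rep=1))[0]
            y = 1.5 * md + 0.7 * rate + noise
            res = size_residuals(series(y, t.tip_labels), series(md, t.tip_labels), t)
            fit = ost.pgls_fit(res, pd.DataFrame({"r": rate}, index=t.tip_labels), t)
            slopes.append(float(fit.coefficients["r"]))
        mean = np.mean(slopes)
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(mean - 0.7) < 4 * se + 0.05


class TestPhyloAnova:
    def test_perfect_separation_gives_smallest_possible_p(self, star_tree_factory):
        t = star_tree_factory(10)
        groups = series(["a"] * 5 + ["b"] * 5, t.tip_labels)
        y = series([0.0] * 5 + [1.0] * 5, t.tip_labels)
        res = phylo_anova(y, groups, t, n_sim=199, seed=0)
        assert res.p_phylo == pytest.approx(1 / 200)

    def test_constant_trait_degenerate(self, star_tree_factory):
        t = star_tree_factory(8)
        groups = series(["a"] * 4 + ["b"] * 4, t.tip_labels)
        y = series([1.0] * 8, t.tip_labels)
        res = phylo_anova(y, groups, t, n_sim=99, seed=0)
        assert res.p_phylo == 1.0

    def test_small_group_rejected(self, star_tree_factory):
        t = star_tree_factory(6)
        groups = series(["a"] * 5 + ["b"], t.tip_labels)
        y = series(np.arange(6.0), t.tip_labels)
        with pytest.raises(InvalidInputError, match="fewer than 2"):
            phylo_anova(y, groups, t, n_sim=99, seed=0)

    def test_star_tree_matches_classical_anova(self, star_tree_factory, rng):
        """With no phylogenetic structure the simulated null reproduces the
        F distribution, so p_phylo tracks the exact F-test P value."""
        from scipy import stats as st

        t = star_tree_factory(30)
        groups = series(["a", "b", "c"] * 10, t.tip_labels)
        diffs = []
        for rep in range(10):
            y = rng.normal(size=30)
            y[:10] += 0.8
            ys = series(y, t.tip_labels)
            res = phylo_anova(ys, groups, t, n_sim=1999, seed=int(rng.integers(2**31)))
            g = [y[(groups.values == lev)] for lev in ("a", "b", "c")]
            p_exact = st.f_oneway(*g).pvalue
            diffs.append(res.p_phylo - p_exact)
        assert np.abs(np.mean(diffs)) < 0.02
        assert np.abs(diffs).max() < 0.06

    def test_reproducible_under_seed(self, star_tree_factory, rng):
        t = star_tree_factory(12)
        groups = series(["a"] * 6 + ["b"] * 6, t.tip_labels)
        y = series(rng.normal(size=12), t.tip_labels)
        r1 = phylo_anova(y, groups, t, n_sim=299, seed=5)
        r2 = phylo_anova(y, groups, t, n_sim=299, seed=5)
        assert r1.p_phylo == r2.p_phylo
        pd.testing.assert_frame_equal(r1.pairwise, r2.pairwise)

    def test_pairwise_symmetric_and_in_unit_interval(self, rng):
        t = gen_tree(18, seed=13)
        groups = series(["a", "b", "c"] * 6, t.tip_labels)
        y = series(rng.normal(size=18), t.tip_labels)
        res = phylo_anova(y, groups, t, n_sim=199, seed=3)
        pw = res.pairwise
        assert np.allclose(pw.values, pw.values.T)
        off = pw.values[~np.eye(3, dtype=bool)]
        assert np.all((off >= 1 / 200) & (off <= 1.0))


class TestPca:
    def test_two_perfectly_correlated_variables(self, rng):
        x = rng.normal(size=30)
        tab = pd.DataFrame({"a": x, "b": 3 * x + 1})
        res = pca(tab, ["a", "b"])
        assert res.variance_explained[0] == pytest.approx(1.0, abs=1e-10)

    def test_isotropic_data_splits_variance_evenly(self, rng):
        tab = pd.DataFrame(rng.normal(size=(4000, 4)), columns=list("abcd"))
        res = pca(tab, list("abcd"))
        assert np.allclose(res.variance_explained, 0.25, atol=0.03)

    def test_fractions_sum_to_one_and_scores_centered(self, rng):
        tab = pd.DataFrame(rng.normal(size=(25, 5)) @ rng.normal(size=(5, 5)),
                           columns=list("abcde"))
        res = pca(tab, list("abcde"))
        assert res.variance_explained.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(res.variance_explained) <= 1e-12)
        assert np.allclose(res.scores.mean(axis=0), 0.0, atol=1e-10)
        G = res.loadings.values.T @ res.loadings.values
        assert np.allclose(G, np.eye(5), atol=1e-10)

    def test_constant_variable_named_in_error(self, rng):
        tab = pd.DataFrame({"a": rng.normal(size=10), "b": np.ones(10)})
        with pytest.raises(FitError, match="b"):
            pca(tab, ["a", "b"])


class TestScreenGenes:
    def _cohort(self, seed=21, n_genes=12, n_coupled=3):
        cfg = SimulationConfig(seed=seed, n_genes=n_genes, n_coupled=n_coupled)
        t = gen_tree(27, seed)
        tr = gen_traits(t, cfg)
        sim = gen_branch_rates(t, tr, cfg)
        tab = ost.build_rate_table(sim.rates, t)
        return t, tr, sim, tab

    def test_composition_equals_direct_calls(self):
        t, tr, sim, tab = self._cohort()
        gene = tab.index[0]
        rep = screen_genes(tab.loc[[gene]], tr.table, t, ["Cc"])
        y = tr.table["Cc"]
        X = pd.DataFrame({"rate": tab.loc[gene]})
        fit = ost.pgls_fit(y, X, t)
        ts = ost.two_step_verification(y, X, t, predictor="rate")
        row = rep.iloc[0]
        assert row["p_all"] == pytest.approx(float(fit.p_values["rate"]))
        assert row["slope"] == pytest.approx(float(fit.coefficients["rate"]))
        assert row["lambda_hat"] == pytest.approx(fit.lambda_hat)
        assert row["p_robust"] == pytest.approx(ts.p_robust)
        assert row["p_max"] == pytest.approx(ts.p_max)

    def test_constant_rates_never_flagged(self):
        t, tr, sim, tab = self._cohort()
        flat = tab.copy()
        flat.loc[:, :] = 0.2
        rep = screen_genes(flat, tr.table, t, ["Cc", "Cp"], compute_two_step=False)
        assert not rep["flagged"].any()
        assert (rep["note"] == "constant predictor").all()

    def test_report_shape_and_sorting(self):
        t, tr, sim, tab = self._cohort()
        rep = screen_genes(tab, tr.table, t, ["Cc", "Cp"], compute_two_step=False,
                           bh_column=True)
        assert len(rep) == len(tab) * 2
        p = rep["p_all"].dropna().values
        assert np.all(np.diff(p) >= 0)
        assert {"gene", "variable", "n", "slope", "lambda_hat", "r2",
                "p_all", "flagged", "p_bh"} <= set(rep.columns)

    def test_size_residual_mode_runs_and_changes_response(self):
        t, tr, sim, tab = self._cohort()
        raw = screen_genes(tab, tr.table, t, ["Cc"], compute_two_step=False)
        res = screen_genes(tab, tr.table, t, ["Cc"], size_proxy="MD",
                           use_size_residuals=True, compute_two_step=False)
        assert not np.allclose(raw["p_all"].values, res["p_all"].values)
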