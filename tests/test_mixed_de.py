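"""Weighted random-intercept fits, moderation, B-statistic, Wilcoxon."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from conftest import model_scale_cohort
from hierde.mixed_de import (
    MixedDE,
    ModerationResult,
    fit_gene_lmm,
    fit_all,
    ebayes_moderate,
    b_statistic,
    bonferroni,
    wilcoxon_region,
    ols_pvalues,
)


def _one_sample_meta(n_per_group=8, seed=0):
    """One sample per subject: the LMM collapses to two-sample OLS."""
    rows = []
    for i in range(n_per_group):
        rows.append(dict(sample_id=f"A{i}", subject_id=f"A{i}", region="HIP",
                         diagnosis="AD", age=80.0 + i, sex="M", apoe4=0, braak=3))
        rows.append(dict(sample_id=f"C{i}", subject_id=f"C{i}", region="HIP",
                         diagnosis="control", age=81.0 + i, sex="F", apoe4=0,
                         braak=2))
    return pd.DataFrame(rows)


class TestFitGeneLMM:
    def test_collapses_to_group_mean_difference(self):
        meta = _one_sample_meta()
        rng = np.random.default_rng(1)
        y = rng.normal(size=len(meta))
        fit = fit_gene_lmm(y, None, meta)
        is_ad = (meta["diagnosis"] == "AD").to_numpy()
        expected = y[is_ad].mean() - y[~is_ad].mean()
        assert fit.logFC == pytest.approx(expected, abs=1e-10)

    def test_weight_scale_invariance(self, small_meta):
        rng = np.random.default_rng(2)
        y = rng.normal(size=len(small_meta))
        w = rng.uniform(0.5, 2.0, size=len(small_meta))
        f1 = fit_gene_lmm(y, w, small_meta)
        f2 = fit_gene_lmm(y, 2.0 * w, small_meta)
        assert f1.logFC == pytest.approx(f2.logFC, abs=1e-10)
        assert f1.tau2 == pytest.approx(f2.tau2, abs=1e-10)
        assert f1.sigma2 == pytest.approx(f2.sigma2, abs=1e-10)

    def test_matches_statsmodels_reml(self, cohort_meta):
        """Independent oracle: statsmodels MixedLM REML, unweighted."""
        import statsmodels.api as sm
        Y = model_scale_cohort(cohort_meta, 5, tau=0.5, sigma=0.5,
                               logfc=0.4, seed=3)
        X = np.column_stack([np.ones(len(cohort_meta)),
                             (cohort_meta["diagnosis"] == "AD").to_numpy(float)])
        for g in range(5):
            y = Y.iloc[g].to_numpy()
            ours = fit_gene_lmm(y, None, cohort_meta)
            ref = sm.MixedLM(y, X, groups=cohort_meta["subject_id"]).fit(reml=True)
            assert ours.logFC == pytest.approx(ref.fe_params[1], abs=1e-5)
            assert ours.tau2 == pytest.approx(
                float(np.asarray(ref.cov_re)[0, 0]), abs=1e-4)
            assert ours.sigma2 == pytest.approx(ref.scale, rel=1e-4)

    def test_wls_identity_at_zero_tau(self, small_meta):
        """When REML picks τ̂² = 0 the fit equals weighted least squares."""
        rng = np.random.default_rng(4)
        n = len(small_meta)
        # zero between-subject spread: subject means are identical, so the
        # REML optimum sits on the τ² = 0 boundary
        sign = np.where(small_meta["region"] == "HIP", 1.0, -1.0)
        y = 0.4 * (small_meta["diagnosis"] == "AD").to_numpy(float) + sign
        w = rng.uniform(0.5, 3.0, size=n)
        fit = fit_gene_lmm(y, w, small_meta)
        assert fit.tau2 == 0.0
        X = np.column_stack([np.ones(n),
                             (small_meta["diagnosis"] == "AD").to_numpy(float)])
        wn = w / w.mean()
        beta_wls = np.linalg.solve(X.T @ (wn[:, None] * X), X.T @ (wn * y))
        assert fit.logFC == pytest.approx(beta_wls[1], abs=1e-8)

    def test_tau2_monte_carlo_recovery(self, cohort_meta):
        """Mean τ̂² over 500 simulated genes within ±10% of τ² = 0.25."""
        Y = model_scale_cohort(cohort_meta, 500, tau=0.5, sigma=0.5, seed=5)
        tab = fit_all(Y, None, cohort_meta)
        assert abs(tab["tau2"].mean() - 0.25) < 0.025

    def test_requires_two_subjects_per_group(self):
        meta = _one_sample_meta(n_per_group=2)
        meta = meta[meta["subject_id"] != "A1"].reset_index(drop=True)
        with pytest.raises(ValueError, match="2 subjects"):
            fit_gene_lmm(np.zeros(len(meta)), None, meta)


class TestFitAll:
    def test_row_count_flags_and_determinism(self, small_meta):
        rng = np.random.default_rng(6)
        Y = rng.normal(size=(100, len(small_meta)))
        Y[7] = 1.5  # constant gene: degenerate, flagged, never dropped
        E = pd.DataFrame(Y, index=[f"g{i}" for i in range(100)],
                         columns=small_meta["sample_id"])
        t1 = fit_all(E, None, small_meta)
        t2 = fit_all(E, None, small_meta)
        assert len(t1) == 100
        assert not t1.loc[7, "converged"]
        assert t1["converged"].sum() == 99
        pd.testing.assert_frame_equal(t1, t2)


class TestModeration:
    def test_equal_variances_are_fixed_point(self):
        fits = pd.DataFrame({"sigma2": np.full(100, 0.3),
                             "df_resid": np.full(100, 10.0)})
        mod = ebayes_moderate(fits)
        assert np.allclose(mod.s_tilde2, 0.3, atol=1e-6)
        assert mod.d0 == np.inf  # no excess spread → complete shrinkage

    def test_infinite_d0_limit_gives_prior_variance(self):
        mod = ModerationResult(d0=np.inf, s0_2=0.25,
                               s_tilde2=np.full(5, 0.25),
                               df_total=np.full(5, np.inf))
        assert np.allclose(mod.s_tilde2, mod.s0_2)

    def test_hyperparameter_recovery(self):
        """s²_g ~ s₀²·F(d_g, d₀) with d₀ = 4, s₀² = 0.25 over 5000 genes."""
        rng = np.random.default_rng(7)
        d0, s0_2, dg = 4.0, 0.25, 10.0
        s2 = s0_2 * (rng.chisquare(dg, 5000) / dg) / (rng.chisquare(d0, 5000) / d0)
        fits = pd.DataFrame({"sigma2": s2, "df_resid": np.full(5000, dg)})
        mod = ebayes_moderate(fits)
        assert abs(mod.d0 - d0) / d0 < 0.15
        assert abs(mod.s0_2 - s0_2) / s0_2 < 0.05

    def test_posterior_between_prior_and_observed(self):
        rng = np.random.default_rng(8)
        s2 = rng.chisquare(8, 500) / 8 * 0.4
        fits = pd.DataFrame({"sigma2": s2, "df_resid": np.full(500, 8.0)})
        mod = ebayes_moderate(fits)
        lo = np.minimum(s2, mod.s0_2)
        hi = np.maximum(s2, mod.s0_2)
        assert np.all(mod.s_tilde2 >= lo - 1e-12)
        assert np.all(mod.s_tilde2 <= hi + 1e-12)


class TestBStatistic:
    def _direct(self, t, df, se, p1, v0):
        """Direct evaluation of the two-component posterior-odds formula."""
        v = se ** 2
        r = (v + v0) / v
        odds = (p1 / (1 - p1)) * r ** -0.5 * (
            (t ** 2 + df) / (t ** 2 / r + df)) ** ((df + 1) / 2)
        return np.log(odds)

    def test_matches_direct_formula_and_monotone(self):
        rng = np.random.default_rng(9)
        t = rng.normal(scale=3, size=200)
        df = np.full(200, 12.0)
        se = np.full(200, 0.4)
        B = b_statistic(t, df, se, prior_prob=0.01, v0=0.5)
        direct = self._direct(t, df, se, 0.01, 0.5)
        assert np.allclose(B, direct, atol=1e-12)
        order_t = np.argsort(np.abs(t))
        assert np.all(np.diff(B[order_t]) > 0)

    def test_zero_t_is_minimum_and_symmetry(self):
        t = np.array([0.0, -2.0, 2.0, 5.0])
        B = b_statistic(t, np.full(4, 10.0), np.full(4, 0.3),
                        prior_prob=0.01, v0=0.4)
        assert B[0] == B.min()
        assert B[1] == pytest.approx(B[2], abs=1e-12)

    def test_estimated_v0_separates_signal(self):
        """With planted large |t|, estimated v₀ ranks signal genes on top."""
        rng = np.random.default_rng(10)
        t = rng.standard_t(12, size=2000)
        t[:20] += 8.0
        df = np.full(2000, 12.0)
        se = np.full(2000, 0.3)
        B = b_statistic(t, df, se, prior_prob=0.01)
        assert set(np.argsort(-B)[:20]) == set(np.argsort(-np.abs(t))[:20])


class TestBonferroni:
    @pytest.mark.parametrize("p,m,expected", [
        (0.5, 3, 1.0),
        (1e-6, 50281, 0.050281),
        (0.0, 100, 0.0),
    ])
    def test_known_values(self, p, m, expected):
        assert bonferroni(p, m) == pytest.approx(expected, abs=1e-12)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            bonferroni(1.5, 10)
        with pytest.raises(ValueError):
            bonferroni(0.5, 0)


class TestWilcoxonRegion:
    def _region_meta(self, n_ad, n_ct):
        rows = []
        for i in range(n_ad):
            rows.append(dict(sample_id=f"A{i}_HIP", subject_id=f"A{i}",
                             region="HIP", diagnosis="AD", age=80, sex="M",
                             apoe4=0, braak=4))
        for i in range(n_ct):
            rows.append(dict(sample_id=f"C{i}_HIP", subject_id=f"C{i}",
                             region="HIP", diagnosis="control", age=80,
                             sex="M", apoe4=0, braak=2))
        return pd.DataFrame(rows)

    def test_exact_small_sample_p(self):
        """{1,2,3} vs {4,5,6}: 2/C(6,3) = 0.1 by enumeration of assignments."""
        meta = self._region_meta(3, 3)
        E = pd.DataFrame([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]], index=["g"],
                         columns=meta["sample_id"])
        p = wilcoxon_region(E, meta, "HIP")
        assert p.iloc[0] == pytest.approx(0.1, abs=1e-12)

    def test_identical_values_give_p_one(self):
        meta = self._region_meta(3, 3)
        E = pd.DataFrame([[2.0] * 6], index=["g"], columns=meta["sample_id"])
        assert wilcoxon_region(E, meta, "HIP").iloc[0] == 1.0

    def test_monotone_transform_invariance(self):
        meta = self._region_meta(5, 6)
        rng = np.random.default_rng(11)
        y = rng.normal(size=(4, 11))
        E = pd.DataFrame(y, index=[f"g{i}" for i in range(4)],
                         columns=meta["sample_id"])
        E2 = np.exp(E)  # strictly monotone
        p1 = wilcoxon_region(E, meta, "HIP")
        p2 = wilcoxon_region(E2, meta, "HIP")
        assert np.allclose(p1, p2, atol=1e-12)

    def test_missing_region_rejected(self):
        meta = self._region_meta(3, 3)
        E = pd.DataFrame([[1.0] * 6], index=["g"], columns=meta["sample_id"])
        with pytest.raises(ValueError, match="absent"):
            wilcoxon_region(E, meta, "FWM")


class TestMixedDEEstimator:
    def test_result_table_contracts(self, cohort_meta):
        Y = model_scale_cohort(cohort_meta, 120, tau=0.4, sigma=0.5, seed=12)
        de = MixedDE().fit(Y, cohort_meta)
        res = de.results_
        assert list(res.columns) == ["gene_id", "logFC", "AvExp", "t",
                                     "P.Value", "adj.P.Val", "B", "converged",
                                     "tau2"]
        ok = res["converged"]
        assert np.all(np.sign(res.loc[ok, "t"]) == np.sign(res.loc[ok, "logFC"]))
        assert np.all(res.loc[ok, "adj.P.Val"] >= res.loc[ok, "P.Value"] - 1e-15)
        assert np.allclose(res["adj.P.Val"].dropna(),
                           np.minimum(1.0, len(res) * res["P.Value"].dropna()))

    def test_power_on_planted_effects(self):
        """Strong planted effects (δ = 1) are mostly recovered by the full
        chain at Bonferroni 0.05, with no false positives."""
        from hierde.preprocess import run_preprocess
        from hierde.synthetic import (CohortDesign, SimulationParams,
                                      generate_metadata, simulate_expression)
        from hierde.voom import VoomWeights
        recalls, false_pos = [], 0
        for rep in range(3):
            meta = generate_metadata(CohortDesign(seed=600 + rep))
            params = SimulationParams(n_genes=2000, de_fraction=0.025,
                                      effect_size=1.0, up_fraction=1.0)
            matrix, truth = simulate_expression(meta, params, seed=700 + rep)
            E_adj = run_preprocess(matrix, meta)
            W = VoomWeights().fit_transform(E_adj, meta)
            res = MixedDE().fit(E_adj, meta, weights=W).results_
            planted = set(np.asarray(truth.gene_ids)[truth.de_flags])
            sig = set(res.loc[res["adj.P.Val"] < 0.05, "gene_id"])
            recalls.append(len(sig & planted) / len(planted))
            false_pos += len(sig - planted)
        assert np.mean(recalls) >= 0.5
        assert false_pos <= 1

    def test_ols_anticonservative_on_clustered_null(self, cohort_meta):
        """Ignoring subjects inflates type-I error relative to the LMM."""
        Y = model_scale_cohort(cohort_meta, 800, tau=0.5, sigma=0.5, seed=13)
        de = MixedDE().fit(Y, cohort_meta)
        lmm_rate = (de.results_["P.Value"].dropna() < 0.05).mean()
        ols_rate = (ols_pvalues(Y, cohort_meta) < 0.05).mean()
        assert ols_rate > lmm_rate
        assert ols_rate > 0.065
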