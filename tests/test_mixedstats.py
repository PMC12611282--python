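"""Mixed-model estimation, Satterthwaite inference, FDR, clusters, RT fits."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from specdyn.mixedstats import (
    by_fdr,
    cluster_filter,
    condition_design,
    exgauss_fit,
    exgauss_mu,
    fit_lmm,
    marginal_r2,
    mass_univariate_r2,
    satterthwaite_p,
)


def brute_force_by(p, q=0.05):
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    ok = p[order] <= np.arange(1, m + 1) * q / (m * c_m)
    k = int(np.max(np.nonzero(ok)[0]) + 1) if ok.any() else 0
    mask = np.zeros(m, dtype=bool)
    mask[order[:k]] = True
    return mask


class TestFitLmm:
    def test_zero_between_subject_variance_matches_ols(self):
        rng = np.random.default_rng(0)
        subj = np.repeat(np.arange(60), 4)
        x = rng.normal(size=240)
        y = 0.5 * x + rng.normal(size=240)
        X = np.column_stack([np.ones(240), x])
        fit = fit_lmm(y, X, {"subject": subj}, ["Intercept", "x"])
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(fit.beta, ols, atol=1e-6)

    def test_variance_components_recovered(self):
        ests = []
        for s in range(15):
            rng = np.random.default_rng(s)
            subj = np.repeat(np.arange(100), 10)
            y = rng.normal(0, 1, 100)[subj] + rng.normal(0, 1, 1000)
            f = fit_lmm(y, np.ones((1000, 1)), {"subject": subj})
            ests.append([f.var_components["subject"], f.sigma2_resid])
        med = np.median(ests, axis=0)
        assert abs(med[0] - 1.0) < 0.15
        assert abs(med[1] - 1.0) < 0.15

    def test_fixed_effect_coverage(self):
        hits = 0
        n_sim = 60
        for s in range(n_sim):
            rng = np.random.default_rng(1000 + s)
            subj = np.repeat(np.arange(40), 4)
            x = np.tile([0.0, 0.0, 1.0, 1.0], 40)
            y = (0.5 * x + rng.normal(0, 0.7, 40)[subj]
                 + rng.normal(0, 1, 160))
            fit = fit_lmm(y, np.column_stack([np.ones(160), x]),
                          {"subject": subj}, ["Intercept", "x"])
            df, _ = satterthwaite_p(fit, "x")
            from scipy import stats

            half = stats.t.ppf(0.975, df) * fit.se[1]
            if abs(fit.beta[1] - 0.5) <= half:
                hits += 1
        assert hits / n_sim >= 0.90

    def test_matches_statsmodels_mixedlm_oracle(self):
        import pandas as pd
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(5)
        subj = np.repeat(np.arange(20), 8)
        cond = np.tile(np.arange(8), 20)
        x = rng.normal(size=160)
        y = (0.4 * x + rng.normal(0, 1, 20)[subj]
             + rng.normal(0, 0.5, 8)[cond] + rng.normal(0, 1, 160))
        ours = fit_lmm(y, np.column_stack([np.ones(160), x]),
                       {"subject": subj, "condition": cond},
                       ["Intercept", "x"])
        df = pd.DataFrame({"y": y, "x": x, "s": subj, "c": cond, "g": 1})
        theirs = smf.mixedlm(
            "y ~ x", df, groups="g",
            vc_formula={"s": "0+C(s)", "c": "0+C(c)"}, re_formula="0",
        ).fit(reml=False, method="lbfgs")
        assert ours.beta[1] == pytest.approx(theirs.params["x"], abs=1e-3)
        assert ours.loglik == pytest.approx(theirs.llf, abs=1e-3)

    def test_singular_design_lists_aliased_columns(self):
        X = np.column_stack([np.ones(20), np.arange(20), 2 * np.arange(20)])
        with pytest.raises(ValueError, match="aliased"):
            fit_lmm(np.zeros(20), X, {"g": np.repeat([0, 1], 10)},
                    ["Intercept", "a", "b"])

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_lmm(np.zeros(10), np.ones((10, 1)), {"g": np.zeros(10)})


class TestMarginalR2:
    def test_null_response_gives_zero(self):
        # y identically zero: no variance anywhere, value defined as 0
        rng = np.random.default_rng(0)
        subj = np.repeat(np.arange(30), 4)
        x = rng.normal(size=120)
        fit = fit_lmm(np.zeros(120), np.column_stack([np.ones(120), x]),
                      {"subject": subj}, ["Intercept", "x"])
        assert marginal_r2(fit, "x") == 0.0

    def test_perfect_fixed_effect_limit(self):
        rng = np.random.default_rng(1)
        subj = np.repeat(np.arange(30), 4)
        x = rng.normal(size=120)
        fit = fit_lmm(x, np.column_stack([np.ones(120), x]),
                      {"subject": subj}, ["Intercept", "x"])
        assert marginal_r2(fit, "x") >= 0.999

    def test_magnitude_matches_plug_in_truth(self):
        errs = []
        for s in range(25):
            rng = np.random.default_rng(300 + s)
            subj = np.repeat(np.arange(60), 8)
            x = rng.normal(0, 1, 480)
            y = x + rng.normal(0, 1, 60)[subj] + rng.normal(0, np.sqrt(2), 480)
            fit = fit_lmm(y, np.column_stack([np.ones(480), x]),
                          {"subject": subj}, ["Intercept", "x"])
            errs.append(abs(abs(marginal_r2(fit, "x")) - 0.25))
        assert np.median(errs) < 0.05

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(2)
        subj = np.repeat(np.arange(30), 4)
        x = rng.normal(size=120)
        y = 0.5 * x + rng.normal(0, 1, 30)[subj] + rng.normal(size=120)
        X = np.column_stack([np.ones(120), x])
        r1 = marginal_r2(fit_lmm(y, X, {"s": subj}, ["Intercept", "x"]), "x")
        r2 = marginal_r2(fit_lmm(5 * y + 3, X, {"s": subj},
                                 ["Intercept", "x"]), "x")
        assert abs(abs(r1) - abs(r2)) < 1e-4


class TestSatterthwaite:
    def test_agrees_with_t_test_when_no_random_variance(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        subj = np.repeat(np.arange(80), 3)
        x = rng.normal(size=240)
        y = 0.4 * x + rng.normal(size=240)
        X = np.column_stack([np.ones(240), x])
        fit = fit_lmm(y, X, {"subject": subj}, ["Intercept", "x"])
        _, p = satterthwaite_p(fit, "x")
        assert p == pytest.approx(sm.OLS(y, X).fit().pvalues[1], abs=1e-3)

    def test_p_monotone_in_t(self):
        from scipy import stats

        ts = np.linspace(0.1, 5.0, 20)
        ps = 2 * stats.t.sf(ts, 17.3)
        assert np.all(np.diff(ps) < 0)

    def test_between_subject_df_matches_classical(self):
        rng = np.random.default_rng(4)
        n_sub = 200
        subj = np.repeat(np.arange(n_sub), 2)
        g = rng.normal(size=n_sub)[subj]
        y = 0.3 * g + rng.normal(0, 1, n_sub)[subj] + rng.normal(0, 0.5,
                                                                 2 * n_sub)
        fit = fit_lmm(y, np.column_stack([np.ones(2 * n_sub), g]),
                      {"subject": subj}, ["Intercept", "g"])
        df, _ = satterthwaite_p(fit, "g")
        classical = n_sub - 2
        assert abs(df - classical) / classical < 0.05


class TestByFdr:
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=60))
    def test_matches_brute_force_step_up(self, p):
        p = np.asarray(p)
        np.testing.assert_array_equal(by_fdr(p, 0.05), brute_force_by(p, 0.05))

    def test_all_ones_rejects_nothing(self):
        assert not by_fdr(np.ones(10)).any()

    def test_single_p_at_q_rejected(self):
        assert by_fdr(np.array([0.05]), q=0.05)[0]

    def test_documented_example(self):
        p = np.array([0.001, 0.01, 0.02, 0.5])
        np.testing.assert_array_equal(by_fdr(p, 0.05),
                                      brute_force_by(p, 0.05))

    def test_nan_entries_excluded(self):
        p = np.array([0.001, np.nan, 0.9])
        mask = by_fdr(p, 0.05)
        assert not mask[1]


class TestClusterFilter:
    def test_isolated_point_removed(self):
        m = np.zeros((4, 10), dtype=bool)
        m[1, 5] = True
        assert not cluster_filter(m).any()

    def test_run_of_three_retained(self):
        m = np.zeros((4, 10), dtype=bool)
        m[2, 3:6] = True
        out = cluster_filter(m)
        assert out[2, 3:6].all() and out.sum() == 3

    def test_three_simultaneous_channels_retained(self):
        m = np.zeros((4, 10), dtype=bool)
        m[0:3, 7] = True
        out = cluster_filter(m)
        assert out[0:3, 7].all() and out.sum() == 3

    def test_output_subset_of_input(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            m = rng.uniform(size=(6, 15)) < 0.3
            out = cluster_filter(m)
            assert not np.any(out & ~m)

    def test_3d_mask_filtered_per_frequency(self):
        m = np.zeros((4, 2, 10), dtype=bool)
        m[1, 0, 2:5] = True  # run at frequency 0
        m[1, 1, 2] = True  # isolated at frequency 1
        out = cluster_filter(m)
        assert out[1, 0, 2:5].all()
        assert not out[1, 1].any()


class TestMassUnivariateR2:
    def test_identity_maps_give_unit_r2(self):
        rng = np.random.default_rng(0)
        maps = rng.normal(size=(8, 4, 3))
        out = mass_univariate_r2(maps, maps)
        assert np.all(out.r2_signed[np.isfinite(out.r2_signed)] >= 0.999)

    def test_sign_flips_with_negated_predictor(self):
        rng = np.random.default_rng(1)
        pred = rng.normal(size=(10, 4, 2))
        dep = 0.8 * pred + 0.3 * rng.normal(size=pred.shape)
        a = mass_univariate_r2(dep, pred)
        b = mass_univariate_r2(dep, -pred)
        np.testing.assert_allclose(a.r2_signed, -b.r2_signed, atol=1e-6)

    def test_constant_predictor_flagged_missing(self):
        rng = np.random.default_rng(2)
        dep = rng.normal(size=(6, 4, 2))
        pred = np.zeros_like(dep)
        out = mass_univariate_r2(dep, pred)
        assert np.all(np.isnan(out.r2_signed))


class TestConditionDesign:
    def test_sum_coding_and_interactions(self):
        labels = [("visual", "0back", "nontarget"), ("visual", "0back", "target"),
                  ("visual", "2back", "nontarget"), ("visual", "2back", "target"),
                  ("verbal", "0back", "nontarget"), ("verbal", "0back", "target"),
                  ("verbal", "2back", "nontarget"), ("verbal", "2back", "target")]
        design = condition_design(labels)
        assert set(design.columns) == {
            "Intercept", "modality", "nback", "stimulus",
            "modality:nback", "modality:stimulus", "nback:stimulus",
            "modality:nback:stimulus"}
        for col in design.columns:
            if col != "Intercept":
                assert set(design[col]) == {-1.0, 1.0}
                assert design[col].sum() == 0

    def test_degenerate_factor_dropped(self):
        labels = [("verbal", "0back", "nontarget"), ("verbal", "0back", "target")]
        design = condition_design(labels)
        assert list(design.columns) == ["Intercept", "stimulus"]


class TestExGauss:
    def test_mu_recovery(self):
        errs = []
        for s in range(30):
            rng = np.random.default_rng(s)
            rts = rng.normal(0.5, 0.05, 1000) + rng.exponential(0.15, 1000)
            mu, _, _ = exgauss_fit(rts)
            errs.append(abs(mu - 0.5))
        assert np.median(errs) < 0.03

    def test_fast_rt_filter_applied(self):
        rng = np.random.default_rng(0)
        rts = rng.normal(0.5, 0.05, 200) + rng.exponential(0.1, 200)
        with_outlier = np.append(rts, 0.1)
        mu_a = exgauss_mu(rts)[0]
        mu_b = exgauss_mu(with_outlier)[0]
        assert mu_a == pytest.approx(mu_b, abs=1e-6)

    def test_near_gaussian_mu_close_to_sample_mean(self):
        rng = np.random.default_rng(1)
        rts = rng.normal(0.5, 0.05, 1000) + rng.exponential(1e-4, 1000)
        mu, _, _ = exgauss_fit(rts)
        assert abs(mu - rts.mean()) < 0.02

    def test_too_few_rts_flagged_missing(self):
        assert np.isnan(exgauss_mu(np.full(5, 0.5))[0])
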