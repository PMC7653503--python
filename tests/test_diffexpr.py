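import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lncq import diffexpr
from lncq.diffexpr import (
    ComparisonSpec,
    ModerationPrior,
    bh_adjust,
    covariate_correlation,
    estimate_moderation_prior,
    fit_feature_models,
    moderated_t,
    pca,
    run_comparison,
    screen_sex_dimorphic,
)


def comp(**kw):
    base = dict(name="c", group_a="a", group_b="b")
    base.update(kw)
    return ComparisonSpec(**base)


class TestFeatureModels:
    def test_noise_free_planted_difference_exact(self, two_group_expr):
        expr, meta = two_group_expr(noise=0.0, effect=1.0)
        fit = fit_feature_models(expr, meta, comp())
        assert fit.loc["F1", "coef"] == pytest.approx(1.0)
        assert fit.loc["F1", "s2"] == pytest.approx(0.0, abs=1e-24)

    def test_sign_convention_antisymmetric(self, two_group_expr):
        expr, meta = two_group_expr(seed=4)
        ab = fit_feature_models(expr, meta, comp())
        ba = fit_feature_models(expr, meta, comp(group_a="b", group_b="a"))
        np.testing.assert_allclose(ab["coef"], -ba["coef"])

    def test_permuted_labels_null_coefficient(self, two_group_expr):
        expr, meta = two_group_expr(n_per_group=100, effect=1.0, noise=0.5, seed=8)
        rng = np.random.default_rng(9)
        meta = meta.copy()
        meta["group"] = rng.permutation(meta["group"].to_numpy())
        fit = fit_feature_models(expr, meta, comp())
        se = np.sqrt(fit["s2"] * fit["v_unscaled"])
        assert (fit["coef"].abs() < 3.5 * se).all()

    def test_sex_adjusted_contrast_matches_normal_equations(self, two_group_expr):
        """Sex covariate: coefficient equals the direct normal-equations
        solve of the two-way model (independent oracle)."""
        expr, meta = two_group_expr(seed=5)
        # confound: add a sex effect on F1
        expr = expr.copy()
        expr.loc["F1", meta["sex"] == "male"] += 2.0
        fit = fit_feature_models(expr, meta, comp(covariates=["sex"]))
        X = np.column_stack(
            [
                np.ones(len(meta)),
                (meta["group"] == "a").to_numpy(float),
                (meta["sex"] == "male").to_numpy(float),
            ]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ expr.loc["F1"].to_numpy())
        assert fit.loc["F1", "coef"] == pytest.approx(beta[1], rel=1e-10)

    def test_rank_deficient_design_names_columns(self, two_group_expr):
        expr, meta = two_group_expr()
        meta = meta.copy()
        meta["dup"] = (meta["group"] == "a").astype(float)  # duplicates indicator
        with pytest.raises(ValueError, match="dup"):
            fit_feature_models(expr, meta, comp(covariates=["dup"]))

    def test_overlapping_selectors_rejected(self, two_group_expr):
        expr, meta = two_group_expr()
        with pytest.raises(ValueError, match="overlap"):
            fit_feature_models(expr, meta, comp(group_b={"group": ["a", "b"]}))

    def test_missingness_filter_drops_feature(self, two_group_expr):
        expr, meta = two_group_expr(n_per_group=10)
        expr = expr.copy()
        expr.loc["F2", meta.index[meta["group"] == "a"][:8]] = np.nan
        fit = fit_feature_models(expr, meta, comp(), missing_max=0.5)
        assert "F2" not in fit.index and "F1" in fit.index


class TestModeration:
    def test_degenerate_equal_variances_give_infinite_d0(self):
        """Zero spread in log s^2 cannot exceed the sampling component, so
        d0 is reported infinite; s0^2 carries the log-scale moment factor
        exp(log(d/2) - digamma(d/2)) of the scaled-chi-square model."""
        from scipy.special import digamma

        prior = estimate_moderation_prior([1.0] * 50, [4] * 50)
        assert math.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(math.exp(math.log(2.0) - digamma(2.0)))

    def test_genuine_common_variance_draws_recover_s0(self):
        """s^2 actually drawn from s0^2 chi2_d / d with s0^2 = 1 recovers a
        prior variance near 1 with very large or infinite d0."""
        rng = np.random.default_rng(8)
        s2 = rng.chisquare(4, size=5000) / 4.0
        prior = estimate_moderation_prior(s2, np.full(5000, 4.0))
        assert prior.s0_sq == pytest.approx(1.0, rel=0.1)
        assert prior.d0 > 50

    def test_all_zero_variances_warn_d0_zero(self, caplog):
        prior = estimate_moderation_prior([0.0, 0.0], [4, 4])
        assert prior.d0 == 0.0

    def test_d0_zero_recovers_ordinary_t(self, two_group_expr):
        expr, meta = two_group_expr(seed=2)
        fit = fit_feature_models(expr, meta, comp())
        mod = moderated_t(fit, ModerationPrior(d0=0.0, s0_sq=1.0))
        ordinary = fit["coef"] / np.sqrt(fit["s2"] * fit["v_unscaled"])
        np.testing.assert_allclose(mod["t"], ordinary)

    def test_posterior_variance_formula(self):
        fit = pd.DataFrame({"coef": [1.0], "s2": [2.0], "df": [4.0], "v_unscaled": [0.5]})
        mod = moderated_t(fit, ModerationPrior(d0=4.0, s0_sq=1.0))
        assert mod["s2_post"].iloc[0] == pytest.approx(1.5)

    def test_infinite_d0_pins_posterior_at_prior(self):
        fit = pd.DataFrame(
            {"coef": [1.0, 2.0], "s2": [5.0, 0.1], "df": [4.0, 4.0],
             "v_unscaled": [0.5, 0.5]}
        )
        mod = moderated_t(fit, ModerationPrior(d0=math.inf, s0_sq=1.0))
        assert (mod["s2_post"] == 1.0).all()

    @settings(derandomize=True, max_examples=50)
    @given(
        s2=st.floats(1e-6, 1e3),
        s0=st.floats(1e-6, 1e3),
        d0=st.floats(0.1, 100),
        d=st.floats(1, 50),
    )
    def test_posterior_variance_between_sample_and_prior(self, s2, s0, d0, d):
        fit = pd.DataFrame({"coef": [1.0], "s2": [s2], "df": [d], "v_unscaled": [1.0]})
        post = moderated_t(fit, ModerationPrior(d0=d0, s0_sq=s0))["s2_post"].iloc[0]
        assert min(s2, s0) - 1e-12 <= post <= max(s2, s0) + 1e-12

    def test_prior_recovery_from_scaled_f_draws(self):
        """2000 features drawn with true d0=4, s0^2=1, d=4 recover the prior
        within the stated brackets."""
        from scipy import stats as sps

        rng = np.random.default_rng(42)
        s2 = sps.f.rvs(4, 4, size=2000, random_state=rng)
        prior = estimate_moderation_prior(s2, np.full(2000, 4.0))
        assert 2.0 <= prior.d0 <= 8.0
        assert 0.8 <= prior.s0_sq <= 1.25


class TestBH:
    def test_step_up_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_all_ones_and_singleton(self):
        assert (bh_adjust([1.0, 1.0, 1.0]) == 1.0).all()
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_domain_check(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=30))
    def test_adjustment_monotone_and_idempotent_upward(self, p):
        adj = bh_adjust(p)
        assert (adj >= np.asarray(p) - 1e-15).all()
        assert (bh_adjust(adj) >= adj - 1e-15).all()


class TestScreens:
    def test_planted_sex_effect_flagged_exactly(self, two_group_expr):
        expr, meta = two_group_expr(n_per_group=12, effect=0.0, noise=0.2, seed=3)
        expr = expr.copy()
        expr.loc["F4", meta["sex"] == "male"] += 3.0
        flagged = screen_sex_dimorphic(expr, meta, alpha=0.05)
        assert flagged == ["F4"]

    def test_null_sex_screen_type_i_control(self, two_group_expr):
        n_flags, n_features = [], 8
        for run in range(200):
            expr, meta = two_group_expr(
                n_per_group=12, effect=0.0, noise=0.5, seed=100 + run
            )
            n_flags.append(len(screen_sex_dimorphic(expr, meta, alpha=0.05)))
        assert np.mean(n_flags) <= 0.05 * n_features

    def test_single_sample_per_sex_rejected(self, two_group_expr):
        expr, meta = two_group_expr(n_per_group=3)
        meta = meta.copy()
        meta["sex"] = ["male"] + ["female"] * 5
        with pytest.raises(ValueError, match="sex"):
            screen_sex_dimorphic(expr, meta)


class TestCovariateCorrelation:
    def test_exact_copy_gives_rho_one(self, two_group_expr):
        expr, meta = two_group_expr(n_per_group=10, seed=6)
        meta = meta.copy()
        meta["eosinophil"] = expr.loc["F2"].to_numpy()
        out = covariate_correlation(expr, meta, "eosinophil")
        assert out.loc["F2", "rho"] == pytest.approx(1.0)
        meta["eosinophil"] = -expr.loc["F2"].to_numpy()
        out = covariate_correlation(expr, meta, "eosinophil")
        assert out.loc["F2", "rho"] == pytest.approx(-1.0)

    def test_independent_covariate_near_zero(self, two_group_expr):
        rhos = []
        for run in range(50):
            expr, meta = two_group_expr(n_per_group=30, effect=0.0, seed=run)
            meta = meta.copy()
            meta["cov"] = np.random.default_rng(10_000 + run).normal(size=len(meta))
            rhos.append(covariate_correlation(expr, meta, "cov")["rho"].mean())
        assert abs(np.mean(rhos)) < 0.03

    def test_constant_covariate_rejected(self, two_group_expr):
        expr, meta = two_group_expr()
        meta = meta.copy()
        meta["cov"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            covariate_correlation(expr, meta, "cov")


class TestPCA:
    def test_rank_one_data_single_component(self):
        t = np.linspace(0, 1, 10)
        X = pd.DataFrame([2 * t, -t, 3 * t], index=["F1", "F2", "F3"],
                         columns=[f"S{i}" for i in range(10)])
        res = pca(X)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_reconstruction_identity(self, two_group_expr):
        expr, _ = two_group_expr(seed=11)
        res = pca(expr)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        centered = expr.T.to_numpy() - expr.T.to_numpy().mean(axis=0)
        np.testing.assert_allclose(recon, centered, atol=1e-10)

    def test_planted_variance_ratio(self):
        rng = np.random.default_rng(0)
        n = 4000
        a = rng.normal(0, 2, n)
        b = rng.normal(0, 1, n)
        X = pd.DataFrame([a, b], index=["F1", "F2"],
                         columns=[f"S{i}" for i in range(n)])
        res = pca(X)
        ratio = res.explained_variance[0] / res.explained_variance[1]
        assert ratio == pytest.approx(4.0, rel=0.15)

    def test_missing_values_rejected(self, two_group_expr):
        expr, _ = two_group_expr()
        expr = expr.copy()
        expr.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            pca(expr)

    def test_loadings_orthonormal_and_variance_nonincreasing(self, two_group_expr):
        expr, _ = two_group_expr(seed=13)
        res = pca(expr)
        L = res.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-10)
        assert (np.diff(res.explained_variance) <= 1e-12).all()


class TestRunComparison:
    def test_de_table_contract(self, two_group_expr):
        expr, meta = two_group_expr(effect=2.0, noise=0.3, seed=1)
        table = run_comparison(expr, meta, comp(significance="adjusted_p"), with_b=True)
        assert {"comparison", "log2fc", "t", "df_total", "p", "p_adj",
                "significant", "B"} <= set(table.columns)
        assert (table["p_adj"] >= table["p"] - 1e-15).all()
        assert bool(table.loc["F1", "significant"])
        assert table["significant"].equals(table["p_adj"] < 0.05)
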