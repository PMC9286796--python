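"""Tests for the mixed-model regressions, VIF, R-squared measures and the
exhaustive AIC search."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from spreadwait.regression import (
    ModelSpec,
    RegressionFit,
    all_subsets_aic,
    fit_lmm,
    r2_marginal_drivers,
    r2_nakagawa,
    vif,
)


def make_data(
    rng,
    n=600,
    n_groups=12,
    betas=(1.0, 0.0, 0.5),
    sigma_alpha=1.0,
    sigma_eps=1.0,
    names=("a", "b", "c"),
):
    g = rng.integers(0, n_groups, n)
    x = rng.standard_normal((n, len(betas)))
    alpha = rng.normal(0, sigma_alpha, n_groups)
    y = 8 + x @ np.array(betas) + alpha[g] + rng.normal(0, sigma_eps, n)
    df = pd.DataFrame(x, columns=list(names))
    df["waiting_time"] = y
    df["level4"] = [f"g{i}" for i in g]
    df["detection_year"] = rng.standard_normal(n)
    df["neighbor_wait"] = rng.standard_normal(n)
    return df


SPEC_ABC = ModelSpec(drivers=("a", "b", "c"), forced=(), group="level4")


class TestFitLmm:
    def test_zero_group_variance_matches_ols(self, rng):
        # sigma2_alpha = 0 -> the mixed fit collapses to OLS
        df = make_data(rng, n=800, sigma_alpha=0.0)
        fit = fit_lmm(df, SPEC_ABC, standardize=False)
        X = sm.add_constant(df[["a", "b", "c"]])
        ols = sm.OLS(df["waiting_time"], X).fit()
        assert fit.sigma2_alpha < 1e-4
        assert np.allclose(fit.params.to_numpy(), ols.params.to_numpy(), atol=1e-4)

    def test_matches_lme4_ml_fit(self, rng, tmp_path):
        # independent oracle: lme4's ML fit of the same model via Rscript
        df = make_data(rng, n=300, n_groups=8)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            textwrap.dedent(
                f"""
                suppressMessages(library(lme4))
                d <- read.csv("{csv}")
                m <- lmer(waiting_time ~ a + b + c + (1 | level4), data = d, REML = FALSE)
                cat(fixef(m), sqrt(diag(vcov(m))), as.numeric(logLik(m)), sep = "\\n")
                """
            )
        )
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)],
            capture_output=True,
            text=True,
            check=True,
        )
        vals = [float(v) for v in out.stdout.strip().splitlines()]
        fe_r, se_r, llf_r = vals[:4], vals[4:8], vals[8]
        fit = fit_lmm(df, SPEC_ABC, standardize=False)
        assert np.allclose(fit.params.to_numpy(), fe_r, atol=1e-4)
        assert np.allclose(fit.bse.to_numpy(), se_r, rtol=1e-3)
        assert fit.loglik == pytest.approx(llf_r, abs=1e-3)

    def test_coefficient_recovery_within_reported_se(self):
        hits = 0
        reps = 30
        for i in range(reps):
            rng = np.random.default_rng(100 + i)
            df = make_data(rng, n=1000, n_groups=20, betas=(1.0, -0.7, 0.5))
            fit = fit_lmm(df, SPEC_ABC, standardize=False)
            ok = all(
                abs(fit.params[t] - b) < 2 * fit.bse[t]
                for t, b in zip(("a", "b", "c"), (1.0, -0.7, 0.5))
            )
            hits += ok
        # each coefficient within 2 SE ~95% of the time; jointly ~86%
        assert hits >= 0.7 * reps

    def test_added_noise_predictor_never_lowers_loglik(self, rng):
        df = make_data(rng)
        small = fit_lmm(df, ModelSpec(drivers=("a",), forced=(), group="level4"))
        big = fit_lmm(df, ModelSpec(drivers=("a", "b"), forced=(), group="level4"))
        assert big.loglik >= small.loglik - 1e-6

    def test_singular_design_reported(self, rng):
        df = make_data(rng)
        df["a_copy"] = df["a"]
        with pytest.raises(ValueError, match="collinear"):
            fit_lmm(
                df,
                ModelSpec(drivers=("a", "a_copy"), forced=(), group="level4"),
            )

    def test_single_group_rejected(self, rng):
        df = make_data(rng)
        df["level4"] = "only"
        with pytest.raises(ValueError, match=">= 2 levels"):
            fit_lmm(df, SPEC_ABC)


class TestVif:
    def test_orthogonal_predictors_give_unit_vif(self):
        x = pd.DataFrame(
            {"u": [1, 1, -1, -1] * 5, "v": [1, -1, 1, -1] * 5}, dtype=float
        )
        out = vif(x)
        assert np.allclose(out, 1.0)

    def test_known_correlation_closed_form(self, rng):
        # corr 0.9 -> VIF = 1/(1-0.81) ~ 5.263
        n = 200_000
        a = rng.standard_normal(n)
        b = 0.9 * a + np.sqrt(1 - 0.81) * rng.standard_normal(n)
        out = vif(pd.DataFrame({"a": a, "b": b}))
        assert out["a"] == pytest.approx(1 / (1 - 0.81), rel=0.02)

    def test_matches_regression_oracle(self, rng):
        x = pd.DataFrame(
            rng.standard_normal((300, 4)) @ rng.standard_normal((4, 4)),
            columns=list("wxyz"),
        )
        out = vif(x)
        for col in x.columns:
            others = np.column_stack(
                [np.ones(len(x))] + [x[c] for c in x.columns if c != col]
            )
            beta, *_ = np.linalg.lstsq(others, x[col], rcond=None)
            resid = x[col] - others @ beta
            r2 = 1 - resid @ resid / np.sum((x[col] - x[col].mean()) ** 2)
            assert out[col] == pytest.approx(1 / (1 - r2), abs=1e-8)

    def test_perfect_collinearity_reports_inf(self, rng):
        a = rng.standard_normal(50)
        out = vif(pd.DataFrame({"a": a, "b": 2 * a}))
        assert np.isinf(out).all()


def _manual_fit(s2f, s2a, s2e):
    return RegressionFit(
        spec=ModelSpec(drivers=("d",), forced=()),
        params=pd.Series(dtype=float),
        bse=pd.Series(dtype=float),
        sigma2_alpha=s2a,
        sigma2_eps=s2e,
        sigma2_f=s2f,
        loglik=0.0,
        aic=0.0,
        n=0,
        n_groups=0,
        design=pd.DataFrame(),
        linpred_driver_var=0.0,
    )


class TestR2:
    def test_arithmetic_identity(self):
        r2m, r2c = r2_nakagawa(_manual_fit(2.0, 1.0, 1.0))
        assert (r2m, r2c) == (0.5, 0.75)

    def test_marginal_equals_conditional_without_group_variance(self):
        r2m, r2c = r2_nakagawa(_manual_fit(2.0, 0.0, 1.0))
        assert r2m == r2c

    def test_all_zero_components_signalled(self):
        with pytest.raises(ValueError, match="undefined"):
            r2_nakagawa(_manual_fit(0.0, 0.0, 0.0))

    def test_ordering_and_bounds_on_fitted_model(self, rng):
        df = make_data(rng, n=800)
        fit = fit_lmm(df, SPEC_ABC)
        r2m, r2c = r2_nakagawa(fit)
        assert 0 <= r2m <= r2c <= 1

    def test_driver_share_zero_without_drivers(self, rng):
        df = make_data(rng)
        fit = fit_lmm(df, ModelSpec(drivers=(), group="level4"))
        assert r2_marginal_drivers(fit) == 0.0

    def test_driver_share_equals_marginal_when_background_is_noise(self):
        # background coefficients ~0 -> driver-only R2 ~ marginal R2
        rng = np.random.default_rng(21)
        df = make_data(rng, n=4000, betas=(2.0, 1.0, 0.0), sigma_alpha=0.5)
        fit = fit_lmm(df, ModelSpec(drivers=("a", "b", "c"), group="level4"))
        r2m, _ = r2_nakagawa(fit)
        assert r2_marginal_drivers(fit) == pytest.approx(r2m, abs=0.02)

    def test_recovers_analytic_variance_share(self):
        # independent predictors: R2m ~ sum(beta^2) / (sum(beta^2)+s2a+s2e)
        rng = np.random.default_rng(22)
        betas, s2a, s2e = (1.0, -0.8, 0.6), 1.0, 1.0
        df = make_data(
            rng, n=2000, n_groups=25, betas=betas,
            sigma_alpha=np.sqrt(s2a), sigma_eps=np.sqrt(s2e),
        )
        fit = fit_lmm(df, SPEC_ABC, standardize=False)
        want = sum(b * b for b in betas) / (sum(b * b for b in betas) + s2a + s2e)
        r2m, _ = r2_nakagawa(fit)
        assert r2m == pytest.approx(want, abs=0.05)
        assert r2_marginal_drivers(fit) == pytest.approx(want, abs=0.05)


class TestAllSubsets:
    def test_two_candidates_enumerate_four_models(self, rng):
        df = make_data(rng)
        _, ranked = all_subsets_aic(
            df, ("a", "b"), ModelSpec(forced=(), group="level4")
        )
        assert len(ranked) == 4
        assert set(ranked["mask"]) == {0, 1, 2, 3}

    def test_matches_brute_force_aic_table(self, rng):
        df = make_data(rng, n=400)
        base = ModelSpec(forced=("detection_year",), group="level4")
        _, ranked = all_subsets_aic(df, ("a", "b"), base)
        for row in ranked.itertuples():
            drivers = tuple(
                c for i, c in enumerate(("a", "b")) if row.mask & (1 << i)
            )
            fit = fit_lmm(
                df, ModelSpec(drivers=drivers, forced=("detection_year",),
                              group="level4"),
            )
            assert row.aic == pytest.approx(fit.aic, abs=1e-8)

    def test_forced_terms_present_in_every_candidate(self, rng):
        df = make_data(rng)
        best, _ = all_subsets_aic(df, ("a",), ModelSpec(group="level4"))
        assert {"detection_year", "neighbor_wait"} <= set(best.params.index)

    def test_aic_ordering_invariant_to_standardization(self, rng):
        df = make_data(rng, n=500)
        base = ModelSpec(forced=(), group="level4")
        _, ranked_std = all_subsets_aic(df, ("a", "b"), base, standardize=True)
        _, ranked_raw = all_subsets_aic(df, ("a", "b"), base, standardize=False)
        assert ranked_std["mask"].tolist() == ranked_raw["mask"].tolist()

    def test_true_driver_selected(self):
        rng = np.random.default_rng(31)
        df = make_data(rng, n=2000, betas=(1.0, 0.0, 0.0))
        best, ranked = all_subsets_aic(
            df, ("a", "b", "c"), ModelSpec(forced=(), group="level4")
        )
        assert "a" in best.spec.drivers
        assert len(ranked) == 8

    def test_too_many_candidates_rejected(self, rng):
        df = make_data(rng)
        with pytest.raises(ValueError, match="15"):
            all_subsets_aic(df, tuple("abcdefghijklmnop"))
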