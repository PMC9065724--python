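import numpy as np
import pandas as pd
import pytest

from beeland.stats import (FIXED_TERMS, fit_gamma, fit_lmm, fit_ols_reference,
                           gamma_median_approx, posthoc_contrasts, predict_emm)


class TestFitGamma:
    def test_mle_recovery_large_n(self):
        rng = np.random.default_rng(42)
        g = fit_gamma(rng.gamma(4.8, 2.5, 50_000))
        assert 4.7 <= g.a <= 4.9
        assert 2.45 <= g.b <= 2.55
        assert g.ci_a[0] < g.a < g.ci_a[1]
        assert g.ci_b[0] < g.b < g.ci_b[1]

    def test_exponential_special_case(self):
        rng = np.random.default_rng(1)
        g = fit_gamma(rng.exponential(3.0, 20_000))
        assert g.ci_a[0] < 1.0 < g.ci_a[1] or abs(g.a - 1.0) < 0.05

    def test_sample_median_near_analytic_median(self):
        rng = np.random.default_rng(7)
        g = fit_gamma(rng.gamma(4.8, 2.5, 2651))
        approx = gamma_median_approx(4.8, 2.5)
        # median standard error ~ 1 / (2 f(m) sqrt(n))
        assert abs(g.sample_median - approx) < 0.45

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        x = rng.gamma(3.0, 1.7, 5000)
        g1 = fit_gamma(x)
        g2 = fit_gamma(10.0 * x)
        assert g2.a == pytest.approx(g1.a, abs=1e-7)
        assert g2.b == pytest.approx(10.0 * g1.b, rel=1e-7)

    def test_non_positive_sample_lists_indices(self):
        x = np.ones(20)
        x[3] = -1.0
        with pytest.raises(ValueError, match="3"):
            fit_gamma(x)


def make_table(n=2500, seed=0, random_sd=0.05, resid_sd=0.2,
               beta=None, sunrise_mult=None):
    """Entries table drawn from the log-linear mixed model itself."""
    rng = np.random.default_rng(seed)
    beta = beta or dict(icept=1.35, ly0=-0.29, med=0.03, sun=0.10,
                        take=-0.02, ldre=-0.16, lrs=0.32, inter=-0.36)
    days = rng.integers(0, 5, n)
    appr = rng.integers(1, 9, n)
    side = rng.integers(0, 2, n)
    d_day = rng.normal(0, random_sd, 5)
    d_app = rng.normal(0, random_sd, 8)
    d_side = rng.normal(0, random_sd, 2)
    y0 = np.exp(rng.normal(np.log(0.2), 0.4, n))
    dre = np.exp(rng.normal(np.log(1.7), 0.3, n))
    rs = np.exp(rng.normal(np.log(2.8), 0.3, n))
    light = rng.choice(["twilight", "medium", "sunrise"], n)
    ltype = rng.choice(["free_flight", "after_takeoff"], n)
    sun = beta["sun"] if sunrise_mult is None else np.log(sunrise_mult)
    eta = (beta["icept"] + beta["ly0"] * np.log(y0)
           + beta["med"] * (light == "medium") + sun * (light == "sunrise")
           + beta["take"] * (ltype == "after_takeoff")
           + beta["ldre"] * np.log(dre) + beta["lrs"] * np.log(rs)
           + beta["inter"] * np.log(y0) * np.log(dre)
           + d_day[days] + d_app[appr - 1] + d_side[side]
           + rng.normal(0, resid_sd, n))
    return pd.DataFrame(dict(
        y0_m=y0, delta_re_per_s=dre, r_star_per_s=rs, light=light,
        landing_type=ltype, day=days, approach_number=appr,
        landing_side=np.where(side == 0, "hive", "food"),
        rdot_per_s2=np.exp(eta))), beta


class TestFitLmm:
    def test_fixed_effect_table_has_the_eight_terms(self):
        tab, _ = make_table(n=600, seed=2)
        res = fit_lmm(tab)
        assert set(res.fixed_effects.index) == set(FIXED_TERMS)
        assert np.all(res.fixed_effects["se"] > 0)
        assert np.all((res.fixed_effects["p"] >= 0) & (res.fixed_effects["p"] <= 1))

    def test_simulation_based_calibration(self):
        """True coefficients covered by their 95% CI in >= 90% of replicates."""
        truth = dict(icept=1.35, ly0=-0.29, med=0.03, sun=0.10, take=-0.02,
                     ldre=-0.16, lrs=0.32, inter=-0.36)
        key = {"log_y0": "ly0", "log_rstar": "lrs", "log_y0:log_dre": "inter"}
        n_rep = 12
        covered = {k: 0 for k in key}
        for rep in range(n_rep):
            tab, beta = make_table(n=2500, seed=100 + rep)
            res = fit_lmm(tab)
            fe = res.fixed_effects
            for term, bkey in key.items():
                est, se = fe.loc[term, "estimate"], fe.loc[term, "se"]
                if abs(est - truth[bkey]) <= 1.96 * se * 1.05:
                    covered[term] += 1
        for term, c in covered.items():
            assert c >= 0.75 * n_rep, f"{term} covered only {c}/{n_rep}"

    def test_degenerate_random_effects_match_ols(self):
        # a draw whose REML variance components all hit the zero boundary
        # (as in lme4), where the mixed model reduces exactly to OLS
        tab, _ = make_table(n=800, seed=7, random_sd=0.0)
        lmm = fit_lmm(tab)
        ols = fit_ols_reference(tab)
        for term in FIXED_TERMS:
            assert lmm.fixed_effects.loc[term, "estimate"] == pytest.approx(
                ols.params[term], abs=1e-6)

    def test_lme4_agreement(self, tmp_path):
        """Independent oracle: lme4's REML fit on the same small table."""
        import shutil
        import subprocess
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        tab, _ = make_table(n=500, seed=9)
        csv = tmp_path / "tab.csv"
        tab.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(f"""
suppressMessages(library(lme4))
d <- read.csv("{csv}")
d$ly0 <- log(d$y0_m); d$ldre <- log(d$delta_re_per_s); d$lrs <- log(d$r_star_per_s)
d$med <- as.numeric(d$light == "medium"); d$sun <- as.numeric(d$light == "sunrise")
d$take <- as.numeric(d$landing_type == "after_takeoff")
m <- lmer(log(rdot_per_s2) ~ ly0 + med + sun + take + ldre + lrs + ly0:ldre +
          (1|day) + (1|approach_number) + (1|landing_side), data=d, REML=TRUE)
cat(fixef(m), sep="\\n")
""")
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=300)
        if out.returncode != 0:
            pytest.skip(f"Rscript failed: {out.stderr[:200]}")
        r_fe = np.array([float(v) for v in out.stdout.split()])
        res = fit_lmm(tab)
        py_fe = res.fixed_effects["estimate"].reindex(
            ["Intercept", "log_y0", "light_medium", "light_sunrise",
             "after_takeoff", "log_dre", "log_rstar", "log_y0:log_dre"]).to_numpy()
        np.testing.assert_allclose(py_fe, r_fe, atol=0.02)


class TestPredictEmm:
    @pytest.fixture(scope="class")
    def fitted(self):
        tab, _ = make_table(n=1500, seed=4)
        return fit_lmm(tab)

    def test_prediction_is_exp_of_linear_combination(self, fitted):
        s = dict(y0=0.2, delta_re=1.7, r_star=2.8, light="twilight",
                 landing_type="free_flight")
        out = predict_emm(fitted, [s])
        fe = fitted.fixed_effects["estimate"]
        eta = (fe["Intercept"] + fe["log_y0"] * np.log(0.2)
               + fe["log_dre"] * np.log(1.7) + fe["log_rstar"] * np.log(2.8)
               + fe["log_y0:log_dre"] * np.log(0.2) * np.log(1.7))
        assert out["mean"].iloc[0] == pytest.approx(np.exp(eta), rel=1e-9)

    def test_doubling_dre_multiplies_by_model_elasticity(self, fitted):
        fe = fitted.fixed_effects["estimate"]
        base = dict(y0=0.2, r_star=2.8, light="twilight", landing_type="free_flight")
        out = predict_emm(fitted, [dict(base, delta_re=1.0),
                                   dict(base, delta_re=2.0)])
        ratio = out["mean"].iloc[1] / out["mean"].iloc[0]
        expected = np.exp((fe["log_dre"] + fe["log_y0:log_dre"] * np.log(0.2))
                          * np.log(2))
        assert ratio == pytest.approx(expected, rel=1e-9)

    def test_bonferroni_adjustment_is_three_times_raw(self, fitted):
        con = posthoc_contrasts(fitted)
        light = con[con["family"] == "light"]
        for _, row in light.iterrows():
            assert row["p_adj"] == pytest.approx(min(1.0, 3 * row["p_raw"]), abs=1e-12)
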