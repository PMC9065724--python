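"""Statistical models: gamma fit of expansion-accelerations and the linear
mixed-effects models of the entry-segment kinematics.

The expansion-acceleration distribution across entry segments is summarized
by a two-parameter gamma fit (shape a, scale b, location fixed at zero).  The
mixed models regress the log response (rdot_e or Ae_mean) on

    log(y0), medium-light, sunrise, after-takeoff, log(dre), log(rstar),
    log(y0) x log(dre)

with random intercepts for experimental day, landing approach number and
landing side (crossed), fitted by REML.  Natural logarithms throughout;
p-values are large-sample Wald.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

log = logging.getLogger(__name__)

FIXED_TERMS = [
    "Intercept",
    "log_y0",
    "light_medium",
    "light_sunrise",
    "after_takeoff",
    "log_dre",
    "log_rstar",
    "log_y0:log_dre",
]


@dataclass
class GammaFit:
    a: float
    b: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    sample_median: float
    n: int


def fit_gamma(samples: np.ndarray) -> GammaFit:
    """Maximum-likelihood gamma(shape, scale) fit with asymptotic 95% CIs.

    Location is fixed at zero; the CIs come from the inverse Fisher
    information of the (a, b) likelihood.
    """
    x = np.asarray(samples, float)
    bad = np.flatnonzero(~(x > 0))
    if bad.size:
        raise ValueError(f"non-positive samples at indices {bad[:10].tolist()}")
    if x.size < 10:
        raise ValueError("need at least 10 samples")
    a, _, b = sps.gamma.fit(x, floc=0)
    n = x.size
    # per-observation Fisher information for (a, b), location known
    info = n * np.array([
        [special.polygamma(1, a), 1.0 / b],
        [1.0 / b, a / b**2],
    ])
    cov = np.linalg.inv(info)
    se_a, se_b = np.sqrt(np.diag(cov))
    z = sps.norm.ppf(0.975)
    return GammaFit(
        a=float(a), b=float(b),
        ci_a=(float(a - z * se_a), float(a + z * se_a)),
        ci_b=(float(b - z * se_b), float(b + z * se_b)),
        sample_median=float(np.median(x)),
        n=n,
    )


def gamma_median_approx(a: float, b: float) -> float:
    """Wilson-Hilferty-type approximation to the gamma median."""
    return b * (a - 1.0 / 3.0 + 8.0 / (405.0 * a))


@dataclass
class LMMResult:
    response: str
    fixed_effects: pd.DataFrame     # index=term; estimate, se, t, p
    random_sd: dict                 # per grouping factor + "residual"
    n_obs: int
    cov_fe: pd.DataFrame
    model: object = field(repr=False, default=None)
    dropped_factors: list = field(default_factory=list)


def _design_frame(table: pd.DataFrame, response: str) -> pd.DataFrame:
    need = {"y0_m", "delta_re_per_s", "r_star_per_s", "light", "landing_type",
            "day", "approach_number", "landing_side", response}
    missing = need - set(table.columns)
    if missing:
        raise ValueError(f"entries table missing column(s): {sorted(missing)}")
    df = table.copy()
    for col in ("y0_m", "delta_re_per_s", "r_star_per_s", response):
        if not np.all(df[col] > 0):
            raise ValueError(f"{col} must be positive for the log transform")
    out = pd.DataFrame({
        "log_resp": np.log(df[response].to_numpy(float)),
        "log_y0": np.log(df["y0_m"].to_numpy(float)),
        "log_dre": np.log(df["delta_re_per_s"].to_numpy(float)),
        "log_rstar": np.log(df["r_star_per_s"].to_numpy(float)),
        "light_medium": (df["light"] == "medium").astype(float).to_numpy(),
        "light_sunrise": (df["light"] == "sunrise").astype(float).to_numpy(),
        "after_takeoff": (df["landing_type"] == "after_takeoff").astype(float).to_numpy(),
        "day": df["day"].astype(str).to_numpy(),
        "approach": df["approach_number"].astype(str).to_numpy(),
        "side": df["landing_side"].astype(str).to_numpy(),
    })
    return out


_FORMULA = ("log_resp ~ log_y0 + light_medium + light_sunrise + after_takeoff"
            " + log_dre + log_rstar + log_y0:log_dre")
_RANDOM = ("day", "approach", "side")


def fit_lmm(table: pd.DataFrame, response: str = "rdot_per_s2") -> LMMResult:
    """REML fit of the log-response mixed model on an entries table.

    Random intercepts for day, approach number and landing side are crossed,
    realized as variance components over a single trivial group.  A factor
    whose variance collapses to (numerically) zero is dropped with a logged
    warning and the model refitted.
    """
    df = _design_frame(table, response)
    factors = [f for f in _RANDOM if df[{"day": "day", "approach": "approach",
                                         "side": "side"}[f]].nunique() >= 2]
    dropped = [f for f in _RANDOM if f not in factors]
    for f in dropped:
        log.warning("random factor %r has < 2 levels; dropped", f)
    df = df.assign(one=1)
    while True:
        vc = {f: f"0 + C({f})" for f in factors}
        if not vc:
            # every random factor degenerate: the model reduces to OLS
            ols = smf.ols(_FORMULA, df).fit()
            fe = pd.DataFrame({
                "estimate": ols.params, "se": ols.bse,
                "t": ols.params / ols.bse,
            })
            fe["p"] = 2 * sps.norm.sf(np.abs(fe["t"]))
            return LMMResult(
                response=response, fixed_effects=fe,
                random_sd={"residual": float(np.sqrt(ols.mse_resid))},
                n_obs=len(df),
                cov_fe=pd.DataFrame(np.asarray(ols.cov_params()),
                                    index=fe.index, columns=fe.index),
                model=ols, dropped_factors=dropped)
        model = smf.mixedlm(_FORMULA, df, groups="one", vc_formula=vc,
                            re_formula="0")
        try:
            # Powell handles the zero-variance boundary that gradient
            # methods stall on (a factor with no real variation must come
            # back with a component of exactly zero, as lme4 does)
            with np.errstate(all="ignore"):
                res = model.fit(reml=True, method="powell", maxiter=2000)
                try:
                    res_g = model.fit(reml=True, method="lbfgs", maxiter=400)
                    if np.isfinite(res_g.llf) and res_g.llf > res.llf + 1e-6:
                        res = res_g
                except Exception:
                    pass
        except Exception as exc:
            if factors:
                log.warning("mixed fit failed (%s); dropping %r", exc, factors[-1])
                dropped.append(factors.pop())
                continue
            raise
        # singular variance component: refit without it
        if vc:
            vcomp = dict(zip(model.exog_vc.names, np.atleast_1d(res.vcomp)))
            singular = [f for f, v in vcomp.items() if v < 1e-10]
        else:
            singular = []
        if singular and factors:
            worst = singular[0]
            log.warning("singular random factor %r; refitting without it", worst)
            factors.remove(worst)
            dropped.append(worst)
            continue
        break

    fe_names = list(res.fe_params.index)
    fe = pd.DataFrame({
        "estimate": res.fe_params.values,
        "se": res.bse_fe.values,
        "t": res.fe_params.values / res.bse_fe.values,
    }, index=fe_names)
    fe["p"] = 2 * sps.norm.sf(np.abs(fe["t"]))
    random_sd = {"residual": float(np.sqrt(res.scale))}
    if vc:
        vcomp = dict(zip(model.exog_vc.names, np.atleast_1d(res.vcomp)))
        for f, v in vcomp.items():
            random_sd[f] = float(np.sqrt(max(v, 0.0)))
    cov = pd.DataFrame(np.asarray(res.cov_params())[:len(fe_names), :len(fe_names)],
                       index=fe_names, columns=fe_names)
    return LMMResult(response=response, fixed_effects=fe, random_sd=random_sd,
                     n_obs=len(df), cov_fe=cov, model=res, dropped_factors=dropped)


def fit_ols_reference(table: pd.DataFrame, response: str = "rdot_per_s2"):
    """Plain OLS with the same fixed-effect design (degenerate-LMM check)."""
    df = _design_frame(table, response)
    return smf.ols(_FORMULA, df).fit()


def _design_row(settings: dict) -> pd.Series:
    log_y0 = np.log(settings["y0"])
    log_dre = np.log(settings["delta_re"])
    return pd.Series({
        "Intercept": 1.0,
        "log_y0": log_y0,
        "light_medium": 1.0 if settings.get("light", "twilight") == "medium" else 0.0,
        "light_sunrise": 1.0 if settings.get("light", "twilight") == "sunrise" else 0.0,
        "after_takeoff": 1.0 if settings.get("landing_type", "free_flight") == "after_takeoff" else 0.0,
        "log_dre": log_dre,
        "log_rstar": np.log(settings["r_star"]),
        "log_y0:log_dre": log_y0 * log_dre,
    })


def predict_emm(result: LMMResult, settings: Sequence[dict],
                observed_ranges: Optional[dict] = None) -> pd.DataFrame:
    """Back-transformed model predictions at given covariate settings.

    Each setting dict gives y0 (m), delta_re (1/s), r_star (1/s) and
    optionally light / landing_type.  Random effects are averaged over (set
    to zero); the CI is a delta-method interval exponentiated from the log
    scale.  Settings outside ``observed_ranges`` draw a warning, not an
    error.
    """
    fe = result.fixed_effects["estimate"]
    cov = result.cov_fe
    rows = []
    for s in settings:
        if observed_ranges:
            for key in ("y0", "delta_re", "r_star"):
                lo, hi = observed_ranges.get(key, (-np.inf, np.inf))
                if not lo <= s[key] <= hi:
                    log.warning("setting %s=%g outside observed range [%g, %g]",
                                key, s[key], lo, hi)
        x = _design_row(s).reindex(fe.index).fillna(0.0)
        eta = float(x @ fe)
        se = float(np.sqrt(x @ cov.values @ x))
        z = sps.norm.ppf(0.975)
        rows.append({
            **s,
            "log_mean": eta, "log_se": se,
            "mean": np.exp(eta),
            "ci_low": np.exp(eta - z * se),
            "ci_high": np.exp(eta + z * se),
            "se_mean": np.exp(eta) * se,   # delta method on the response scale
        })
    return pd.DataFrame(rows)


def posthoc_contrasts(result: LMMResult) -> pd.DataFrame:
    """Bonferroni-adjusted pairwise light contrasts and the landing-type one.

    The family is the three pairwise light comparisons plus the single
    landing-type comparison, each adjusted within its family per the
    reported procedure (adjusted p = min(1, m * p_raw)).
    """
    fe = result.fixed_effects["estimate"]
    cov = result.cov_fe

    def contrast(vec: dict) -> tuple[float, float]:
        x = pd.Series(0.0, index=fe.index)
        for k, v in vec.items():
            x[k] = v
        est = float(x @ fe)
        se = float(np.sqrt(x @ cov.values @ x))
        return est, se

    rows = []
    light_family = [
        ("medium - twilight", {"light_medium": 1.0}),
        ("sunrise - twilight", {"light_sunrise": 1.0}),
        ("sunrise - medium", {"light_sunrise": 1.0, "light_medium": -1.0}),
    ]
    for name, vec in light_family:
        est, se = contrast(vec)
        p = 2 * sps.norm.sf(abs(est / se))
        rows.append({"contrast": name, "family": "light", "estimate": est,
                     "se": se, "p_raw": p, "p_adj": min(1.0, 3 * p)})
    est, se = contrast({"after_takeoff": 1.0})
    p = 2 * sps.norm.sf(abs(est / se))
    rows.append({"contrast": "after_takeoff - free_flight", "family": "landing_type",
                 "estimate": est, "se": se, "p_raw": p, "p_adj": min(1.0, p)})
    return pd.DataFrame(rows)
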