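"""Mixed-effects driver regressions with exhaustive AIC subset selection.

Waiting time is regressed on a candidate subset of the ten drivers plus two
forced background variables, with a level-IV eco-region random intercept:

    W_i = beta_0 + x_i' beta + alpha_{g(i)} + e_i,
    alpha_g ~ N(0, sigma2_alpha),  e_i ~ N(0, sigma2_eps).

Fits use maximum likelihood (not REML) so that AIC is comparable across
fixed-effect structures; AIC counts the fixed effects (incl. intercept)
plus the two variance components.  All 2^k driver subsets are enumerated,
ties broken by fewer parameters then lexicographic term order.  Predictors
are z-standardized within each model's fitting subset so coefficients are
comparable across terms.

Model quality is summarized by the variance-inflation factors of the
selected design and by the marginal / conditional R^2 of Nakagawa &
Schielzeth:

    R2_marginal    = s2_f / (s2_f + s2_alpha + s2_eps)
    R2_conditional = (s2_f + s2_alpha) / (s2_f + s2_alpha + s2_eps)

with ``s2_f`` the variance of the fixed-effects linear predictor over the
fitted rows.  A driver-only marginal R^2 replaces the numerator by the
variance of the linear predictor restricted to driver terms (coefficients
from the full fit) — exact under orthogonality, an approximation otherwise.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "ModelSpec",
    "RegressionFit",
    "fit_lmm",
    "all_subsets_aic",
    "vif",
    "r2_nakagawa",
    "r2_marginal_drivers",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelSpec:
    """One candidate mixed-model structure."""

    response: str = "waiting_time"
    drivers: tuple[str, ...] = ()
    forced: tuple[str, ...] = ("detection_year", "neighbor_wait")
    group: str = "level4"

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(self.forced) + tuple(self.drivers)


@dataclass
class RegressionFit:
    """A fitted random-intercept model and its summaries."""

    spec: ModelSpec
    params: pd.Series  # fixed effects incl. intercept
    bse: pd.Series
    sigma2_alpha: float
    sigma2_eps: float
    sigma2_f: float
    loglik: float
    aic: float
    n: int
    n_groups: int
    design: pd.DataFrame = field(repr=False)  # standardized fixed-effect columns
    linpred_driver_var: float = 0.0

    @property
    def terms(self) -> tuple[str, ...]:
        return self.spec.terms


def _standardize(x: pd.DataFrame) -> pd.DataFrame:
    out = x.astype(float).copy()
    for c in out.columns:
        sd = out[c].std(ddof=1)
        if sd > 0:
            out[c] = (out[c] - out[c].mean()) / sd
        else:
            out[c] = 0.0
    return out


def fit_lmm(
    table: pd.DataFrame, spec: ModelSpec, standardize: bool = True
) -> RegressionFit:
    """Maximum-likelihood fit of W ~ fixed effects + (1 | level-IV unit)."""
    terms = list(spec.terms)
    x = table[terms]
    if standardize:
        x = _standardize(x)
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(x)), x.to_numpy()]))
    if rank < len(terms) + 1:
        corr = x.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.max().sort_values(ascending=False)
        bad = list(worst.index[worst > 0.999]) or terms
        raise ValueError(f"singular design; collinear columns: {bad}")
    exog = sm.add_constant(x, has_constant="add")
    groups = table[spec.group]
    if groups.nunique() < 2:
        raise ValueError("random-intercept grouping needs >= 2 levels")
    model = sm.MixedLM(table[spec.response].astype(float), exog, groups=groups)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        res = model.fit(reml=False)
        bse_fe = res.bse_fe  # may hit sqrt of ~0 at a variance boundary
    sigma2_alpha = float(res.cov_re.iloc[0, 0])
    sigma2_eps = float(res.scale)
    llf = float(res.llf)
    params = res.fe_params
    if sigma2_alpha <= 1e-10 or not np.isfinite(llf):
        # at the sigma2_alpha = 0 boundary the ML solution is plain OLS;
        # the profiled mixed-model likelihood degenerates there (inf llf,
        # singular covariance), so evaluate the boundary fit directly
        ols = sm.OLS(table[spec.response].astype(float), exog).fit()
        params = ols.params
        bse_fe = ols.bse
        sigma2_alpha = 0.0
        sigma2_eps = float(ols.ssr / len(table))
        llf = float(ols.llf)
    if not np.isfinite(llf):
        raise ValueError("mixed-model fit failed (non-finite likelihood)")
    linpred = exog.to_numpy() @ params.to_numpy()
    sigma2_f = float(np.var(linpred, ddof=1))
    k_fixed = len(params)
    aic = -2.0 * llf + 2.0 * (k_fixed + 2)  # + sigma2_alpha, sigma2_eps
    drv = list(spec.drivers)
    if drv:
        lp_drv = x[drv].to_numpy() @ params[drv].to_numpy()
        drv_var = float(np.var(lp_drv, ddof=1))
    else:
        drv_var = 0.0
    return RegressionFit(
        spec=spec,
        params=params,
        bse=bse_fe,
        sigma2_alpha=sigma2_alpha,
        sigma2_eps=sigma2_eps,
        sigma2_f=sigma2_f,
        loglik=llf,
        aic=float(aic),
        n=len(table),
        n_groups=int(groups.nunique()),
        design=x,
        linpred_driver_var=drv_var,
    )


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per predictor: 1 / (1 - R2_j), where R2_j
    regresses predictor j on the others (intercept included).  Perfect
    collinearity reports inf."""
    if design.shape[1] < 2:
        raise ValueError("VIF needs >= 2 predictors")
    if design.shape[0] <= design.shape[1]:
        raise ValueError("VIF needs n > p")
    out = {}
    for col in design.columns:
        others = sm.add_constant(design.drop(columns=col), has_constant="add")
        r2 = sm.OLS(design[col].astype(float), others).fit().rsquared
        out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def r2_nakagawa(fit: RegressionFit) -> tuple[float, float]:
    """Marginal and conditional R^2 from the fit's variance components."""
    total = fit.sigma2_f + fit.sigma2_alpha + fit.sigma2_eps
    if total <= 0:
        raise ValueError("all variance components are zero; R2 undefined")
    r2m = fit.sigma2_f / total
    r2c = (fit.sigma2_f + fit.sigma2_alpha) / total
    return float(r2m), float(r2c)


def r2_marginal_drivers(fit: RegressionFit) -> float:
    """Marginal R^2 of the driver terms alone (background variables
    excluded), using the full-fit coefficients."""
    total = fit.sigma2_f + fit.sigma2_alpha + fit.sigma2_eps
    if total <= 0:
        raise ValueError("all variance components are zero; R2 undefined")
    return float(fit.linpred_driver_var / total)


def all_subsets_aic(
    table: pd.DataFrame,
    candidates: tuple[str, ...],
    spec: ModelSpec | None = None,
    standardize: bool = True,
) -> tuple[RegressionFit, pd.DataFrame]:
    """Exhaustive AIC model selection over all 2^k driver subsets.

    Every candidate model carries the forced background terms and the
    random intercept.  Returns the minimum-AIC fit (ties: fewer parameters,
    then lexicographic term order) and the full ranked table.  Subsets
    whose fit fails are logged and marked, never silently dropped.
    """
    if len(candidates) > 15:
        raise ValueError("more than 15 candidate drivers (2^k enumeration)")
    base = spec or ModelSpec()
    rows = []
    fits: dict[int, RegressionFit] = {}
    for mask in range(2 ** len(candidates)):
        drivers = tuple(
            c for i, c in enumerate(candidates) if mask & (1 << i)
        )
        mspec = ModelSpec(
            response=base.response,
            drivers=drivers,
            forced=base.forced,
            group=base.group,
        )
        row = {
            "mask": mask,
            "k": len(drivers),
            "terms": "+".join(drivers) or "(forced only)",
            "aic": np.nan,
            "loglik": np.nan,
            "ok": False,
        }
        try:
            fit = fit_lmm(table, mspec, standardize=standardize)
        except Exception as exc:  # noqa: BLE001 — any failed subset is logged
            logger.warning("subset %s failed: %s", drivers, exc)
            rows.append(row)
            continue
        if not np.isfinite(fit.aic):
            logger.warning("subset %s returned non-finite AIC; skipped", drivers)
            rows.append(row)
            continue
        fits[mask] = fit
        row.update(aic=fit.aic, loglik=fit.loglik, ok=True)
        rows.append(row)
    if not fits:
        raise RuntimeError("every candidate subset failed to fit")
    ranked = pd.DataFrame(rows)
    ranked["delta_aic"] = ranked["aic"] - ranked["aic"].min()
    ranked = ranked.sort_values(
        ["aic", "k", "terms"], na_position="last"
    ).reset_index(drop=True)
    best_mask = int(ranked.loc[0, "mask"])
    return fits[best_mask], ranked
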