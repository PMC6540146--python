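"""Log-linear mixed models with neighbourhood-in-city random intercepts.

Outcomes are log(y + c) transformed; each association model has one
built-environment exposure plus the full individual/neighbourhood
covariate adjustment set, random intercepts for city and for study
neighbourhood nested in city (REML), and Wald 95% CIs.  Exponentiated
coefficients are reported as percentage change in the outcome per unit
exposure.  Supporting statistics: a boundary-corrected likelihood-ratio
test of the multilevel structure, the adjusted ICC from intercept-only
models, and marginal/conditional R^2 (variance of the fixed-effect
predictor relative to fixed + random + residual variance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

Z975 = float(stats.norm.ppf(0.975))

DEFAULT_COVARIATES = (
    "sex",
    "age",
    "ethnicity",
    "income",
    "marital",
    "education",
    "employment",
    "car_access",
    "deprivation",
    "preference",
)
_NUMERIC_COVARIATES = {"age", "deprivation"}


@dataclass
class ModelSpec:
    """Specification of one association model."""

    outcome: str
    exposure: str
    definition: str | None = None
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    offset: float = 1.0  # c in log(y + c)
    city_col: str = "city_id"
    nbhd_col: str = "study_neighbourhood_id"

    def __post_init__(self) -> None:
        if self.offset < 0:
            raise ValueError("offset must be non-negative")


@dataclass
class ModelResult:
    """One fitted association with all derived statistics."""

    outcome: str
    exposure: str
    definition: str | None
    n_used: int
    n_dropped: int
    beta_hat: float
    se: float
    ci_low: float
    ci_high: float
    pct_change: float
    pct_low: float
    pct_high: float
    sigma2_city: float
    sigma2_nbhd: float
    sigma2_resid: float
    r2_marginal: float
    r2_conditional: float
    evidence: bool
    offset: float
    fallback: str = "none"  # none | drop_city | ols
    icc_null: float | None = None

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class LRTestResult:
    statistic: float
    pvalue: float
    df_mixture: tuple[int, int] = (1, 2)


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------


def transform_outcome(y, c: float) -> np.ndarray:
    """log(y + c); requires y >= 0 and c > 0 whenever any y is zero."""
    y = np.asarray(y, dtype=float)
    if (y < 0).any():
        raise ValueError("outcomes must be non-negative")
    if c <= 0 and (y == 0).any():
        raise ValueError("offset c must be positive when outcomes contain zeros")
    return np.log(y + c)


def pct_change(beta_hat: float, ci: tuple[float, float]) -> tuple[float, float, float]:
    """Map a log-scale estimate and CI to the percentage-change scale.

    100*(exp(x)-1) is strictly increasing, so the CI ordering is preserved
    and the evidence judgement is identical on either scale.
    """
    f = lambda v: 100.0 * (np.exp(v) - 1.0)
    return (float(f(beta_hat)), float(f(ci[0])), float(f(ci[1])))


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------


def _formula(spec: ModelSpec, columns: Sequence[str], lhs: str = "_ylog") -> str:
    terms = [spec.exposure]
    for c in spec.covariates:
        if c not in columns:
            continue
        terms.append(c if c in _NUMERIC_COVARIATES else f"C({c})")
    return f"{lhs} ~ " + " + ".join(terms)


def _prepare(spec: ModelSpec, data: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    needed = [spec.outcome, spec.exposure, spec.city_col, spec.nbhd_col] + [
        c for c in spec.covariates if c in data.columns
    ]
    df = data.loc[:, sorted(set(needed))].copy()
    n0 = len(df)
    df = df.dropna()
    df["_ylog"] = transform_outcome(df[spec.outcome].to_numpy(), spec.offset)
    return df, n0 - len(df)


def _fit_mixed(formula: str, df: pd.DataFrame, city: str, nbhd: str, reml: bool = True):
    model = smf.mixedlm(
        formula,
        df,
        groups=city,
        re_formula="1",
        vc_formula={"nbhd": f"0 + C({nbhd})"},
    )
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # variance components on the boundary can defeat a single optimizer
        for method in ("bfgs", "powell", "cg"):
            res = model.fit(reml=reml, method=method, maxiter=200)
            if res.converged:
                break
    return res


def _variances(res) -> tuple[float, float, float]:
    s_city = float(np.asarray(res.cov_re)[0, 0]) if res.cov_re.size else 0.0
    s_nbhd = float(res.vcomp[0]) if len(res.vcomp) else 0.0
    return s_city, s_nbhd, float(res.scale)


def r2_nakagawa(res) -> tuple[float, float]:
    """Marginal and conditional R^2 of a fitted mixed (or OLS) model.

    sigma2_f is the sample variance of the fixed-effect linear predictor;
    marginal R^2 = sigma2_f / total, conditional adds the random-intercept
    variances to the numerator.
    """
    if hasattr(res, "fe_params"):
        pred = np.asarray(res.model.exog) @ np.asarray(res.fe_params)
        s_city, s_nbhd, s_resid = _variances(res)
    else:  # OLS fallback
        pred = res.fittedvalues
        s_city = s_nbhd = 0.0
        s_resid = float(res.scale)
    sigma2_f = float(np.var(pred))
    total = sigma2_f + s_city + s_nbhd + s_resid
    if total <= 0:
        raise ValueError("zero total variance; R^2 undefined")
    return sigma2_f / total, (sigma2_f + s_city + s_nbhd) / total


def fit_lmm(spec: ModelSpec, data: pd.DataFrame) -> ModelResult:
    """REML fit of one association model with the nested random structure.

    Missing-value rows are dropped (counted in ``n_dropped``).  If the full
    random structure fails to fit, the city variance component is dropped
    (``fallback='drop_city'``); if that also fails the model collapses to
    OLS (``fallback='ols'``), each flagged explicitly in the result.
    """
    df, n_dropped = _prepare(spec, data)
    if df[spec.city_col].nunique() < 2:
        raise ValueError("need at least 2 cities")
    formula = _formula(spec, df.columns)

    fallback = "none"
    res = None
    try:
        res = _fit_mixed(formula, df, spec.city_col, spec.nbhd_col)
        if not (res.converged and np.isfinite(res.bse.get(spec.exposure, np.nan))):
            res = None
    except Exception:
        res = None
    if res is None:
        fallback = "drop_city"
        try:
            model = smf.mixedlm(formula, df, groups=spec.nbhd_col, re_formula="1")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(reml=True, method="lbfgs", maxiter=200)
            if not (res.converged and np.isfinite(res.bse.get(spec.exposure, np.nan))):
                res = None
        except Exception:
            res = None
    if res is not None and fallback == "drop_city":
        beta = float(res.fe_params[spec.exposure])
        se = float(res.bse[spec.exposure])
        s_city, s_nbhd, s_resid = 0.0, float(np.asarray(res.cov_re)[0, 0]), float(res.scale)
        r2m, r2c = r2_nakagawa(res)
    elif res is not None:
        beta = float(res.fe_params[spec.exposure])
        se = float(res.bse[spec.exposure])
        s_city, s_nbhd, s_resid = _variances(res)
        r2m, r2c = r2_nakagawa(res)
    else:
        fallback = "ols"
        ols = smf.ols(formula, df).fit()
        beta = float(ols.params[spec.exposure])
        se = float(ols.bse[spec.exposure])
        s_city = s_nbhd = 0.0
        s_resid = float(ols.scale)
        r2m, r2c = r2_nakagawa(ols)

    ci = (beta - Z975 * se, beta + Z975 * se)
    pc, pl, ph = pct_change(beta, ci)
    return ModelResult(
        outcome=spec.outcome,
        exposure=spec.exposure,
        definition=spec.definition,
        n_used=len(df),
        n_dropped=n_dropped,
        beta_hat=beta,
        se=se,
        ci_low=ci[0],
        ci_high=ci[1],
        pct_change=pc,
        pct_low=pl,
        pct_high=ph,
        sigma2_city=s_city,
        sigma2_nbhd=s_nbhd,
        sigma2_resid=s_resid,
        r2_marginal=r2m,
        r2_conditional=r2c,
        evidence=bool(ci[0] > 0 or ci[1] < 0),
        offset=spec.offset,
        fallback=fallback,
    )


# ---------------------------------------------------------------------------
# clustering diagnostics
# ---------------------------------------------------------------------------


def lr_test_clustering(spec: ModelSpec, data: pd.DataFrame) -> LRTestResult:
    """LR test of the two-level random structure in the empty model.

    ML fits of the intercept-only model with and without the city and
    neighbourhood random intercepts; the statistic is referred to a 50:50
    mixture of chi-square(1) and chi-square(2) because both variance
    components lie on the boundary under the null.
    """
    df, _ = _prepare(spec, data)
    full = _fit_mixed("_ylog ~ 1", df, spec.city_col, spec.nbhd_col, reml=False)
    if not full.converged:
        raise RuntimeError("mixed intercept-only model did not converge")
    null = sm.OLS(df["_ylog"].to_numpy(), np.ones((len(df), 1))).fit()
    stat = max(0.0, 2.0 * (float(full.llf) - float(null.llf)))
    p = 0.5 * stats.chi2.sf(stat, 1) + 0.5 * stats.chi2.sf(stat, 2)
    return LRTestResult(statistic=stat, pvalue=float(p))


def icc_null(spec: ModelSpec, data: pd.DataFrame) -> float:
    """Adjusted ICC from the intercept-only (null) REML model.

    (sigma2_city + sigma2_nbhd) / (sigma2_city + sigma2_nbhd + sigma2_resid).
    """
    df, _ = _prepare(spec, data)
    res = _fit_mixed("_ylog ~ 1", df, spec.city_col, spec.nbhd_col, reml=True)
    s_city, s_nbhd, s_resid = _variances(res)
    total = s_city + s_nbhd + s_resid
    if total <= 0:
        return 0.0
    return (s_city + s_nbhd) / total
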