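"""Mixed-model inference for the five roost predictions.

Each response (settling slope, logit night-calling proportion,
pre-departure slope, departure cohesion, roost-emptying time) is fitted
as a Gaussian linear mixed model with crossed random intercepts for
roost site and month, scaled fixed predictors, maximum-likelihood
estimation (required for valid likelihood-ratio tests across fixed
effect specifications), single-term-deletion LRTs and VIF screening.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import chi2

__all__ = [
    "ModelSpec",
    "ModelReport",
    "logit_transform",
    "inverse_logit",
    "scale_predictors",
    "fit_lmm",
    "drop1_lrt",
    "variance_inflation",
    "run_prediction_suite",
    "PREDICTION_SPECS",
]


def logit_transform(p, eps: float = 1e-3):
    """log(p/(1-p)) with p clamped to [eps, 1-eps] so exact 0/1
    proportions stay finite."""
    arr = np.asarray(p, dtype=np.float64)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    clamped = np.clip(arr, eps, 1.0 - eps)
    out = np.log(clamped / (1.0 - clamped))
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def inverse_logit(x):
    return expit(x)


def scale_predictors(
    table: pd.DataFrame, columns: list[str]
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Centre each column to mean 0 and scale to sample SD 1 (binary
    indicators included), so coefficient magnitudes are comparable
    effect sizes.  Returns the scaled table and {column: (mean, sd)}."""
    out = table.copy()
    constants: dict[str, tuple[float, float]] = {}
    for col in columns:
        x = pd.to_numeric(out[col], errors="raise").astype(float)
        mu, sd = float(x.mean()), float(x.std(ddof=1))
        if sd == 0.0 or not math.isfinite(sd):
            raise ValueError(f"cannot scale zero-variance column '{col}'")
        out[col] = (x - mu) / sd
        constants[col] = (mu, sd)
    return out, constants


@dataclass(frozen=True)
class ModelSpec:
    """One prediction model: response (+ optional logit transform),
    fixed predictors, crossed site/month random intercepts, optional
    site-exclusion subset."""

    response: str
    fixed_predictors: tuple[str, ...]
    transform: str = "identity"        # identity | logit
    random_intercepts: tuple[str, ...] = ("site", "month")
    exclude_sites: tuple[str, ...] = ()
    name: str = ""

    def __post_init__(self) -> None:
        if self.transform not in ("identity", "logit"):
            raise ValueError(f"unknown transform '{self.transform}'")
        if self.response in self.fixed_predictors:
            raise ValueError("response cannot be one of its own predictors")


@dataclass
class ModelReport:
    """Fitted-model summary: scaled coefficients, single-term-deletion
    LRTs, VIFs, log-likelihood/AIC and a convergence flag."""

    spec: ModelSpec
    coefficients: pd.DataFrame            # estimate, se per term
    lrt: pd.DataFrame | None              # chi2, df, p, dAIC per predictor
    vif: dict[str, float]
    n_obs: int
    n_dropped: int
    loglik: float
    aic: float
    converged: bool
    scaling: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "name": self.spec.name or self.spec.response,
            "response": self.spec.response,
            "transform": self.spec.transform,
            "n_obs": self.n_obs,
            "n_dropped": self.n_dropped,
            "loglik": self.loglik,
            "aic": self.aic,
            "converged": self.converged,
            "coefficients": self.coefficients.to_dict(orient="index"),
            "lrt": None if self.lrt is None else self.lrt.to_dict(orient="index"),
            "vif": self.vif,
        }

    def summary_text(self) -> str:
        lines = [f"Model: {self.spec.name or self.spec.response} "
                 f"({self.spec.transform} response), n = {self.n_obs}"]
        lines.append(self.coefficients.round(4).to_string())
        if self.lrt is not None:
            lines.append("Single-term deletions:")
            lines.append(self.lrt.round(4).to_string())
        lines.append("VIF: " + ", ".join(f"{k}={v:.2f}" for k, v in self.vif.items()))
        return "\n".join(lines)


def variance_inflation(table: pd.DataFrame, columns: list[str]) -> dict[str, float]:
    """VIF per predictor from the design matrix with intercept."""
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    X = sm.add_constant(table[list(columns)].astype(float).to_numpy())
    return {
        col: float(variance_inflation_factor(X, i + 1))
        for i, col in enumerate(columns)
    }


def _prepare(table: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, int]:
    needed = [spec.response, *spec.fixed_predictors, *spec.random_intercepts]
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise ValueError(f"table lacks columns {missing}")
    df = table.copy()
    if spec.exclude_sites:
        df = df[~df["site"].isin(spec.exclude_sites)]
    before = len(df)
    df = df.dropna(subset=needed).reset_index(drop=True)
    n_dropped = before - len(df)
    if len(df) < len(spec.fixed_predictors) + 3:
        raise ValueError(f"only {len(df)} complete cases for '{spec.response}'")
    df, scaling = scale_predictors(df, list(spec.fixed_predictors))
    y = df[spec.response].astype(float)
    df["_y"] = logit_transform(y.to_numpy()) if spec.transform == "logit" else y
    df.attrs["scaling"] = scaling
    return df, n_dropped


def _fit_ml(df: pd.DataFrame, predictors: tuple[str, ...],
            random_intercepts: tuple[str, ...]):
    """ML fit of a Gaussian LMM with crossed random intercepts via
    variance components over a single all-data group."""
    df = df.copy()
    df["_grp"] = 1
    rhs = " + ".join(predictors) if predictors else "1"
    vc = {re: f"0 + C({re})" for re in random_intercepts}
    model = sm.MixedLM.from_formula(
        f"_y ~ {rhs}", groups="_grp", vc_formula=vc, re_formula="0", data=df
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=False, method="lbfgs", maxiter=200)
            if not res.converged:
                res = model.fit(reml=False, method="powell", maxiter=500)
        except Exception:
            res = model.fit(reml=False, method="powell", maxiter=500)
    k = len(predictors) + 1 + len(random_intercepts) + 1  # betas + VCs + resid
    aic = -2.0 * res.llf + 2.0 * k
    return res, aic


def fit_lmm(table: pd.DataFrame, spec: ModelSpec,
            with_lrt: bool = True) -> ModelReport:
    """Fit one prediction model (ML) and assemble its report.

    Rows with missing values in any model variable are dropped (count
    reported); predictors are scaled in the complete-case subset, so
    coefficients are per-SD effect sizes.  Non-convergence is flagged,
    not raised.
    """
    df, n_dropped = _prepare(table, spec)
    res, aic = _fit_ml(df, spec.fixed_predictors, spec.random_intercepts)
    fe = res.fe_params
    with warnings.catch_warnings():
        # near-boundary variance components can make the numerical
        # Hessian indefinite; the SEs come back NaN, which we keep
        warnings.simplefilter("ignore", RuntimeWarning)
        se = res.bse_fe.reindex(fe.index)
    coef = pd.DataFrame({"estimate": fe, "se": se})
    report = ModelReport(
        spec=spec,
        coefficients=coef,
        lrt=None,
        vif=variance_inflation(df, list(spec.fixed_predictors))
        if len(spec.fixed_predictors) > 1 else
        {p: 1.0 for p in spec.fixed_predictors},
        n_obs=len(df),
        n_dropped=n_dropped,
        loglik=float(res.llf),
        aic=float(aic),
        converged=bool(res.converged),
        scaling=df.attrs["scaling"],
    )
    if with_lrt and report.converged:
        report.lrt = drop1_lrt(table, spec, _full=(df, res, aic))
    return report


def drop1_lrt(table: pd.DataFrame, spec: ModelSpec, _full=None) -> pd.DataFrame:
    """Single-term deletion: for each fixed predictor, refit without it
    (ML) and report chi2 = 2(ll_full - ll_reduced), df = 1, the chi2
    p-value, and dAIC = AIC_reduced - AIC_full (positive = dropping the
    term worsens the model)."""
    if _full is None:
        df, _ = _prepare(table, spec)
        res_full, aic_full = _fit_ml(df, spec.fixed_predictors,
                                     spec.random_intercepts)
    else:
        df, res_full, aic_full = _full
    rows = {}
    for term in spec.fixed_predictors:
        reduced = tuple(p for p in spec.fixed_predictors if p != term)
        try:
            res_red, aic_red = _fit_ml(df, reduced, spec.random_intercepts)
            stat = max(0.0, 2.0 * (res_full.llf - res_red.llf))
            rows[term] = {
                "chi2": stat,
                "df": 1,
                "p": float(chi2.sf(stat, 1)),
                "dAIC": float(aic_red - aic_full),
                "converged": bool(res_red.converged),
            }
        except Exception:
            rows[term] = {"chi2": math.nan, "df": 1, "p": math.nan,
                          "dAIC": math.nan, "converged": False}
    return pd.DataFrame.from_dict(rows, orient="index")


#: Predictor sets for the five prediction models.  Background noise in
#: the window relevant to each response; departure models additionally
#: carry the overnight-calling proportion; roost size and daily weather
#: enter everywhere.
_WEATHER = ("roost_size", "temp_mean", "wind_mean", "rain")

PREDICTION_SPECS: dict[str, ModelSpec] = {
    "settling": ModelSpec(
        name="settling",
        response="settle_slope",
        fixed_predictors=("noise_prearrival", *_WEATHER),
    ),
    "night_calling": ModelSpec(
        name="night_calling",
        response="night_call_prop",
        transform="logit",
        fixed_predictors=("noise_overnight", *_WEATHER),
    ),
    "predeparture": ModelSpec(
        name="predeparture",
        response="predeparture_slope",
        fixed_predictors=("noise_predeparture", "night_call_prop", *_WEATHER),
    ),
    "cohesion": ModelSpec(
        name="cohesion",
        response="largest_group_prop",
        transform="logit",
        fixed_predictors=("noise_predeparture", "night_call_prop", *_WEATHER),
    ),
    "emptying": ModelSpec(
        name="emptying",
        response="time_to_empty_s",
        fixed_predictors=("noise_predeparture", "night_call_prop", *_WEATHER),
    ),
}

#: The acoustic models are re-run on the four non-urban sites with mean
#: overnight light as an extra predictor (the light logger at the most
#: urban site failed; this also checks that effects are not driven by
#: that site).  Sample sizes preclude light variants of the two
#: departure models.
_LIGHT_MODELS = ("settling", "night_calling", "predeparture")


def run_prediction_suite(
    metrics_table: pd.DataFrame,
    departures_table: pd.DataFrame | None = None,
    exclude_site: str | None = None,
    threshold_column: str = "night_call_prop",
) -> dict[str, ModelReport]:
    """Fit the five prediction models (plus four-site light variants
    when `exclude_site` is given) and return their reports.

    `metrics_table` holds one row per night; `departures_table`, if
    separate, is joined on site + date and must carry
    `largest_group_prop` and `time_to_empty_s`.  `threshold_column`
    lets the suite be re-run with the conservative 0.4-threshold
    calling proportion (`night_call_prop_alt`).
    """
    table = metrics_table.copy()
    if departures_table is not None:
        missing = [k for k in ("site", "date") if k not in departures_table.columns]
        if missing:
            raise ValueError(f"departures table lacks join keys {missing}")
        table = table.merge(departures_table, on=["site", "date"], how="left")
    reports: dict[str, ModelReport] = {}
    for key, spec in PREDICTION_SPECS.items():
        spec_used = spec
        if threshold_column != "night_call_prop":
            spec_used = ModelSpec(
                name=spec.name,
                response=threshold_column if spec.response == "night_call_prop"
                else spec.response,
                transform=spec.transform,
                fixed_predictors=tuple(
                    threshold_column if p == "night_call_prop" else p
                    for p in spec.fixed_predictors
                ),
                exclude_sites=spec.exclude_sites,
            )
        try:
            reports[key] = fit_lmm(table, spec_used)
        except ValueError as exc:
            warnings.warn(f"model '{key}' skipped: {exc}")
    if exclude_site is not None:
        for key in _LIGHT_MODELS:
            base = PREDICTION_SPECS[key]
            spec4 = ModelSpec(
                name=f"{key}_foursite",
                response=base.response,
                transform=base.transform,
                fixed_predictors=(*base.fixed_predictors, "light_mean"),
                exclude_sites=(exclude_site,),
            )
            try:
                reports[f"{key}_foursite"] = fit_lmm(table, spec4)
            except ValueError as exc:
                warnings.warn(f"model '{key}_foursite' skipped: {exc}")
    return reports
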