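"""Observational association models.

Implements the two-step analysis design: categorical contrasts of drinker
categories against an infrequent-drinker reference, then dose-response
modelling among regular drinkers only (per-SD and quintile analyses with
a median-based trend test), plus restricted-cubic-spline regression with
AIC-based knot selection on log intake, and a sensitivity-analysis
harness.

Continuous outcomes use ordinary least squares, glaucoma uses
maximum-likelihood logistic regression; both report Wald 95% intervals.
Model fitting is delegated to statsmodels; the restricted-cubic-spline
basis, Harrell knot heuristics, quintile construction and trend test are
implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "Covariate",
    "DEFAULT_COVARIATES",
    "ModelResult",
    "SplineFit",
    "build_design",
    "fit_linear",
    "fit_logistic",
    "categorical_analysis",
    "assign_quintiles",
    "quintile_analysis",
    "rcs_basis",
    "harrell_knots",
    "fit_rcs",
    "run_sensitivity",
    "per_sd_analysis",
]

CONTINUOUS_OUTCOMES = ("iop", "mrnfl", "mgcipl")
ALL_OUTCOMES = CONTINUOUS_OUTCOMES + ("glaucoma",)


@dataclass(frozen=True)
class Covariate:
    name: str
    kind: str  # "continuous" | "categorical"
    reference: str | None = None


#: the thirteen adjustment covariates of the maximally adjusted models
DEFAULT_COVARIATES: tuple[Covariate, ...] = (
    Covariate("age", "continuous"),
    Covariate("sex", "categorical", "women"),
    Covariate("ethnicity", "categorical", "White"),
    Covariate("townsend", "continuous"),
    Covariate("season", "categorical", "Summer"),
    Covariate("bmi", "continuous"),
    Covariate("height", "continuous"),
    Covariate("sbp", "continuous"),
    Covariate("spherical_equivalent", "continuous"),
    Covariate("diabetes", "continuous"),  # 0/1 indicator
    Covariate("smoking_status", "categorical", "never"),
    Covariate("smoking_intensity", "continuous"),
    Covariate("physical_activity", "continuous"),
)


@dataclass
class ModelResult:
    """A fitted association for one model term."""

    term: str
    estimate: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    scale: str = "identity"  # "identity" | "odds-ratio"

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("confidence bounds must bracket the estimate")


class CollinearityError(ValueError):
    """Raised when the design matrix is rank deficient."""


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # identify offending columns via the QR decomposition
        _, r = np.linalg.qr(arr)
        diag = np.abs(np.diag(r))
        bad = [X.columns[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise CollinearityError(f"rank-deficient design; collinear terms: {bad}")


def build_design(
    data: pd.DataFrame,
    covariates: Sequence[Covariate] = DEFAULT_COVARIATES,
    extra: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble an intercept + exposure + covariate design matrix.

    Categorical covariates are dummy-expanded against their stated
    reference level; ``extra`` columns (exposure terms) come first.
    """
    cols = [pd.Series(1.0, index=data.index, name="const")]
    if extra is not None:
        for c in extra.columns:
            cols.append(extra[c].astype(float))
    for cov in covariates:
        if cov.kind == "continuous":
            cols.append(data[cov.name].astype(float))
        else:
            dummies = pd.get_dummies(data[cov.name], prefix=cov.name, dtype=float)
            ref = f"{cov.name}_{cov.reference}"
            if ref in dummies:
                dummies = dummies.drop(columns=ref)
            cols.extend(dummies[c] for c in dummies.columns)
    return pd.concat(cols, axis=1)


def _wald_result(
    term: str, beta: float, se: float, n: int, scale: str, df: float | None = None
) -> ModelResult:
    if df is None:
        crit = stats.norm.ppf(0.975)
        p = 2 * stats.norm.sf(abs(beta) / se) if se > 0 else (1.0 if beta == 0 else 0.0)
    else:
        crit = stats.t.ppf(0.975, df)
        p = 2 * stats.t.sf(abs(beta) / se, df) if se > 0 else 1.0
    lo, hi = beta - crit * se, beta + crit * se
    if scale == "odds-ratio":
        return ModelResult(term, float(np.exp(beta)), float(np.exp(lo)),
                           float(np.exp(hi)), float(max(p, np.finfo(float).tiny)),
                           n, scale)
    return ModelResult(term, float(beta), float(lo), float(hi),
                       float(max(p, np.finfo(float).tiny)), n, scale)


def _complete_cases(
    data: pd.DataFrame, outcome: str, exposure_cols: Iterable[str],
    covariates: Sequence[Covariate],
) -> pd.DataFrame:
    needed = [outcome, *exposure_cols, *(c.name for c in covariates)]
    return data.dropna(subset=[c for c in needed if c in data.columns])


def fit_linear(
    data: pd.DataFrame,
    outcome: str,
    exposure: str | pd.DataFrame,
    covariates: Sequence[Covariate] = DEFAULT_COVARIATES,
) -> list[ModelResult]:
    """Ordinary least squares of ``outcome`` on exposure term(s) plus
    covariates, on complete cases; Wald 95% CIs for each exposure term."""
    extra = data[[exposure]] if isinstance(exposure, str) else exposure
    df = _complete_cases(data.join(extra[extra.columns.difference(data.columns)]),
                         outcome, extra.columns, covariates)
    X = build_design(df, covariates, extra=df[list(extra.columns)])
    if len(df) < X.shape[1] + 1:
        raise ValueError("too few complete cases for the requested model")
    _check_rank(X)
    res = sm.OLS(df[outcome].astype(float), X).fit()
    return [
        _wald_result(c, res.params[c], res.bse[c], int(res.nobs), "identity")
        for c in extra.columns
    ]


def _fit_logit(y, X):
    """Newton (IRLS-equivalent) logistic fit with a quasi-Newton fallback
    for ill-conditioned designs (e.g. rare outcomes with many parameters)."""
    import warnings as _warnings

    model = sm.Logit(y, X)
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, maxiter=100)
            if res.mle_retvals.get("converged", True):
                return res
        except np.linalg.LinAlgError:
            pass
        return model.fit(disp=0, method="bfgs", maxiter=500)


def fit_logistic(
    data: pd.DataFrame,
    outcome: str,
    exposure: str | pd.DataFrame,
    covariates: Sequence[Covariate] = DEFAULT_COVARIATES,
) -> list[ModelResult]:
    """Maximum-likelihood logistic regression; estimates reported as
    odds ratios with Wald 95% CIs.  ``outcome`` must be a 0/1 column."""
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    extra = data[[exposure]] if isinstance(exposure, str) else exposure
    df = _complete_cases(data.join(extra[extra.columns.difference(data.columns)]),
                         outcome, extra.columns, covariates)
    y = df[outcome].astype(float)
    if y.nunique() < 2:
        raise ValueError("both outcome classes must be present")
    X = build_design(df, covariates, extra=df[list(extra.columns)])
    _check_rank(X)
    try:
        res = _fit_logit(y, X)
    except PerfectSeparationError as err:  # pragma: no cover - data dependent
        raise ValueError(f"perfect separation detected: {err}") from err
    return [
        _wald_result(c, res.params[c], res.bse[c], int(res.nobs), "odds-ratio")
        for c in extra.columns
    ]


# ---------------------------------------------------------------------------
# step 1: categorical analysis
# ---------------------------------------------------------------------------

def _glaucoma_frame(data: pd.DataFrame) -> pd.DataFrame:
    """Rows eligible for the glaucoma model, with a 0/1 ``glaucoma`` column."""
    df = data[data["glaucoma_status"].isin(["case", "control"])].copy()
    df["glaucoma"] = (df["glaucoma_status"] == "case").astype(float)
    return df


def categorical_analysis(
    data: pd.DataFrame,
    reference: str = "infrequent",
    outcomes: Sequence[str] = ALL_OUTCOMES,
    covariates: Sequence[Covariate] = DEFAULT_COVARIATES,
    pool_never_infrequent: bool = False,
) -> dict[str, list[ModelResult]]:
    """Contrasts of each drinker category against the reference category.

    With ``pool_never_infrequent`` the never and infrequent categories are
    merged into a single reference.  The reference itself is reported as a
    zero contrast (OR 1 for glaucoma).
    """
    data = data.copy()
    if pool_never_infrequent:
        data["category"] = data["category"].replace(
            {"never": "never+infrequent", "infrequent": "never+infrequent"}
        )
        reference = "never+infrequent"
    if (data["category"] == reference).sum() == 0:
        raise ValueError(f"empty reference category {reference!r}")
    levels = [c for c in ("never", "never+infrequent", "infrequent", "regular",
                          "former") if (data["category"] == c).any()]
    if len(levels) < 2:
        raise ValueError("need at least 2 populated categories")
    out: dict[str, list[ModelResult]] = {}
    for outcome in outcomes:
        if outcome == "glaucoma":
            df = _glaucoma_frame(data)
            fitter, scale = fit_logistic, "odds-ratio"
        else:
            df = data
            fitter, scale = fit_linear, "identity"
        dummies = pd.get_dummies(df["category"], prefix="category", dtype=float)
        dummies = dummies.drop(columns=f"category_{reference}")
        results = fitter(df, outcome, dummies, covariates)
        ref_est = 1.0 if scale == "odds-ratio" else 0.0
        results.insert(
            0,
            ModelResult(f"category_{reference}", ref_est, ref_est, ref_est, 1.0,
                        results[0].n, scale),
        )
        out[outcome] = results
    return out


# ---------------------------------------------------------------------------
# step 2: dose-response among regular drinkers
# ---------------------------------------------------------------------------

def _regular_subset(data: pd.DataFrame) -> pd.DataFrame:
    return data[(data["category"] == "regular") & data["included_after_trim"]]


def per_sd_analysis(
    data: pd.DataFrame,
    outcome: str,
    covariates: Sequence[Covariate] = DEFAULT_COVARIATES,
) -> ModelResult:
    """Per-SD-of-intake association among trimmed regular drinkers."""
    df = _regular_subset(data)
    if outcome == "glaucoma":
        df = _glaucoma_frame(df)
        return fit_logistic(df, "glaucoma", "standardized_intake", covariates)[0]
    return fit_linear(df, outcome, "standardized_intake", covariates)[0]


def assign_quintiles(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Quintile labels (1..5) and cut points for an intake vector.

    Cut points are the interpolated 20/40/60/80th percentiles; intervals
    are lower-closed and ties at a cut point go to the lower quintile.
    """
    v = np.asarray(values, dtype=float)
    if np.unique(v[~np.isnan(v)]).size < 5:
        raise ValueError("too few distinct values to form quintiles")
    cuts = np.percentile(v[~np.isnan(v)], [20, 40, 60, 80])
    labels = np.searchsorted(cuts, v, side="left") + 1
    return labels, cuts


@dataclass
class QuintileResults:
    results: list[ModelResult]  # Q1 (reference) .. Q5
    medians: np.ndarray  # median g/week within each quintile
    trend_p: float
    n: int


def quintile_analysis(
    data: pd.DataFrame,
    outcome: str,
    covariates: Sequence[Covariate] = DEFAULT_COVARIATES,
) -> QuintileResults:
    """Quintile contrasts (Q2-Q5 vs Q1) and a median-based trend test.

    The trend p-value comes from refitting the model with each
    participant assigned their quintile's median intake as a continuous
    term, testing that term with a Wald test.
    """
    df = _regular_subset(data)
    if outcome == "glaucoma":
        df = _glaucoma_frame(df)
        ycol, fitter = "glaucoma", fit_logistic
    else:
        ycol, fitter = outcome, fit_linear
    df = df.dropna(subset=[ycol, "grams_per_week"])
    labels, _ = assign_quintiles(df["grams_per_week"].to_numpy())
    df = df.assign(_quintile=labels)
    medians = np.array(
        [df.loc[df["_quintile"] == q, "grams_per_week"].median() for q in range(1, 6)]
    )
    dummies = pd.get_dummies(df["_quintile"], prefix="quintile", dtype=float).drop(
        columns="quintile_1"
    )
    results = fitter(df, ycol, dummies, covariates)
    ref = 1.0 if outcome == "glaucoma" else 0.0
    results.insert(0, ModelResult("quintile_1", ref, ref, ref, 1.0, results[0].n,
                                  results[0].scale))
    trend_term = pd.DataFrame(
        {"quintile_median_intake": medians[df["_quintile"].to_numpy() - 1]},
        index=df.index,
    )
    trend_res = fitter(df, ycol, trend_term, covariates)[0]
    return QuintileResults(results, medians, trend_res.p, results[1].n)


# ---------------------------------------------------------------------------
# restricted cubic splines
# ---------------------------------------------------------------------------

#: Harrell's fixed heuristic knot percentiles by number of knots
HARRELL_PERCENTILES: dict[int, tuple[float, ...]] = {
    3: (10, 50, 90),
    4: (5, 35, 65, 95),
    5: (5, 27.5, 50, 72.5, 95),
    6: (5, 23, 41, 59, 77, 95),
    7: (2.5, 18.33, 34.17, 50, 65.83, 81.67, 97.5),
}


def harrell_knots(x: np.ndarray, n_knots: int) -> np.ndarray:
    """Knot locations at Harrell's heuristic percentiles of ``x``."""
    if n_knots not in HARRELL_PERCENTILES:
        raise ValueError("number of knots must be between 3 and 7")
    return np.percentile(np.asarray(x, float), HARRELL_PERCENTILES[n_knots])


def rcs_basis(x: np.ndarray, knots: Sequence[float]) -> np.ndarray:
    """Restricted-cubic-spline basis (truncated-power parameterisation).

    Returns a matrix with a linear column plus ``k - 2`` nonlinear
    columns; the represented function is linear beyond the boundary
    knots, with continuous first and second derivatives everywhere.
    Nonlinear terms are scaled by the squared boundary-knot span for
    numerical balance.
    """
    t = np.asarray(knots, dtype=float)
    if t.ndim != 1 or t.size < 3:
        raise ValueError("need at least 3 knots")
    if np.any(np.diff(t) <= 0):
        raise ValueError("knots must be strictly increasing")
    x = np.asarray(x, dtype=float)
    k = t.size
    span2 = (t[-1] - t[0]) ** 2

    def cube(u):
        return np.clip(u, 0.0, None) ** 3

    cols = [x]
    for j in range(k - 2):
        term = (
            cube(x - t[j])
            - cube(x - t[k - 2]) * (t[-1] - t[j]) / (t[-1] - t[k - 2])
            + cube(x - t[-1]) * (t[k - 2] - t[j]) / (t[-1] - t[k - 2])
        )
        cols.append(term / span2)
    return np.column_stack(cols)


@dataclass
class SplineFit:
    """Selected restricted-cubic-spline dose-response model."""

    n_knots: int
    knot_positions: np.ndarray  # on the log-intake scale
    coefficients: np.ndarray  # spline-term coefficients (linear first)
    coefficient_cov: np.ndarray  # covariance of the spline-term coefficients
    aic: float
    aic_table: dict[int, float]
    curve: pd.DataFrame  # grams, units_uk, estimate, ci_low, ci_high
    scale: str  # "identity" | "log-odds"


def fit_rcs(
    data: pd.DataFrame,
    outcome: str,
    k_range: Sequence[int] = (3, 4, 5, 6, 7),
    covariates: Sequence[Covariate] = DEFAULT_COVARIATES,
    grid_points: int = 100,
    reference_grams: float | None = None,
) -> SplineFit:
    """Fit restricted cubic splines of outcome on log intake, choosing the
    number of knots (3-7, Harrell percentiles) by minimum AIC.

    The returned curve gives the adjusted outcome difference relative to
    ``reference_grams`` (default: median intake) over an intake grid,
    with pointwise Wald 95% bands; for glaucoma the curve is on the
    log-odds scale.
    """
    if any(k not in HARRELL_PERCENTILES for k in k_range):
        raise ValueError("knot counts must lie in 3..7")
    df = _regular_subset(data)
    df = df[df["grams_per_week"] > 0]
    if outcome == "glaucoma":
        df = _glaucoma_frame(df)
        ycol, scale = "glaucoma", "log-odds"
    else:
        ycol, scale = outcome, "identity"
    df = df.dropna(subset=[ycol, "grams_per_week",
                           *(c.name for c in covariates)])
    logx = np.log(df["grams_per_week"].to_numpy())

    best = None
    aic_table: dict[int, float] = {}
    for k in k_range:
        knots = harrell_knots(logx, k)
        basis = rcs_basis(logx, knots)
        names = ["rcs_linear"] + [f"rcs_nl{j}" for j in range(1, k - 1)]
        extra = pd.DataFrame(basis, columns=names, index=df.index)
        X = build_design(df, covariates, extra=extra)
        _check_rank(X)
        if scale == "identity":
            res = sm.OLS(df[ycol].astype(float), X).fit()
        else:
            res = _fit_logit(df[ycol].astype(float), X)
        aic_table[k] = float(res.aic)
        if best is None or res.aic < best[0]:
            best = (float(res.aic), k, knots, res, names)

    aic, k, knots, res, names = best
    grid = np.linspace(
        np.percentile(df["grams_per_week"], 1),
        np.percentile(df["grams_per_week"], 99),
        grid_points,
    )
    ref = float(np.median(df["grams_per_week"])) if reference_grams is None else reference_grams
    bg = rcs_basis(np.log(grid), knots)
    br = rcs_basis(np.log([ref]), knots)
    contrast = bg - br  # spline columns only; covariates cancel
    beta = res.params[names].to_numpy()
    cov_b = res.cov_params().loc[names, names].to_numpy()
    est = contrast @ beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", contrast, cov_b, contrast))
    from .exposure import grams_to_units

    curve = pd.DataFrame(
        {
            "grams": grid,
            "units_uk": grams_to_units(grid, "UK"),
            "estimate": est,
            "ci_low": est - 1.96 * se,
            "ci_high": est + 1.96 * se,
        }
    )
    return SplineFit(k, knots, beta, cov_b, aic, aic_table, curve, scale)


# ---------------------------------------------------------------------------
# sensitivity analyses
# ---------------------------------------------------------------------------

SENSITIVITY_VARIANTS = (
    "sex-stratified",
    "subgroup",
    "alternative-outcome",
    "beverage-type",
    "extra-covariates",
    "exclude-glaucoma",
)


def _interaction_p(
    data: pd.DataFrame, outcome: str, modifier: pd.Series,
    covariates: Sequence[Covariate],
) -> float:
    """Wald p of an intake x modifier product term in the per-SD model."""
    df = _regular_subset(data)
    if outcome == "glaucoma":
        df = _glaucoma_frame(df)
        ycol, fitter = "glaucoma", fit_logistic
    else:
        ycol, fitter = outcome, fit_linear
    mod = modifier.loc[df.index].astype(float)
    extra = pd.DataFrame(
        {
            "standardized_intake": df["standardized_intake"],
            "modifier": mod,
            "intake_x_modifier": df["standardized_intake"] * mod,
        },
        index=df.index,
    )
    res = fitter(df, ycol, extra, covariates)
    return res[2].p


def run_sensitivity(
    data: pd.DataFrame,
    variant: str,
    outcome: str,
    covariates: Sequence[Covariate] = DEFAULT_COVARIATES,
    **kwargs,
):
    """Re-run the per-SD primary analysis under a named sensitivity variant.

    Variants: ``sex-stratified`` (per-stratum fits + interaction p),
    ``subgroup`` (boolean ``mask=``), ``alternative-outcome``
    (``status_col=`` alternative glaucoma status column),
    ``beverage-type`` (per-beverage intake terms), ``extra-covariates``
    (``extra=`` list of continuous covariate names), and
    ``exclude-glaucoma`` (drop ascertained cases from a continuous-outcome
    analysis).
    """
    if variant not in SENSITIVITY_VARIANTS:
        raise ValueError(f"unknown sensitivity variant {variant!r}")

    if variant == "sex-stratified":
        strata = {
            sex: per_sd_analysis(
                data[data["sex"] == sex],
                outcome,
                [c for c in covariates if c.name != "sex"],
            )
            for sex in ("women", "men")
        }
        modifier = (data["sex"] == "men").astype(float)
        # the modifier main effect replaces the sex covariate in the
        # interaction model (otherwise the design is collinear)
        strata["interaction_p"] = _interaction_p(
            data, outcome, modifier, [c for c in covariates if c.name != "sex"]
        )
        return strata

    if variant == "subgroup":
        return per_sd_analysis(data[kwargs["mask"]], outcome, covariates)

    if variant == "alternative-outcome":
        df = data.copy()
        df["glaucoma_status"] = df[kwargs["status_col"]]
        return per_sd_analysis(df, "glaucoma", covariates)

    if variant == "beverage-type":
        from .exposure import BEVERAGES, K_MONTHLY, default_beverage_table

        table = kwargs.get("beverage_table") or default_beverage_table()
        df = _regular_subset(data).copy()
        k = np.where(df["reporting_period"] == "weekly", 1.0, K_MONTHLY)
        out = {}
        for bev in BEVERAGES:
            grams = df[f"portions_{bev}"].to_numpy(float) * table.grams_per_portion(bev) * k
            sd = grams.std()
            if sd == 0:
                continue
            term = pd.DataFrame({f"{bev}_per_sd": (grams - grams.mean()) / sd},
                                index=df.index)
            if outcome == "glaucoma":
                out[bev] = fit_logistic(_glaucoma_frame(df), "glaucoma", term,
                                        covariates)[0]
            else:
                out[bev] = fit_linear(df, outcome, term, covariates)[0]
        return out

    if variant == "extra-covariates":
        extra = [Covariate(name, "continuous") for name in kwargs["extra"]]
        return per_sd_analysis(data, outcome, list(covariates) + extra)

    # exclude-glaucoma
    if outcome == "glaucoma":
        raise ValueError("exclude-glaucoma applies to continuous outcomes only")
    return per_sd_analysis(data[data["glaucoma_status"] != "case"], outcome,
                           covariates)
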