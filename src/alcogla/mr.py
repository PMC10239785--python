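"""Two-sample Mendelian randomization.

Instrument construction, allele harmonisation, and the estimator battery
for summary-level MR with per-SNP exposure betas ``bx`` (SE ``sx``) and
outcome betas ``by`` (SE ``sy``):

* Wald ratio — single-SNP estimate ``by/bx`` with a first-order (or
  optional second-order) delta-method SE;
* IVW — weighted regression of ``by`` on ``bx`` through the origin with
  weights ``1/sy^2``; fixed-effect or multiplicative random-effects
  (SE inflated by sqrt(max(1, Q/(n-1)))); Cochran's Q and I² attached;
* MR-Egger — the same regression with an intercept after orienting all
  ``bx`` positive; the intercept tests average directional pleiotropy;
  the I²GX regression-dilution statistic quantifies exposure-beta
  measurement error;
* weighted median — the 50% point of the inverse-variance-weighted
  empirical quantile function of the Wald ratios (breakdown 50%);
* weighted mode — argmax of a normal-kernel-smoothed weighted density of
  the ratios (zero modal pleiotropy assumption);
* MR-PRESSO — residual-sum-of-squares global heterogeneity test against
  parametric simulation, per-SNP outlier flagging with Bonferroni
  correction, an outlier-corrected IVW and a distortion test;
* multivariable MR — joint weighted regression on two exposure-beta
  columns (e.g. adjusting an alcohol instrument for genetically proxied
  smoking initiation).

All estimators are invariant to SNP ordering and to joint sign flips of
``(bx, by)`` for any SNP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MREstimate",
    "harmonize",
    "build_instrument",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "weighted_mode",
    "mr_presso",
    "multivariable_mr",
    "run_mr_battery",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class MREstimate:
    """One MR estimate with its diagnostics.

    ``diagnostics`` may carry, depending on the method: Q, Q_p, I2,
    egger_intercept, intercept_se, intercept_p, I2GX, outlier_ids,
    global_p, distortion_p, n_dropped.
    """

    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n_snps: int
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("confidence bounds must bracket the estimate")


def _normal_est(method, est, se, n, df=None, **diag) -> MREstimate:
    if df is None:
        crit = stats.norm.ppf(0.975)
        p = 2 * stats.norm.sf(abs(est) / se) if se > 0 else 0.0
    else:
        crit = stats.t.ppf(0.975, df)
        p = 2 * stats.t.sf(abs(est) / se, df) if se > 0 else 0.0
    return MREstimate(method, float(est), float(se), float(est - crit * se),
                      float(est + crit * se), float(p), int(n), dict(diag))


# ---------------------------------------------------------------------------
# plumbing
# ---------------------------------------------------------------------------

def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT.get(ea.upper()) == oa.upper()


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    exposure2: pd.DataFrame | None = None,
    drop_palindromic: bool = True,
) -> pd.DataFrame:
    """Inner-join exposure and outcome summary tables on variant id and
    align outcome effects to the exposure's effect allele.

    Input tables use the columns ``snp_id, effect_allele, other_allele,
    beta, se, pval, n``.  Where the outcome reports the swapped allele
    pair the outcome beta's sign is flipped; strand-ambiguous (A/T, C/G)
    variants are dropped when ``drop_palindromic`` (their count is in the
    result's ``attrs["n_palindromic_dropped"]``).  Row order follows
    sorted variant id, so the result is independent of input order.
    """
    ex = exposure.set_index("snp_id")
    out = outcome.set_index("snp_id")
    shared = ex.index.intersection(out.index)
    if shared.empty:
        raise ValueError("no overlapping variants between studies")
    shared = shared.sort_values()
    ex, out = ex.loc[shared], out.loc[shared]

    same = (ex["effect_allele"].to_numpy() == out["effect_allele"].to_numpy()) & (
        ex["other_allele"].to_numpy() == out["other_allele"].to_numpy()
    )
    swapped = (ex["effect_allele"].to_numpy() == out["other_allele"].to_numpy()) & (
        ex["other_allele"].to_numpy() == out["effect_allele"].to_numpy()
    )
    palindromic = np.array(
        [_is_palindromic(a, b) for a, b in zip(ex["effect_allele"], ex["other_allele"])]
    )
    keep = (same | swapped) & (~palindromic if drop_palindromic else True)

    hz = pd.DataFrame(
        {
            "snp_id": shared,
            "effect_allele": ex["effect_allele"].to_numpy(),
            "other_allele": ex["other_allele"].to_numpy(),
            "beta_exposure": ex["beta"].to_numpy(dtype=float),
            "se_exposure": ex["se"].to_numpy(dtype=float),
            "pval_exposure": ex["pval"].to_numpy(dtype=float),
            "beta_outcome": np.where(swapped, -out["beta"].to_numpy(dtype=float),
                                     out["beta"].to_numpy(dtype=float)),
            "se_outcome": out["se"].to_numpy(dtype=float),
        }
    )[keep].reset_index(drop=True)
    if exposure2 is not None:
        e2 = exposure2.set_index("snp_id")
        hz["beta_exposure2"] = e2.loc[hz["snp_id"], "beta"].to_numpy(dtype=float)
        hz["se_exposure2"] = e2.loc[hz["snp_id"], "se"].to_numpy(dtype=float)
    if (hz["se_exposure"] <= 0).any() or (hz["se_outcome"] <= 0).any():
        raise ValueError("standard errors must be positive")
    hz.attrs["n_palindromic_dropped"] = int(palindromic.sum()) if drop_palindromic else 0
    return hz


def build_instrument(
    stats_df: pd.DataFrame,
    p_threshold: float = 5e-8,
    exclude_ids: tuple = (),
) -> pd.DataFrame:
    """Select instrument variants by exposure p-value and an exclusion list.

    With an empty exclusion list this is the full instrument; excluding a
    flagged variant (e.g. the ADH1B locus) gives the restricted
    instrument, differing only by that variant's contribution.
    """
    keep = (stats_df["pval_exposure"] <= p_threshold) & ~stats_df["snp_id"].isin(
        exclude_ids
    )
    inst = stats_df[keep].reset_index(drop=True)
    if inst.empty:
        raise ValueError("instrument is empty after filtering")
    return inst


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def wald_ratio(
    beta_exposure: float,
    se_exposure: float,
    beta_outcome: float,
    se_outcome: float,
    second_order: bool = False,
) -> tuple[float, float]:
    """Single-SNP causal estimate ``by/bx`` with a delta-method SE.

    First order: ``sy/|bx|``.  Second order adds the exposure-beta
    uncertainty term ``by^2 sx^2 / bx^4``.
    """
    if beta_exposure == 0:
        raise ZeroDivisionError("zero exposure beta")
    est = beta_outcome / beta_exposure
    var = se_outcome**2 / beta_exposure**2
    if second_order:
        var += beta_outcome**2 * se_exposure**2 / beta_exposure**4
    return float(est), float(np.sqrt(var))


def _ratios_and_weights(df: pd.DataFrame, second_order: bool = False):
    bx = df["beta_exposure"].to_numpy(dtype=float)
    by = df["beta_outcome"].to_numpy(dtype=float)
    sx = df["se_exposure"].to_numpy(dtype=float)
    sy = df["se_outcome"].to_numpy(dtype=float)
    if np.any(bx == 0):
        raise ZeroDivisionError("zero exposure beta in instrument")
    ratios = by / bx
    var = sy**2 / bx**2
    if second_order:
        var += by**2 * sx**2 / bx**4
    return ratios, 1.0 / var


def ivw(df: pd.DataFrame, variance_model: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance weighted estimate.

    Weighted regression of outcome betas on exposure betas through the
    origin with weights ``1/sy^2``.  Under the multiplicative
    random-effects model (default) the SE is inflated by
    ``sqrt(max(1, Q/(n-1)))``; Cochran's Q, its p-value and I² are
    attached.  With a single variant this reduces to the Wald ratio.
    """
    if variance_model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown variance model {variance_model!r}")
    n = len(df)
    if n < 1:
        raise ValueError("empty instrument")
    bx = df["beta_exposure"].to_numpy(dtype=float)
    by = df["beta_outcome"].to_numpy(dtype=float)
    w = 1.0 / df["se_outcome"].to_numpy(dtype=float) ** 2
    if n == 1:
        est, se = wald_ratio(bx[0], df["se_exposure"].iloc[0], by[0],
                             df["se_outcome"].iloc[0])
        return _normal_est("wald_ratio", est, se, 1, note="single-variant fallback")
    s2 = np.sum(w * bx**2)
    est = np.sum(w * bx * by) / s2
    se = 1.0 / np.sqrt(s2)
    q = float(np.sum(w * (by - est * bx) ** 2))
    q_p = float(stats.chi2.sf(q, n - 1))
    i2 = float(max(0.0, (q - (n - 1)) / q)) if q > 0 else 0.0
    if variance_model == "multiplicative_random":
        se *= np.sqrt(max(1.0, q / (n - 1)))
    return _normal_est(f"ivw_{variance_model}", est, se, n, Q=q, Q_p=q_p, I2=i2)


def _orient_positive(df: pd.DataFrame) -> pd.DataFrame:
    """Flip each SNP so the exposure beta is positive (joint sign flip)."""
    sign = np.sign(df["beta_exposure"].to_numpy(dtype=float))
    sign[sign == 0] = 1.0
    out = df.copy()
    out["beta_exposure"] = df["beta_exposure"] * sign
    out["beta_outcome"] = df["beta_outcome"] * sign
    return out


def egger(df: pd.DataFrame) -> MREstimate:
    """MR-Egger regression: weighted regression of ``by`` on ``bx`` with an
    intercept, weights ``1/sy^2``, after orienting all exposure betas
    positive.

    The slope is the causal estimate (valid under InSIDE); the intercept
    and its p-value test average directional pleiotropy.  Inference uses
    t(n-2) quantiles with multiplicative overdispersion; the I²GX
    statistic ``(Q_GX - (n-1)) / Q_GX`` quantifies regression dilution
    from exposure-beta measurement error.
    """
    n = len(df)
    if n < 3:
        raise ValueError("MR-Egger needs at least 3 variants")
    df = _orient_positive(df)
    bx = df["beta_exposure"].to_numpy(dtype=float)
    by = df["beta_outcome"].to_numpy(dtype=float)
    sx = df["se_exposure"].to_numpy(dtype=float)
    w = 1.0 / df["se_outcome"].to_numpy(dtype=float) ** 2

    X = np.column_stack([np.ones(n), bx])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = by - X @ coef
    q = float(np.sum(w * resid**2))
    # standard WLS overdispersion (unfloored), t(n-2) inference
    phi = q / (n - 2)
    cov = phi * np.linalg.inv(xtwx)
    se_int, se_slope = np.sqrt(np.diag(cov))

    # regression-dilution I²GX on the oriented exposure betas
    wx = 1.0 / sx**2
    bx_bar = np.sum(wx * bx) / np.sum(wx)
    q_gx = float(np.sum((bx - bx_bar) ** 2 / sx**2))
    i2gx = max(0.0, (q_gx - (n - 1)) / q_gx) if q_gx > 0 else 0.0

    intercept_p = float(2 * stats.t.sf(abs(coef[0]) / se_int, n - 2))
    return _normal_est(
        "egger", coef[1], se_slope, n, df=n - 2,
        egger_intercept=float(coef[0]), intercept_se=float(se_int),
        intercept_p=intercept_p, Q=q,
        Q_p=float(stats.chi2.sf(q, n - 2)), I2GX=float(i2gx),
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """The 50% point of the weighted empirical quantile function.

    Cumulative standardized weights s_j = (cumsum(w)_j - w_j/2) / sum(w)
    over ratio-sorted variants, linearly interpolated at 0.5.
    """
    order = np.argsort(ratios)
    r, w = ratios[order], weights[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, s, r))


def _parametric_boot(df: pd.DataFrame, point_fn, n_boot: int, seed: int) -> float:
    """Bootstrap SE: resample betas from their reported SEs, re-estimate."""
    rng = np.random.default_rng(seed)
    bx = df["beta_exposure"].to_numpy(dtype=float)
    by = df["beta_outcome"].to_numpy(dtype=float)
    sx = df["se_exposure"].to_numpy(dtype=float)
    sy = df["se_outcome"].to_numpy(dtype=float)
    n = len(df)
    ests = np.empty(n_boot)
    for b in range(n_boot):
        bxb = bx + rng.normal(0, sx)
        byb = by + rng.normal(0, sy)
        ests[b] = point_fn(byb / bxb, bxb**2 / sy**2)
    return float(ests.std(ddof=1))


def weighted_median(df: pd.DataFrame, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted-median estimator (consistent while valid variants carry
    more than half the weight); SE from a parametric bootstrap."""
    n = len(df)
    if n < 3:
        raise ValueError("weighted median needs at least 3 variants")
    ratios, w = _ratios_and_weights(df)
    est = _weighted_median_point(ratios, w)
    se = _parametric_boot(df, _weighted_median_point, n_boot, seed)
    return _normal_est("weighted_median", est, se, n)


def _mode_bandwidth(ratios: np.ndarray, phi: float) -> float:
    n = len(ratios)
    mad = np.median(np.abs(ratios - np.median(ratios))) / 0.6745
    sd = ratios.std(ddof=1)
    scale = min(sd, mad) if mad > 0 else sd
    if scale == 0:
        return 0.0
    return phi * 0.9 * scale * n ** (-1 / 5)


def _mode_grid(ratios: np.ndarray, h: float, n_grid: int = 512) -> np.ndarray:
    return np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, n_grid)


def _weighted_mode_point(ratios: np.ndarray, weights: np.ndarray,
                         phi: float = 1.0, n_grid: int = 512) -> float:
    h = _mode_bandwidth(ratios, phi)
    if h == 0:  # all ratios identical
        return float(ratios[0])
    grid = _mode_grid(ratios, h, n_grid)
    dens = np.sum(
        weights[:, None] * np.exp(-0.5 * ((grid[None, :] - ratios[:, None]) / h) ** 2),
        axis=0,
    )
    return float(grid[np.argmax(dens)])


def weighted_mode(
    df: pd.DataFrame, phi: float = 1.0, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted-mode estimator: argmax of a normal-kernel weighted density
    of Wald ratios with a modified-Silverman (MAD-based) bandwidth scaled
    by ``phi``, evaluated on a 512-point grid spanning the ratios plus
    three bandwidths; SE from a parametric bootstrap."""
    if phi <= 0:
        raise ValueError("bandwidth factor must be positive")
    n = len(df)
    if n < 3:
        raise ValueError("weighted mode needs at least 3 variants")
    ratios, w = _ratios_and_weights(df)
    est = _weighted_mode_point(ratios, w, phi)
    se = _parametric_boot(
        df, lambda r, ww: _weighted_mode_point(r, ww, phi), n_boot, seed
    )
    return _normal_est("weighted_mode", est, se, n)


# ---------------------------------------------------------------------------
# MR-PRESSO
# ---------------------------------------------------------------------------

def _loo_ivw_preds(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effect IVW slope for each variant, vectorised."""
    s1, s2 = np.sum(w * bx * by), np.sum(w * bx**2)
    return (s1 - w * bx * by) / (s2 - w * bx**2)


def mr_presso(
    df: pd.DataFrame,
    n_sim: int = 1000,
    seed: int = 0,
    significance: float = 0.05,
) -> MREstimate:
    """MR-PRESSO: global pleiotropy test, outlier detection and a
    corrected estimate.

    The observed residual sum of squares (each variant's outcome beta
    against its leave-one-out IVW prediction, weighted by ``1/sy^2``) is
    compared against ``n_sim`` parametric simulations under the
    no-pleiotropy model to give the global p (exceedance fraction with
    the +1 correction).  Per-variant observed residuals are compared to
    their simulated distributions, Bonferroni-corrected, to flag
    outliers; the corrected estimate is the IVW on the retained variants,
    and the distortion p compares the observed correction against
    corrections from removing random variant subsets of the same size.
    Per the usual reporting convention, no corrected estimate is returned
    when no outliers are detected.
    """
    n = len(df)
    if n < 4:
        raise ValueError("MR-PRESSO needs at least 4 variants")
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100")
    rng = np.random.default_rng(seed)
    bx = df["beta_exposure"].to_numpy(dtype=float)
    by = df["beta_outcome"].to_numpy(dtype=float)
    sx = df["se_exposure"].to_numpy(dtype=float)
    sy = df["se_outcome"].to_numpy(dtype=float)
    w = 1.0 / sy**2

    theta_loo = _loo_ivw_preds(bx, by, w)
    obs_resid = w * (by - theta_loo * bx) ** 2
    rss_obs = float(np.sum(obs_resid))

    # parametric simulations under the no-pleiotropy model
    bx_sim = bx[None, :] + rng.normal(0, sx, (n_sim, n))
    by_sim = theta_loo[None, :] * bx[None, :] + rng.normal(0, sy, (n_sim, n))
    s1 = np.sum(w * bx_sim * by_sim, axis=1, keepdims=True)
    s2 = np.sum(w * bx_sim**2, axis=1, keepdims=True)
    theta_loo_sim = (s1 - w * bx_sim * by_sim) / (s2 - w * bx_sim**2)
    sim_resid = w * (by_sim - theta_loo_sim * bx_sim) ** 2
    rss_sim = np.sum(sim_resid, axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (1 + n_sim))
    # per-SNP test uses the plain exceedance fraction so that a residual
    # beyond every simulated value can clear the Bonferroni threshold
    outlier_p = np.mean(sim_resid >= obs_resid[None, :], axis=0)
    outliers = np.where(outlier_p * n < significance)[0]
    outlier_ids = list(df["snp_id"].iloc[outliers]) if "snp_id" in df else list(outliers)

    base = ivw(df, "multiplicative_random")
    if outliers.size == 0:
        return MREstimate(
            "mr_presso", base.estimate, base.se, base.ci_low, base.ci_high,
            base.p, n,
            {"global_p": global_p, "outlier_ids": [], "distortion_p": np.nan,
             "corrected": False, **base.diagnostics},
        )

    keep = np.ones(n, dtype=bool)
    keep[outliers] = False
    corrected = ivw(df[keep], "multiplicative_random")
    distortion_obs = corrected.estimate - base.estimate
    # null distribution: remove random subsets of the same size
    n_draw = min(n_sim, 500)
    rand_est = np.empty(n_draw)
    for b in range(n_draw):
        drop = rng.choice(n, size=outliers.size, replace=False)
        mask = np.ones(n, dtype=bool)
        mask[drop] = False
        rand_est[b] = ivw(df[mask], "fixed").estimate
    rand_dist = rand_est - base.estimate
    distortion_p = float(
        (1 + np.sum(np.abs(rand_dist) >= abs(distortion_obs))) / (1 + n_draw)
    )
    return MREstimate(
        "mr_presso", corrected.estimate, corrected.se, corrected.ci_low,
        corrected.ci_high, corrected.p, int(keep.sum()),
        {"global_p": global_p, "outlier_ids": outlier_ids,
         "distortion_p": distortion_p, "corrected": True,
         **corrected.diagnostics},
    )


def multivariable_mr(df: pd.DataFrame) -> MREstimate:
    """Multivariable MR: weighted regression of outcome betas jointly on
    both exposure-beta columns, no intercept, weights ``1/sy^2``;
    reports the primary-exposure coefficient with a multiplicative
    overdispersion-inflated SE."""
    if "beta_exposure2" not in df:
        raise ValueError("second exposure betas required for multivariable MR")
    n = len(df)
    if n < 3:
        raise ValueError("multivariable MR needs at least 3 variants")
    X = df[["beta_exposure", "beta_exposure2"]].to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < 2:
        raise ValueError("collinear exposure-beta columns")
    by = df["beta_outcome"].to_numpy(dtype=float)
    w = 1.0 / df["se_outcome"].to_numpy(dtype=float) ** 2
    xtwx = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(xtwx, X.T @ (w * by))
    resid = by - X @ coef
    q = float(np.sum(w * resid**2))
    phi = max(1.0, q / (n - 2))
    cov = phi * np.linalg.inv(xtwx)
    return _normal_est("multivariable_mr", coef[0], np.sqrt(cov[0, 0]), n,
                       Q=q, coefficient_exposure2=float(coef[1]))


def run_mr_battery(
    df: pd.DataFrame,
    methods: tuple = ("ivw", "median", "mode", "egger", "presso"),
    seed: int = 0,
    variance_model: str = "multiplicative_random",
    n_boot: int = 1000,
    n_sim: int = 1000,
) -> list[MREstimate]:
    """Run the requested estimators on one harmonised instrument."""
    out = []
    for m in methods:
        if m == "ivw":
            out.append(ivw(df, variance_model))
        elif m == "median":
            out.append(weighted_median(df, n_boot, seed))
        elif m == "mode":
            out.append(weighted_mode(df, 1.0, n_boot, seed))
        elif m == "egger":
            out.append(egger(df))
        elif m == "presso":
            out.append(mr_presso(df, n_sim, seed))
        elif m == "mvmr":
            out.append(multivariable_mr(df))
        else:
            raise ValueError(f"unknown MR method {m!r}")
    return out
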