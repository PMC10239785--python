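"""Polygenic score construction and gene-environment interaction.

The glaucoma polygenic risk score (PRS) is a standard weighted sum of
risk-allele dosages, sum_i beta_i x dosage_i, standardised to mean 0 and
SD 1 within the scoring cohort.  Interaction with alcohol intake is
tested by adding a multiplicative intake x PRS product term (continuous
PRS) to the maximally adjusted regression model; per-PRS-quintile per-SD
intake effects are reported descriptively.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .association import (
    Covariate,
    DEFAULT_COVARIATES,
    ModelResult,
    _glaucoma_frame,
    _regular_subset,
    fit_linear,
    fit_logistic,
)

__all__ = ["PRSVector", "compute_prs", "InteractionResult", "interaction_analysis"]


@dataclass
class PRSVector:
    """Per-participant polygenic score: raw, standardised, and quintile."""

    raw: pd.Series
    standardized: pd.Series
    quintile: pd.Series

    def __post_init__(self) -> None:
        z = self.standardized.to_numpy()
        if abs(z.mean()) > 1e-10 or abs(z.std() - 1.0) > 1e-10:
            raise ValueError("standardized score must have mean 0, SD 1")


def compute_prs(
    dosages: pd.DataFrame,
    variant_info: pd.DataFrame,
    weights: pd.DataFrame,
    mean_impute: bool = True,
) -> PRSVector:
    """Weighted-sum PRS over a participants x variants dosage matrix.

    ``variant_info`` states which allele each dosage column counts; where
    it differs from the weight file's effect allele the dosage is flipped
    to ``2 - d``.  Missing dosages are mean-imputed per variant by
    default (a stand-in for imputed genotypes).  Raises on unmatched
    variant ids, duplicate weight ids, or a constant raw score
    (standardisation undefined).
    """
    w = weights.set_index("snp_id")
    if w.index.duplicated().any():
        raise ValueError("duplicate variant ids in weight file")
    info = variant_info.set_index("snp_id")
    missing = [s for s in w.index if s not in dosages.columns or s not in info.index]
    if missing:
        raise ValueError(f"unmatched variant ids: {missing[:5]}")

    d = dosages[list(w.index)].to_numpy(dtype=float)
    if np.nanmin(d, initial=0.0) < 0 or np.nanmax(d, initial=0.0) > 2:
        raise ValueError("dosages must lie in [0, 2]")
    if np.isnan(d).any():
        if not mean_impute:
            raise ValueError("missing dosages present and mean_impute=False")
        col_mean = np.nanmean(d, axis=0)
        d = np.where(np.isnan(d), col_mean[None, :], d)

    flip = (
        info.loc[w.index, "counted_allele"].to_numpy()
        != w["effect_allele"].to_numpy()
    )
    d = np.where(flip[None, :], 2.0 - d, d)
    raw = d @ w["weight"].to_numpy(dtype=float)
    sd = raw.std()
    if sd == 0:
        raise ValueError("degenerate score: raw PRS is constant")
    z = (raw - raw.mean()) / sd
    # exact re-centring guards against floating-point drift at large n
    z = (z - z.mean()) / z.std()
    cuts = np.percentile(z, [20, 40, 60, 80])
    quintile = np.searchsorted(cuts, z, side="left") + 1
    idx = dosages.index
    return PRSVector(
        pd.Series(raw, index=idx, name="prs_raw"),
        pd.Series(z, index=idx, name="prs"),
        pd.Series(quintile, index=idx, name="prs_quintile"),
    )


@dataclass
class InteractionResult:
    """Multiplicative interaction test plus quintile-stratified effects."""

    interaction: ModelResult  # the intake x PRS product term
    main_effect: ModelResult  # per-SD intake main effect
    quintile_effects: list[ModelResult] | None  # per-SD effect in PRS Q1..Q5


def interaction_analysis(
    data: pd.DataFrame,
    outcome: str,
    prs_col: str = "prs",
    covariates: Sequence[Covariate] = DEFAULT_COVARIATES,
    quintile_effects: bool = True,
) -> InteractionResult:
    """Test modification of the intake association by the PRS.

    Fits the maximally adjusted model with intake, PRS and their product
    (continuous PRS) among trimmed regular drinkers; the product term's
    Wald p is the headline interaction test.  PRS quintiles are computed
    on the analysis subset actually modelled, and the per-SD intake
    effect is refit within each quintile (descriptive forest-plot layout).
    """
    df = _regular_subset(data)
    if outcome == "glaucoma":
        df = _glaucoma_frame(df)
        ycol, fitter = "glaucoma", fit_logistic
    else:
        ycol, fitter = outcome, fit_linear
    df = df.dropna(subset=[ycol, "standardized_intake", prs_col,
                           *(c.name for c in covariates)])

    extra = pd.DataFrame(
        {
            "standardized_intake": df["standardized_intake"],
            "prs_main": df[prs_col].astype(float),
            "intake_x_prs": df["standardized_intake"] * df[prs_col].astype(float),
        },
        index=df.index,
    )
    res = fitter(df, ycol, extra, covariates)
    main, interaction = res[0], res[2]

    quintiles = None
    if quintile_effects:
        cuts = np.percentile(df[prs_col].to_numpy(float), [20, 40, 60, 80])
        q = np.searchsorted(cuts, df[prs_col].to_numpy(float), side="left") + 1
        quintiles = []
        for qq in range(1, 6):
            sub = df[q == qq]
            r = fitter(sub, ycol, "standardized_intake", covariates)[0]
            quintiles.append(
                ModelResult(f"prs_q{qq}", r.estimate, r.ci_low, r.ci_high, r.p,
                            r.n, r.scale)
            )
    return InteractionResult(interaction, main, quintiles)
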