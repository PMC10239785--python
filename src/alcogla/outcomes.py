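"""Glaucoma-related phenotype derivation.

Turns raw per-eye measurements, treatment flags and diagnosis records into
analysis-ready phenotypes:

* corneal-compensated IOP — mean of available eyes, pretreatment value
  imputed for participants on ocular hypotensives by dividing the measured
  pressure by 0.7, participants with relevant ocular surgical history set
  to missing, extreme tails removed at the population level;
* OCT inner-retinal thicknesses (mRNFL, mGCIPL) — mean of available eyes;
* prevalent glaucoma status — self-report or qualifying ICD code within a
  window ending one year after baseline, with suspect-code and treated
  controls and young-onset cases excluded.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exposure import trim_percentiles

__all__ = [
    "IOP_TREATMENT_DIVISOR",
    "participant_iop",
    "derive_iop",
    "derive_oct",
    "is_glaucoma_code",
    "is_suspect_code",
    "ascertain_glaucoma",
    "ascertain_glaucoma_table",
]

#: measured-on-treatment IOP is divided by this to impute the pretreatment value
IOP_TREATMENT_DIVISOR = 0.7

#: default diagnosis window: any time before baseline up to 1 year after,
#: with "up to 1 year" read inclusively as <= 365 days
DIAGNOSIS_WINDOW_DAYS = 365

#: cases diagnosed before this age are excluded (likely non-adult-onset)
MIN_DIAGNOSIS_AGE = 30


def _mean_of_eyes(right: float, left: float) -> float:
    vals = [v for v in (right, left) if v is not None and not np.isnan(v)]
    if not vals:
        return np.nan
    return float(np.mean(vals))


def participant_iop(
    right: float,
    left: float,
    treated: bool = False,
    excluded: bool = False,
) -> float:
    """Single-participant IOP: mean of available eyes, /0.7 if treated.

    Returns NaN when both eyes are missing or any exclusion flag
    (glaucoma surgery/laser, corneal graft, refractive surgery,
    significant trauma) is set.  Population-level trimming is applied
    separately in :func:`derive_iop`.
    """
    for v in (right, left):
        if v is not None and not np.isnan(v) and v < 0:
            raise ValueError("negative IOP measurement")
    if excluded:
        return np.nan
    iop = _mean_of_eyes(right, left)
    if treated and not np.isnan(iop):
        iop /= IOP_TREATMENT_DIVISOR
    return iop


def derive_iop(
    measures: pd.DataFrame,
    treated: pd.Series,
    excluded: pd.Series,
    trim: tuple[float, float] = (0.5, 0.5),
) -> pd.Series:
    """Cohort-level IOP with population trimming.

    ``measures`` carries ``iop_right``/``iop_left`` columns (mmHg, NaN for
    a missing eye).  After the per-participant rule of
    :func:`participant_iop`, values in the extreme ``trim`` percentiles of
    the derived distribution are set to missing.
    """
    r = measures["iop_right"].to_numpy(dtype=float)
    l = measures["iop_left"].to_numpy(dtype=float)
    if np.nanmin(np.concatenate([r, l]), initial=0.0) < 0:
        raise ValueError("negative IOP measurement")
    with warnings.catch_warnings():
        # both-eyes-missing rows legitimately yield NaN
        warnings.simplefilter("ignore", category=RuntimeWarning)
        iop = np.nanmean(np.column_stack([r, l]), axis=1)
    iop = np.where(treated.to_numpy(dtype=bool), iop / IOP_TREATMENT_DIVISOR, iop)
    iop = np.where(excluded.to_numpy(dtype=bool), np.nan, iop)
    if trim != (0.0, 0.0) and np.any(~np.isnan(iop)):
        keep = trim_percentiles(iop, *trim)
        iop = np.where(keep, iop, np.nan)
    return pd.Series(iop, index=measures.index, name="iop")


def derive_oct(measures: pd.DataFrame) -> pd.DataFrame:
    """Mean-of-available-eyes mRNFL and mGCIPL thicknesses (μm).

    Expects ``mrnfl_right``/``mrnfl_left``/``mgcipl_right``/``mgcipl_left``
    columns; a participant with no available eye for a layer gets NaN for
    that layer.
    """
    out = {}
    for layer in ("mrnfl", "mgcipl"):
        r = measures[f"{layer}_right"].to_numpy(dtype=float)
        l = measures[f"{layer}_left"].to_numpy(dtype=float)
        if np.nanmin(np.concatenate([r, l]), initial=0.0) < 0:
            raise ValueError(f"negative {layer} thickness")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            out[layer] = np.nanmean(np.column_stack([r, l]), axis=1)
    return pd.DataFrame(out, index=measures.index)


# ---------------------------------------------------------------------------
# glaucoma ascertainment
# ---------------------------------------------------------------------------

def _normalize_code(code: str) -> str:
    code = str(code).strip().upper()
    if not code:
        raise ValueError("empty ICD code")
    return code


def is_glaucoma_code(code: str) -> bool:
    """Qualifying glaucoma code: ICD-10 H40.* except H40.0, any H42.*;
    ICD-9 365.* except 365.0.  Matching is prefix-based on normalised
    codes with dots retained."""
    c = _normalize_code(code)
    if c.startswith("H42"):
        return True
    if c.startswith("H40"):
        return not c.startswith("H40.0")
    if c.startswith("365"):
        return not c.startswith("365.0")
    return False


def is_suspect_code(code: str) -> bool:
    """Glaucoma-suspect code (ICD-10 H40.0, ICD-9 365.0)."""
    c = _normalize_code(code)
    return c.startswith("H40.0") or c.startswith("365.0")


def ascertain_glaucoma(
    self_report: bool,
    records: Iterable[tuple[str, int, float]],
    on_ocular_hypotensives: bool = False,
    window_days: int = DIAGNOSIS_WINDOW_DAYS,
    min_age: float = MIN_DIAGNOSIS_AGE,
) -> str:
    """Classify one participant as ``"case"``, ``"control"`` or ``"excluded"``.

    ``records`` is an iterable of ``(code, days_from_baseline,
    age_at_diagnosis)`` tuples (age may be NaN).  A participant is a case
    on self-reported glaucoma or glaucoma surgery, or on any qualifying
    code dated no later than ``window_days`` after baseline.  Cases whose
    earliest qualifying diagnosis age is below ``min_age`` are excluded.
    Controls on ocular hypotensive medication or carrying a suspect code
    are excluded.  The result does not depend on record order.
    """
    case = bool(self_report)
    suspect = False
    min_dx_age = np.inf
    for code, day, age in records:
        code = _normalize_code(code)
        if is_glaucoma_code(code) and day <= window_days:
            case = True
            if age is not None and not np.isnan(age):
                min_dx_age = min(min_dx_age, age)
        elif is_suspect_code(code):
            suspect = True
    if case:
        if min_dx_age < min_age:
            return "excluded"
        return "case"
    if on_ocular_hypotensives or suspect:
        return "excluded"
    return "control"


def ascertain_glaucoma_table(
    participants: pd.DataFrame,
    diagnoses: pd.DataFrame,
    window_days: int = DIAGNOSIS_WINDOW_DAYS,
    min_age: float = MIN_DIAGNOSIS_AGE,
) -> pd.Series:
    """Vectorised ascertainment over a cohort.

    ``participants`` must carry ``self_report_glaucoma`` and
    ``on_ocular_hypotensives`` columns indexed by participant id;
    ``diagnoses`` is long-format with ``participant_id``, ``code``,
    ``days_from_baseline`` and ``age_at_diagnosis`` columns.
    """
    status = pd.Series("control", index=participants.index, dtype=object)
    dx = diagnoses.copy()
    dx["code"] = dx["code"].map(_normalize_code)
    qual = dx["code"].map(is_glaucoma_code) & (
        dx["days_from_baseline"] <= window_days
    )
    susp = dx["code"].map(is_suspect_code)

    case_ids = set(dx.loc[qual, "participant_id"])
    case = participants["self_report_glaucoma"].astype(bool) | participants.index.isin(
        case_ids
    )

    young = dx.loc[qual & (dx["age_at_diagnosis"] < min_age), "participant_id"]
    young_ids = participants.index.isin(set(young))

    suspect_ids = participants.index.isin(set(dx.loc[susp, "participant_id"]))
    treated = participants["on_ocular_hypotensives"].astype(bool).to_numpy()

    status[case.to_numpy()] = "case"
    status[case.to_numpy() & young_ids] = "excluded"
    ctrl = ~case.to_numpy()
    status[ctrl & (treated | suspect_ids)] = "excluded"
    return status.rename("glaucoma_status")
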