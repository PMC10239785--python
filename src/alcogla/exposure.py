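"""Alcohol-exposure derivation.

Converts touchscreen-questionnaire drinking responses into drinker
categories and grams of ethanol per week, applies percentile trimming,
and converts between grams, UK/US units, and guideline thresholds.

A participant reports a drinking frequency (one of six printed options)
and, if they drink at least on special occasions, per-beverage portion
counts for six beverage types.  Reporters at frequency "1-2 times a week"
or more give weekly counts; less frequent drinkers give monthly counts,
which are rescaled to a weekly equivalent with the conversion factor
k = 12 months x 7 days / 365 days (printed as 0.23).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FREQUENCIES",
    "WEEKLY_FREQUENCIES",
    "MONTHLY_FREQUENCIES",
    "BEVERAGES",
    "K_MONTHLY",
    "ETHANOL_DENSITY_G_PER_ML",
    "BeverageTable",
    "default_beverage_table",
    "classify_drinker",
    "classify_drinkers",
    "quantify_weekly_grams",
    "quantify_cohort_grams",
    "trim_percentiles",
    "standardize_intake",
    "derive_exposure",
    "guideline_grams",
    "grams_to_units",
]

# The six printed frequency responses, most to least frequent.
FREQ_DAILY = "Daily/almost daily"
FREQ_3_4_WEEK = "3-4 times a week"
FREQ_1_2_WEEK = "1-2 times a week"
FREQ_1_3_MONTH = "1-3 times a month"
FREQ_SPECIAL = "Special occasions only"
FREQ_NEVER = "Never"

FREQUENCIES = (
    FREQ_DAILY,
    FREQ_3_4_WEEK,
    FREQ_1_2_WEEK,
    FREQ_1_3_MONTH,
    FREQ_SPECIAL,
    FREQ_NEVER,
)

#: frequencies at which weekly portion counts are collected (k = 1)
WEEKLY_FREQUENCIES = frozenset({FREQ_DAILY, FREQ_3_4_WEEK, FREQ_1_2_WEEK})
#: frequencies at which monthly portion counts are collected (k = 12*7/365)
MONTHLY_FREQUENCIES = frozenset({FREQ_1_3_MONTH, FREQ_SPECIAL})

#: monthly-to-weekly conversion factor, kept at full precision internally;
#: the commonly printed value 0.23 is this number rounded.
K_MONTHLY = 12.0 * 7.0 / 365.0

#: density of ethanol at room temperature, g/mL
ETHANOL_DENSITY_G_PER_ML = 0.789

#: the six questionnaire beverage types, in questionnaire order
BEVERAGES = (
    "red_wine",
    "white_wine",
    "beer_cider",
    "spirits",
    "fortified_wine",
    "other",
)

CATEGORIES = ("never", "infrequent", "regular", "former")


@dataclass(frozen=True)
class BeverageTable:
    """Portion sizes and alcohol concentrations for the six beverage types.

    ``portion_ml`` maps beverage -> typical portion volume in mL and
    ``abv_percent`` maps beverage -> alcohol by volume (%).  The ethanol
    concentration in g/mL is ABV/100 x 0.789 (ethanol density).
    """

    portion_ml: Mapping[str, float]
    abv_percent: Mapping[str, float]

    def __post_init__(self) -> None:
        for bev in BEVERAGES:
            if bev not in self.portion_ml or bev not in self.abv_percent:
                raise ValueError(f"beverage table missing entry for {bev!r}")
            if self.portion_ml[bev] <= 0:
                raise ValueError(f"non-positive portion volume for {bev!r}")
            conc = self.abv_percent[bev] / 100.0 * ETHANOL_DENSITY_G_PER_ML
            if not (0 < conc <= ETHANOL_DENSITY_G_PER_ML):
                raise ValueError(f"alcohol concentration out of range for {bev!r}")

    def concentration_g_per_ml(self, beverage: str) -> float:
        return self.abv_percent[beverage] / 100.0 * ETHANOL_DENSITY_G_PER_ML

    def grams_per_portion(self, beverage: str) -> float:
        """Grams of ethanol in one portion of ``beverage``."""
        return self.portion_ml[beverage] * self.concentration_g_per_ml(beverage)

    def grams_per_portion_vector(self) -> np.ndarray:
        return np.array([self.grams_per_portion(b) for b in BEVERAGES])

    @classmethod
    def from_file(cls, path) -> "BeverageTable":
        """Read a 3-column delimited file (beverage, portion_ml, abv_percent)."""
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
        df.columns = [c.strip().lower() for c in df.columns]
        return cls(
            portion_ml=dict(zip(df["beverage"], df["portion_ml"].astype(float))),
            abv_percent=dict(zip(df["beverage"], df["abv_percent"].astype(float))),
        )

    def to_file(self, path) -> None:
        pd.DataFrame(
            {
                "beverage": list(BEVERAGES),
                "portion_ml": [self.portion_ml[b] for b in BEVERAGES],
                "abv_percent": [self.abv_percent[b] for b in BEVERAGES],
            }
        ).to_csv(path, sep="\t", index=False)


def default_beverage_table() -> BeverageTable:
    """UK-typical portion sizes and strengths.

    These are documented stand-ins for food-composition-table values
    (175 mL glass of wine at 12% ABV, 568 mL pint of beer/cider at 4%,
    25 mL spirit measure at 40%, 50 mL fortified wine at 17.5%, 250 mL
    "other" at 4%); fully replaceable via :meth:`BeverageTable.from_file`.
    """
    return BeverageTable(
        portion_ml={
            "red_wine": 175.0,
            "white_wine": 175.0,
            "beer_cider": 568.0,
            "spirits": 25.0,
            "fortified_wine": 50.0,
            "other": 250.0,
        },
        abv_percent={
            "red_wine": 12.0,
            "white_wine": 12.0,
            "beer_cider": 4.0,
            "spirits": 40.0,
            "fortified_wine": 17.5,
            "other": 4.0,
        },
    )


# ---------------------------------------------------------------------------
# drinker categorisation
# ---------------------------------------------------------------------------

def classify_drinker(frequency: str, ever_drank: bool | None = None) -> str | None:
    """Map a frequency response (plus ever-drank for "Never") to a category.

    * "Never" + ever_drank False -> ``"never"``
    * "Never" + ever_drank True  -> ``"former"``
    * "Special occasions only"   -> ``"infrequent"``
    * "1-3 times a month" or more often -> ``"regular"``

    Returns ``None`` (an explicit missing-category signal) when frequency
    is "Never" but ever_drank is unavailable.
    """
    if frequency not in FREQUENCIES:
        raise ValueError(f"unknown drinking frequency {frequency!r}")
    if frequency == FREQ_NEVER:
        if ever_drank is None or (isinstance(ever_drank, float) and np.isnan(ever_drank)):
            return None
        return "former" if ever_drank else "never"
    if frequency == FREQ_SPECIAL:
        return "infrequent"
    return "regular"


def classify_drinkers(frequency: pd.Series, ever_drank: pd.Series) -> pd.Series:
    """Vectorised :func:`classify_drinker`; missing categories become NaN."""
    bad = ~frequency.isin(FREQUENCIES)
    if bad.any():
        raise ValueError(
            f"unknown drinking frequency values: {sorted(frequency[bad].unique())}"
        )
    out = pd.Series("regular", index=frequency.index, dtype=object)
    out[frequency == FREQ_SPECIAL] = "infrequent"
    never = frequency == FREQ_NEVER
    out[never] = np.where(
        ever_drank[never].isna(),
        None,
        np.where(ever_drank[never].astype("boolean").fillna(False), "former", "never"),
    )
    return out


# ---------------------------------------------------------------------------
# quantification
# ---------------------------------------------------------------------------

def _k_factor(reporting_period: str) -> float:
    if reporting_period == "weekly":
        return 1.0
    if reporting_period == "monthly":
        return K_MONTHLY
    raise ValueError(f"unknown reporting period {reporting_period!r}")


def quantify_weekly_grams(
    portions: Mapping[str, float] | Sequence[float],
    reporting_period: str,
    table: BeverageTable | None = None,
) -> float:
    """Total ethanol intake in grams per week for one participant.

    Sum over the six beverage types of
    ``portions_i x portion_volume_i (mL) x concentration_i (g/mL) x k``
    with k = 1 for weekly reporters and k = 12*7/365 for monthly reporters.
    """
    if table is None:
        table = default_beverage_table()
    if isinstance(portions, Mapping):
        counts = np.array([float(portions.get(b, 0.0)) for b in BEVERAGES])
    else:
        counts = np.asarray(portions, dtype=float)
        if counts.shape != (len(BEVERAGES),):
            raise ValueError(f"expected {len(BEVERAGES)} portion counts")
    if np.any(counts < 0):
        raise ValueError("portion counts must be non-negative")
    k = _k_factor(reporting_period)
    return float(np.dot(counts, table.grams_per_portion_vector()) * k)


def quantify_cohort_grams(
    questionnaire: pd.DataFrame, table: BeverageTable | None = None
) -> pd.Series:
    """Vectorised grams/week over a questionnaire table.

    Expects columns ``portions_<beverage>`` for the six beverages and a
    ``reporting_period`` column; rows whose category implies no
    quantification (never/former drinkers) get NaN.
    """
    if table is None:
        table = default_beverage_table()
    gpp = table.grams_per_portion_vector()
    cols = [f"portions_{b}" for b in BEVERAGES]
    counts = questionnaire[cols].to_numpy(dtype=float)
    if np.nanmin(counts, initial=0.0) < 0:
        raise ValueError("portion counts must be non-negative")
    k = np.where(
        questionnaire["reporting_period"].to_numpy() == "weekly", 1.0, K_MONTHLY
    )
    grams = counts @ gpp * k
    cat = classify_drinkers(questionnaire["frequency"], questionnaire["ever_drank"])
    grams = pd.Series(grams, index=questionnaire.index, name="grams_per_week")
    grams[~cat.isin(["infrequent", "regular"])] = np.nan
    return grams


# ---------------------------------------------------------------------------
# trimming and standardisation
# ---------------------------------------------------------------------------

def trim_percentiles(
    values: np.ndarray | pd.Series, lower_pct: float = 1.0, upper_pct: float = 1.0
) -> np.ndarray:
    """Inclusion mask excluding the extreme tails of ``values``.

    Values strictly below the ``lower_pct``-th percentile or strictly above
    the ``(100 - upper_pct)``-th percentile are excluded.  Percentiles use
    linear interpolation between closest ranks; ties at either threshold
    are retained (exclusion is strict).  NaNs are never included.
    """
    if not (0 <= lower_pct < 50 and 0 <= upper_pct < 50):
        raise ValueError("trim percentages must lie in [0, 50)")
    v = np.asarray(values, dtype=float)
    if v.size == 0 or np.all(np.isnan(v)):
        raise ValueError("cannot trim an all-missing vector")
    lo = np.nanpercentile(v, lower_pct)
    hi = np.nanpercentile(v, 100.0 - upper_pct)
    with np.errstate(invalid="ignore"):
        return (v >= lo) & (v <= hi)


def standardize_intake(
    grams: pd.Series | np.ndarray, include: np.ndarray | None = None
) -> pd.Series | np.ndarray:
    """Standardise intake to mean 0, SD 1 over the included subset.

    The mean and (population) SD are computed over ``include`` (default:
    all non-missing values); the affine transform is then applied to every
    value, so excluded rows still carry a z-score on the common scale.
    """
    v = np.asarray(grams, dtype=float)
    if include is None:
        include = ~np.isnan(v)
    sel = v[np.asarray(include, dtype=bool)]
    sel = sel[~np.isnan(sel)]
    if sel.size < 2:
        raise ValueError("need at least 2 included values to standardise")
    mu, sd = sel.mean(), sel.std()
    if sd == 0:
        raise ValueError("intake is constant on the included subset")
    z = (v - mu) / sd
    if isinstance(grams, pd.Series):
        return pd.Series(z, index=grams.index, name="standardized_intake")
    return z


def derive_exposure(
    questionnaire: pd.DataFrame,
    table: BeverageTable | None = None,
    trim: tuple[float, float] = (1.0, 1.0),
) -> pd.DataFrame:
    """Full exposure derivation for a questionnaire table.

    Returns a frame indexed like the input with columns ``category``,
    ``grams_per_week`` (NaN for never/former drinkers),
    ``included_after_trim`` (True only for regular drinkers inside the
    trim bounds) and ``standardized_intake`` (z-scored over the included
    regular drinkers; NaN for non-regular rows).
    """
    category = classify_drinkers(
        questionnaire["frequency"], questionnaire["ever_drank"]
    )
    grams = quantify_cohort_grams(questionnaire, table)
    regular = (category == "regular").to_numpy()
    include = np.zeros(len(questionnaire), dtype=bool)
    reg_grams = grams.to_numpy()[regular]
    include[regular] = trim_percentiles(reg_grams, *trim)
    z = np.full(len(questionnaire), np.nan)
    z_all = standardize_intake(grams.to_numpy(), include)
    z[regular] = z_all[regular]
    return pd.DataFrame(
        {
            "category": category,
            "grams_per_week": grams,
            "included_after_trim": include,
            "standardized_intake": z,
        },
        index=questionnaire.index,
    )


# ---------------------------------------------------------------------------
# units and guidelines
# ---------------------------------------------------------------------------

#: grams of ethanol per UK unit and per US standard drink
UNIT_GRAMS = {"UK": 8.0, "US": 14.0}

#: guideline ceilings in units/drinks per week
_GUIDELINE_UNITS = {
    ("UK", "women"): 14.0,
    ("UK", "men"): 14.0,
    ("US", "women"): 7.0,
    ("US", "men"): 14.0,
}


def guideline_grams(jurisdiction: str, sex: str) -> float:
    """Weekly drinking-guideline ceiling in grams of ethanol.

    UK: 14 units/week for both sexes at 8 g/unit (112 g/week).
    US: 7 (women) or 14 (men) standard drinks/week at 14 g/drink
    (98 and 196 g/week).
    """
    key = (jurisdiction.upper(), sex.lower())
    if key not in _GUIDELINE_UNITS:
        raise ValueError(f"unknown jurisdiction/sex {key}")
    return _GUIDELINE_UNITS[key] * UNIT_GRAMS[key[0]]


def grams_to_units(grams: float | np.ndarray, system: str) -> float | np.ndarray:
    """Convert grams/week to UK units (8 g) or US standard drinks (14 g)."""
    system = system.upper()
    if system not in UNIT_GRAMS:
        raise ValueError(f"unknown unit system {system!r}")
    g = np.asarray(grams, dtype=float)
    if np.any(g < 0):
        raise ValueError("grams must be non-negative")
    out = g / UNIT_GRAMS[system]
    return float(out) if np.isscalar(grams) else out
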