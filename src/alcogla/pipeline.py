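"""End-to-end orchestration: simulate -> derive -> associate -> gxe -> mr.

The pipeline's central object is the *analysis table*: one row per
participant with drinker category, grams/week, trim inclusion,
standardized intake, the thirteen adjustment covariates, the PRS, and
the derived phenotypes (IOP, mRNFL, mGCIPL, glaucoma status).  Stages
read and write tab-delimited files with a comment header carrying the
configuration hash, and a JSON manifest records seeds, versions and
row counts in/out of every stage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (
    categorical_analysis,
    fit_rcs,
    per_sd_analysis,
    quintile_analysis,
)
from .exposure import BeverageTable, default_beverage_table, derive_exposure
from .gxe import interaction_analysis
from .mr import build_instrument, harmonize, run_mr_battery
from .outcomes import ascertain_glaucoma_table, derive_iop, derive_oct
from .synthetic import (
    CohortConfig,
    SimulatedCohort,
    SummaryConfig,
    generate_cohort,
    generate_summary_stats,
)

__all__ = [
    "build_analysis_table",
    "RunConfig",
    "run_pipeline",
    "write_table",
    "read_table",
    "results_frame",
]

IOP_EXCLUSION_FLAGS = (
    "glaucoma_surgery",
    "corneal_graft",
    "refractive_surgery",
    "eye_trauma",
)


def build_analysis_table(
    cohort: SimulatedCohort | tuple[pd.DataFrame, pd.DataFrame],
    beverage_table: BeverageTable | None = None,
    intake_trim: tuple[float, float] = (1.0, 1.0),
    iop_trim: tuple[float, float] = (0.5, 0.5),
) -> pd.DataFrame:
    """Derive the analysis-ready table from raw participant data.

    Runs the exposure derivation (categories, grams/week, trim,
    standardisation), IOP derivation (mean of eyes, pretreatment
    imputation, surgical exclusions, population trimming), OCT averaging
    and glaucoma ascertainment, and joins everything to the covariates.
    """
    if isinstance(cohort, SimulatedCohort):
        participants, diagnoses = cohort.participants, cohort.diagnoses
    else:
        participants, diagnoses = cohort
    exposure = derive_exposure(participants, beverage_table, intake_trim)
    excluded = participants[list(IOP_EXCLUSION_FLAGS)].any(axis=1)
    iop = derive_iop(
        participants, participants["on_ocular_hypotensives"], excluded, iop_trim
    )
    oct_df = derive_oct(participants)
    status = ascertain_glaucoma_table(participants, diagnoses)

    keep_cols = [
        "age", "sex", "ethnicity", "townsend", "bmi", "height", "sbp",
        "spherical_equivalent", "diabetes", "smoking_status",
        "smoking_intensity", "physical_activity", "season", "prs",
        "reporting_period",
    ] + [c for c in participants.columns if c.startswith("portions_")]
    table = participants[keep_cols].copy()
    table = pd.concat([exposure, table], axis=1)
    table["iop"] = iop
    table["mrnfl"] = oct_df["mrnfl"]
    table["mgcipl"] = oct_df["mgcipl"]
    table["glaucoma_status"] = status
    return table


# ---------------------------------------------------------------------------
# delimited i/o with a provenance header
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path, meta: dict | None = None,
                index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def results_frame(results) -> pd.DataFrame:
    """Tidy frame from ModelResult / MREstimate objects or mappings of them."""
    rows = []

    def add(prefix, r):
        d = asdict(r) if hasattr(r, "__dataclass_fields__") else dict(r)
        d.pop("diagnostics", None)
        rows.append({"analysis": prefix, **d})

    if isinstance(results, dict):
        for key, val in results.items():
            if isinstance(val, list):
                for r in val:
                    add(str(key), r)
            else:
                add(str(key), val)
    elif isinstance(results, list):
        for r in results:
            add("", r)
    else:
        add("", results)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# run configuration and orchestration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Declarative configuration for a full pipeline run."""

    out_dir: str = "alcogla_run"
    seed: int = 0
    n_participants: int = 20_000
    stages: tuple = ("simulate", "derive", "associate", "gxe", "mr")
    outcomes: tuple = ("iop", "mrnfl", "mgcipl", "glaucoma")
    intake_trim: tuple = (1.0, 1.0)
    iop_trim: tuple = (0.5, 0.5)
    knot_range: tuple = (3, 4, 5, 6, 7)
    reference_category: str = "infrequent"
    mr_methods: tuple = ("ivw", "median", "mode", "egger", "presso")
    mr_exclude: tuple = ()
    mr_n_snps: int = 80
    variance_model: str = "multiplicative_random"

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("stages", "outcomes", "intake_trim", "iop_trim",
                    "knot_range", "mr_methods", "mr_exclude"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def digest(self) -> str:
        """Hash of the analytic configuration (output location excluded,
        so identical analyses hash identically wherever they are written)."""
        payload = asdict(self)
        payload.pop("out_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in order and write a report bundle.

    Returns the manifest (also written to ``manifest.json``): package
    version, configuration + hash, seeds, and per-stage row counts.
    Stages are resumable: a stage re-run from persisted intermediates
    with the same configuration is idempotent (byte-identical outputs).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config.digest(), "package_version": __version__}
    manifest: dict = {
        "package_version": __version__,
        "config": asdict(config),
        "config_hash": config.digest(),
        "stages": {},
    }

    cohort = None
    table = None

    if "simulate" in config.stages:
        cc = CohortConfig(n_participants=config.n_participants, seed=config.seed)
        cohort = generate_cohort(cc)
        write_table(cohort.participants, out / "participants.tsv", meta, index=True)
        write_table(cohort.diagnoses, out / "diagnoses.tsv", meta)
        manifest["stages"]["simulate"] = {
            "rows_out": int(len(cohort.participants)),
            "diagnosis_rows": int(len(cohort.diagnoses)),
        }

    if "derive" in config.stages:
        if cohort is None:
            participants = pd.read_csv(out / "participants.tsv", sep="\t",
                                       comment="#", index_col="participant_id")
            # text round-trip leaves nullable booleans as objects/strings
            for col in ("ever_drank", "with_meals"):
                participants[col] = participants[col].map(
                    {True: True, False: False, "True": True, "False": False}
                ).astype("boolean")
            diagnoses = read_table(out / "diagnoses.tsv")
            cohort = (participants, diagnoses)
        table = build_analysis_table(
            cohort, intake_trim=config.intake_trim, iop_trim=config.iop_trim
        )
        write_table(table, out / "analysis_table.tsv", meta, index=True)
        status_counts = table["glaucoma_status"].value_counts().to_dict()
        manifest["stages"]["derive"] = {
            "rows_in": int(len(table)),
            "rows_out": int(len(table)),
            "regular_included": int(
                ((table["category"] == "regular")
                 & table["included_after_trim"]).sum()
            ),
            "iop_missing": int(table["iop"].isna().sum()),
            "glaucoma_status": {k: int(v) for k, v in status_counts.items()},
        }

    if table is None and any(
        s in config.stages for s in ("associate", "gxe")
    ):
        table = pd.read_csv(out / "analysis_table.tsv", sep="\t", comment="#",
                            index_col="participant_id")

    if "associate" in config.stages:
        cat = categorical_analysis(table, config.reference_category,
                                   outcomes=config.outcomes)
        rows = []
        for outcome in config.outcomes:
            rows.append(results_frame({f"categorical_{outcome}": cat[outcome]}))
            rows.append(results_frame(
                {f"per_sd_{outcome}": per_sd_analysis(table, outcome)}
            ))
            q = quintile_analysis(table, outcome)
            qf = results_frame({f"quintile_{outcome}": q.results})
            qf["trend_p"] = q.trend_p
            rows.append(qf)
        assoc = pd.concat(rows, ignore_index=True)
        write_table(assoc, out / "associations.tsv", meta)
        spline_rows = []
        for outcome in config.outcomes:
            fit = fit_rcs(table, outcome, k_range=config.knot_range)
            curve = fit.curve.assign(outcome=outcome, n_knots=fit.n_knots,
                                     aic=fit.aic)
            spline_rows.append(curve)
        write_table(pd.concat(spline_rows, ignore_index=True),
                    out / "spline_curves.tsv", meta)
        manifest["stages"]["associate"] = {
            "rows_in": int(len(table)),
            "result_rows": int(len(assoc)),
        }

    if "gxe" in config.stages:
        res = interaction_analysis(table, "iop")
        gxe_frame = results_frame(
            {"interaction": res.interaction, "main_effect": res.main_effect,
             "quintiles": res.quintile_effects}
        )
        write_table(gxe_frame, out / "gxe.tsv", meta)
        manifest["stages"]["gxe"] = {
            "rows_in": int(len(table)),
            "result_rows": int(len(gxe_frame)),
        }

    if "mr" in config.stages:
        sc = SummaryConfig(n_snps=config.mr_n_snps, seed=config.seed)
        scenario = generate_summary_stats(sc)
        write_table(scenario.exposure, out / "sumstats_exposure.tsv", meta)
        write_table(scenario.outcome, out / "sumstats_outcome.tsv", meta)
        hz = harmonize(scenario.exposure, scenario.outcome)
        inst = build_instrument(hz, p_threshold=1.0,
                                exclude_ids=tuple(config.mr_exclude))
        ests = run_mr_battery(inst, config.mr_methods, seed=config.seed,
                              variance_model=config.variance_model)
        write_table(results_frame(ests), out / "mr_results.tsv", meta)
        manifest["stages"]["mr"] = {
            "n_snps": int(len(inst)),
            "result_rows": len(ests),
        }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
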