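"""Cohort tables, inclusion criteria, and the end-to-end pipeline.

Measurements arrive as a long-format CSV (patient_id, day, sdnam1_pm) and
patient metadata as one row per patient (GVHD status/grade/onset day plus
categorical covariates).  A patient enters the analysis only if the series
has at least 8 observations within 100 days after transplant and at least
one within 7 days — the minimum for identifying the 8-parameter model and
anchoring its early dynamics.

``run_pipeline`` chains every stage: inclusion -> per-patient two-variant
fits and AIC comparison -> binomial preference test -> R_day_n at the
configured horizons -> Welch/Wilcoxon group comparisons, grade-stratified
summaries, ROC per horizon, and covariate Fisher tests; results are emitted
as flat CSVs plus a disposition log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .fitting import (MODEL2, CohortFitResult, FitOptions, PatientSeries,
                      comparisons_to_frame, fit_cohort)
from .stats import (binomial_preference_test, compare_groups, compute_rday,
                    fisher_2x2, half_life, roc_analysis)

logger = logging.getLogger("sdnam1")

__all__ = [
    "CohortMetadata",
    "PipelineConfig",
    "PipelineResult",
    "read_measurements",
    "read_metadata",
    "series_from_frame",
    "write_measurements",
    "inclusion_filter",
    "run_pipeline",
]

MEASUREMENT_COLUMNS = ("patient_id", "day", "sdnam1_pm")


@dataclass(frozen=True)
class CohortMetadata:
    """One patient's clinical metadata row."""

    patient_id: str
    gvhd_status: bool
    gvhd_grade: int
    onset_day: float | None
    covariates: dict

    def __post_init__(self) -> None:
        if self.gvhd_status != (self.gvhd_grade >= 1):
            raise ValueError(
                f"{self.patient_id}: gvhd_grade >= 1 iff gvhd_status positive"
            )
        if self.gvhd_status != (self.onset_day is not None):
            raise ValueError(
                f"{self.patient_id}: onset_day present iff GVHD positive"
            )


@dataclass(frozen=True)
class PipelineConfig:
    horizons: tuple[float, ...] = (20.0, 30.0, 40.0, 50.0)
    fit_options: FitOptions = field(default_factory=FitOptions)
    covariates: tuple[str, ...] = ("tbi", "graft", "donor", "conditioning",
                                   "allele", "prophylaxis")
    output_dir: str | None = None


@dataclass(frozen=True)
class PipelineResult:
    disposition: dict
    fits: CohortFitResult
    fit_table: pd.DataFrame
    preference: object            # BinomialTestResult
    rday_table: pd.DataFrame
    group_comparisons: pd.DataFrame
    grade_summary: pd.DataFrame
    roc_table: pd.DataFrame
    fisher_table: pd.DataFrame
    half_life_mean: float
    half_life_sd: float


def series_from_frame(df: pd.DataFrame) -> list[PatientSeries]:
    """Group a long-format measurement table into day-sorted PatientSeries."""
    series = []
    for pid, grp in df.groupby("patient_id", sort=True):
        grp = grp.sort_values("day")
        series.append(PatientSeries(
            patient_id=str(pid),
            days=grp["day"].to_numpy(float),
            concentrations=grp["sdnam1_pm"].to_numpy(float),
        ))
    return series


def read_measurements(path) -> list[PatientSeries]:
    """Read a long-format measurement CSV into day-sorted per-patient series.

    Duplicate (patient, day) rows are averaged with a logged warning; missing
    columns, non-numeric values and negative concentrations are validation
    errors naming the offending rows.
    """
    df = pd.read_csv(path)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    for col in ("day", "sdnam1_pm"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()] + 2  # 1-based + header
        if len(bad):
            raise ValueError(f"{path}: non-numeric {col} at row(s) {list(bad)}")
        if coerced.isna().any():
            rows = list(df.index[coerced.isna()] + 2)
            raise ValueError(f"{path}: missing {col} at row(s) {rows}")
        df[col] = coerced
    neg = df.index[df["sdnam1_pm"] < 0] + 2
    if len(neg):
        raise ValueError(f"{path}: negative concentration at row(s) {list(neg)}")
    dup = df.duplicated(subset=["patient_id", "day"], keep=False)
    if dup.any():
        logger.warning("%s: averaging %d duplicate (patient, day) rows",
                       path, int(dup.sum()))
        df = (df.groupby(["patient_id", "day"], as_index=False)["sdnam1_pm"]
                .mean())
    return series_from_frame(df)


def write_measurements(series: list[PatientSeries], path) -> None:
    rows = [{"patient_id": s.patient_id, "day": d, "sdnam1_pm": c}
            for s in series for d, c in zip(s.days, s.concentrations)]
    pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS)).to_csv(path, index=False)


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("patient_id", "gvhd_status"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col}")
    df["gvhd_status"] = df["gvhd_status"].astype(int)
    return df


def inclusion_filter(series: PatientSeries) -> tuple[bool, str]:
    """Apply the inclusion rule: >= 8 observations in [0, 100] days and >= 1
    in [0, 7] days after transplant (closed intervals; day 0 counts in both).

    Returns ``(included, reason)``; reason is empty when included.
    """
    d = series.days
    n100 = int(np.sum((d >= 0) & (d <= 100)))
    n7 = int(np.sum((d >= 0) & (d <= 7)))
    if n100 < 8:
        return False, f"fewer than 8 observations in [0,100] (found {n100})"
    if n7 < 1:
        return False, "no observation in [0,7]"
    return True, ""


def run_pipeline(measurements: list[PatientSeries], metadata: pd.DataFrame,
                 config: PipelineConfig | None = None) -> PipelineResult:
    """Run inclusion, fitting, model selection and all cohort statistics.

    Per-patient fit failures are logged and excluded (with counts in the
    disposition); an empty post-inclusion cohort is fatal.
    """
    cfg = config or PipelineConfig()
    meta = metadata.set_index(metadata["patient_id"].astype(str))

    flags = {s.patient_id: inclusion_filter(s) for s in measurements}
    included = [s for s in measurements if flags[s.patient_id][0]]
    excluded = {pid: reason for pid, (ok, reason) in flags.items() if not ok}
    if not included:
        raise ValueError("no patient satisfies the inclusion criteria")

    fits = fit_cohort(included, cfg.fit_options)
    fit_table = comparisons_to_frame(fits.comparisons)
    pref = binomial_preference_test(fits.n_model2_preferred, fits.n_compared)

    # half-life of clearance from each patient's preferred-variant mu
    mus = np.array([
        (c.fit2 if c.preferred == MODEL2 else c.fit1).params.mu
        for c in fits.comparisons
    ])
    hl = np.array([half_life(m) for m in mus])

    rday_rows = []
    for c in fits.comparisons:
        # R_day_n from the AIC-preferred fit: under the two-source model there
        # is no transient compartment and R is exactly 0
        params = (c.fit2 if c.preferred == MODEL2 else c.fit1).params
        row = {"patient_id": c.patient_id, "preferred": c.preferred}
        for h in cfg.horizons:
            rv = compute_rday(params, h, patient_id=c.patient_id)
            row[f"r_day_{int(h)}"] = rv.r_day_n
            row[f"auc_x1_{int(h)}"] = rv.auc_x1
            row[f"auc_x2_{int(h)}"] = rv.auc_x2
        rday_rows.append(row)
    rday = pd.DataFrame(rday_rows)
    rday = rday.merge(
        meta[["gvhd_status"] + [c for c in ("gvhd_grade",) if c in meta.columns]],
        left_on="patient_id", right_index=True, how="left",
    )

    labels = rday["gvhd_status"].astype(bool).to_numpy()
    gc_rows, roc_rows = [], []
    for h in cfg.horizons:
        vals = rday[f"r_day_{int(h)}"].to_numpy()
        gc = compare_groups(vals, labels, horizon=h)
        gc_rows.append(dataclasses.asdict(gc))
        rr = roc_analysis(vals, labels, horizon=h)
        roc_rows.append(dataclasses.asdict(rr))
    group_comparisons = pd.DataFrame(gc_rows)
    roc_table = pd.DataFrame(roc_rows)

    if "gvhd_grade" in rday.columns:
        value_cols = [f"r_day_{int(h)}" for h in cfg.horizons]
        grade_summary = (rday.groupby("gvhd_grade")[value_cols]
                         .agg(["count", "mean", "median", "std"]))
        grade_summary.columns = ["_".join(c) for c in grade_summary.columns]
        grade_summary = grade_summary.reset_index()
    else:
        grade_summary = pd.DataFrame()

    fisher_rows = []
    gv = meta.loc[[c.patient_id for c in fits.comparisons], "gvhd_status"].astype(bool)
    for cov in cfg.covariates:
        if cov not in meta.columns:
            continue
        cv = meta.loc[gv.index, cov]
        levels = sorted(cv.dropna().unique())
        if len(levels) != 2:
            continue
        tab = [[int(np.sum((cv == lv) & (gv == g))) for g in (False, True)]
               for lv in levels]
        fisher_rows.append({"covariate": cov, "level_a": levels[0],
                            "level_b": levels[1], "p_value": fisher_2x2(tab)})
    fisher_table = pd.DataFrame(fisher_rows)

    disposition = {
        "n_input": len(measurements),
        "n_included": len(included),
        "n_excluded": len(excluded),
        "exclusion_reasons": excluded,
        "n_fit_failed": len(fits.failures),
        "fit_failures": fits.failures,
        "n_compared": fits.n_compared,
        "n_model2_preferred": fits.n_model2_preferred,
    }
    result = PipelineResult(
        disposition=disposition, fits=fits, fit_table=fit_table,
        preference=pref, rday_table=rday, group_comparisons=group_comparisons,
        grade_summary=grade_summary, roc_table=roc_table,
        fisher_table=fisher_table,
        half_life_mean=float(hl.mean()), half_life_sd=float(hl.std(ddof=1)),
    )
    if cfg.output_dir is not None:
        _write_outputs(result, cfg)
    return result


def _write_outputs(result: PipelineResult, cfg: PipelineConfig) -> None:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.fit_table.to_csv(out / "fits.csv", index=False)
    result.rday_table.to_csv(out / "rday.csv", index=False)
    result.group_comparisons.to_csv(out / "group_comparisons.csv", index=False)
    result.grade_summary.to_csv(out / "grade_summary.csv", index=False)
    result.roc_table.to_csv(out / "roc.csv", index=False)
    result.fisher_table.to_csv(out / "fisher.csv", index=False)
    log = {
        "package_version": __version__,
        "seed": cfg.fit_options.seed,
        "horizons": list(cfg.horizons),
        "disposition": result.disposition,
        "model2_preference": dataclasses.asdict(result.preference),
        "half_life_mean_days": result.half_life_mean,
        "half_life_sd_days": result.half_life_sd,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
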