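"""End-to-end analysis pipeline.

Fixed stage order: simulate (or load) -> hourly aggregation -> inclusion
filters -> variable screening + PMM imputation -> episode classification
(extended definition, with a standard-only sensitivity rerun) -> Table-1
group comparison -> crude KM / log-rank / Cox (univariate + adjusted) ->
propensity matching + IPW with balance diagnostics and matched KM ->
threshold x duration sensitivity grid. Every stage writes delimited text
into the output directory and is logged with row counts; a JSON manifest
records the config snapshot, seeds, file digests and per-stage counts.
The whole run is a deterministic function of (config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .describe import compare_groups
from .detect import EpisodeRule, classify_cohort, summarize_calls
from .errors import PehrError
from .grid import check_monotonicity, run_grid
from .ingest import (apply_inclusion_filters, hourly_medians, pmm_impute,
                     screen_variables)
from .matching import (estimate_propensity, ipw_weights, matched_km,
                       nn_match, smd_table)
from .simulate import simulate_cohort
from .survival import censor_at_horizon, cox_fit, km_fit, logrank_test, \
    survival_at

log = logging.getLogger(__name__)

_CSV_KW = dict(index=False, float_format="%.10g")

TABLE1_CONTINUOUS = ("age", "weight", "sofa", "map", "temperature", "spo2")
TABLE1_CATEGORICAL = (
    "sex_male", "myocardial_infarction", "congestive_heart_failure",
    "peripheral_vascular_disease", "cerebrovascular_disease", "dementia",
    "chronic_pulmonary_disease", "rheumatic_disease", "peptic_ulcer_disease",
    "liver_disease", "diabetes", "renal_disease", "malignant_cancer",
    "sepsis", "ventilation", "vasopressor", "beta_blocker")


@dataclass
class RunResult:
    """Handle on a finished run: output paths, summary numbers, manifest."""

    outdir: Path
    files: dict[str, str]
    summary: dict
    manifest: dict


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, files: dict, name: str) -> None:
    df.to_csv(path, **_CSV_KW)
    files[name] = str(path)


def run_pipeline(config: PipelineConfig, outdir,
                 vitals: Optional[pd.DataFrame] = None,
                 patients: Optional[pd.DataFrame] = None) -> RunResult:
    """Execute the full analysis; returns paths, summary and manifest.

    When ``vitals``/``patients`` are not supplied, a synthetic cohort is
    generated from ``config.simulation``.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    counts: dict[str, int] = {}
    summary: dict = {}

    # ---------------------------------------------------------- stage 1/2
    if vitals is None or patients is None:
        log.info("simulate: generating synthetic cohort "
                 "(n=%d)", config.simulation.n_patients)
        vitals, patients, truth = simulate_cohort(config.simulation)
        _write(vitals, outdir / "vitals.csv", files, "vitals")
        _write(patients, outdir / "patients.csv", files, "patients")
        _write(truth, outdir / "truth.csv", files, "truth")
    counts["n_input"] = len(patients)
    counts["n_vital_samples"] = len(vitals)

    death_hours = {
        row.subject_id: float(row.death_offset_hours)
        for row in patients.itertuples()
        if "death_offset_hours" in patients.columns
        and pd.notna(row.death_offset_hours)}
    series_map = hourly_medians(vitals, death_hours)
    retained, exclusions = apply_inclusion_filters(
        patients, series_map, config.min_los_hours,
        config.max_missing_fraction)
    _write(exclusions, outdir / "exclusions.csv", files, "exclusions")
    counts["n_retained"] = len(retained)
    counts["n_excluded"] = len(exclusions)
    log.info("ingest: retained %d of %d subjects", len(retained),
             len(patients))
    cohort = patients[patients["subject_id"].isin(retained)] \
        .reset_index(drop=True)
    keep_cols = screen_variables(cohort, config.variable_missing_threshold)
    cohort = cohort[keep_cols]
    cohort = pmm_impute(cohort, k_donors=config.pmm_donors,
                        seed=config.seed + 1)

    # ------------------------------------------------------------ detect
    rule = EpisodeRule(threshold=config.hr_threshold,
                       window_hours=config.window_hours,
                       required_hours=config.required_hours,
                       min_terminal_run=config.min_terminal_run)
    calls = classify_cohort(series_map, cohort, rule, mode="extended")
    _write(calls, outdir / "episode_calls.csv", files, "episode_calls")
    call_counts = summarize_calls(calls)
    counts.update(call_counts)
    cohort = cohort.merge(calls[["subject_id", "exposed"]], on="subject_id")
    cohort["exposed"] = cohort["exposed"].astype(int)
    summary["n_cohort"] = len(cohort)
    summary["n_standard"] = call_counts["n_standard"]
    summary["n_extended"] = call_counts["n_extended"]
    summary["prevalence"] = float(cohort["exposed"].mean())
    log.info("detect: %d standard + %d extended positives (prevalence %.3f)",
             call_counts["n_standard"], call_counts["n_extended"],
             summary["prevalence"])

    # ---------------------------------------------------------- describe
    cont = [v for v in TABLE1_CONTINUOUS if v in cohort.columns]
    cat = [v for v in TABLE1_CATEGORICAL if v in cohort.columns]
    table1 = compare_groups(cohort, "exposed", cont, cat)
    _write(table1, outdir / "table1.csv", files, "table1")

    # ----------------------------------------------------------- survive
    cohort = censor_at_horizon(cohort, config.horizon_days)
    summary["mortality"] = float(cohort["event"].mean())
    fits = km_fit(cohort["time"], cohort["event"].astype(bool),
                  cohort["exposed"])
    km_frames = pd.concat([f.to_frame() for f in fits.values()],
                          ignore_index=True)
    _write(km_frames, outdir / "km_curves.csv", files, "km_curves")
    stat, lr_p = logrank_test(cohort["time"], cohort["event"].astype(bool),
                              cohort["exposed"])
    summary["logrank_p"] = lr_p
    summary["surv90_unexposed"] = survival_at(fits[0], config.horizon_days)
    summary["surv90_exposed"] = survival_at(fits[1], config.horizon_days) \
        if 1 in fits else float("nan")

    uni = cox_fit(cohort, ["exposed"], tie_method=config.tie_method)
    _write(uni.summary(), outdir / "cox_univariate.csv", files,
           "cox_univariate")
    adj = [c for c in config.adjust_covariates if c in cohort.columns]
    multi = cox_fit(cohort, ["exposed", *adj], tie_method=config.tie_method)
    _write(multi.summary(), outdir / "cox_multivariate.csv", files,
           "cox_multivariate")
    summary["hr_univariate"] = uni["exposed"]["hr"]
    summary["hr_adjusted"] = multi["exposed"]["hr"]
    summary["hr_adjusted_ci"] = [multi["exposed"]["ci_low"],
                                 multi["exposed"]["ci_high"]]
    log.info("survive: crude HR %.3f, adjusted HR %.3f (log-rank p %.2g)",
             summary["hr_univariate"], summary["hr_adjusted"], lr_p)

    # ------------------------------------------------- sensitivity rerun
    calls_std = classify_cohort(series_map, cohort, rule,
                                mode="standard_only")
    sens = cohort.drop(columns=["exposed"]).merge(
        calls_std[["subject_id", "exposed"]], on="subject_id")
    sens["exposed"] = sens["exposed"].astype(int)
    sens_fit = cox_fit(sens, ["exposed", *adj], tie_method=config.tie_method)
    _write(sens_fit.summary(), outdir / "sensitivity_cox.csv", files,
           "sensitivity_cox")
    summary["hr_adjusted_standard_only"] = sens_fit["exposed"]["hr"]
    counts["n_standard_only_positive"] = int(sens["exposed"].sum())

    # -------------------------------------------------------------- match
    psm_cov = [c for c in config.psm_covariates if c in cohort.columns]
    ps_data = estimate_propensity(cohort, psm_cov)
    match = nn_match(ps_data, config.caliper_multiplier,
                     seed=config.seed + 2)
    _write(match.pairs, outdir / "psm_pairs.csv", files, "psm_pairs")
    counts["n_matched_pairs"] = match.n_matched
    weights = ipw_weights(ps_data, stabilized=True)
    smd_crude = smd_table(ps_data, psm_cov)
    smd_matched = smd_table(ps_data, psm_cov, pairs=match.pairs)
    smd_weighted = smd_table(ps_data, psm_cov, weights=weights)
    smd = smd_crude.rename(columns={"smd": "crude"})
    smd["matched"] = smd_matched["smd"]
    smd["weighted"] = smd_weighted["smd"]
    match.smd = smd
    _write(smd, outdir / "smd.csv", files, "smd")
    m_fits, m_stat, m_p = matched_km(match, cohort)
    m_frames = pd.concat([f.to_frame() for f in m_fits.values()],
                         ignore_index=True)
    _write(m_frames, outdir / "matched_km.csv", files, "matched_km")
    summary["matched_logrank_p"] = m_p
    summary["matched_surv90_unexposed"] = survival_at(m_fits[0],
                                                      config.horizon_days)
    summary["matched_surv90_exposed"] = survival_at(m_fits[1],
                                                    config.horizon_days)
    summary["max_smd_crude"] = float(smd["crude"].max())
    summary["max_smd_matched"] = float(smd["matched"].max())
    summary["max_smd_weighted"] = float(smd["weighted"].max())
    log.info("match: %d pairs, max SMD crude %.3f -> matched %.3f",
             match.n_matched, summary["max_smd_crude"],
             summary["max_smd_matched"])

    # --------------------------------------------------------------- grid
    grid_df, positives = run_grid(
        series_map, cohort, config.grid_thresholds, config.grid_durations,
        config.grid_covariates, config.min_terminal_run)
    _write(grid_df, outdir / "grid.csv", files, "grid")
    violations = check_monotonicity(positives)
    summary["grid_monotonicity_violations"] = len(violations)
    if len(violations):
        log.warning("grid: %d containment violations!", len(violations))

    # ----------------------------------------------------------- manifest
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "simulation_seed": config.simulation.seed,
        "config": config.to_dict(),
        "stage_counts": counts,
        "summary": summary,
        "files": {name: {"path": p, "sha256": _digest(Path(p))}
                  for name, p in files.items()},
        "generated_at": _time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    files["manifest"] = str(outdir / "manifest.json")
    return RunResult(outdir=outdir, files=files, summary=summary,
                     manifest=manifest)
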