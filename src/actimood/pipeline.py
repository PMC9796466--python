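"""End-to-end pipeline: simulate -> phenotype -> metrics -> compare.

One :class:`~actimood.config.RunConfig` drives a deterministic run that
emits the cohort table, per-participant rest-activity/sleep metrics, a tidy
comparison-results table, a human-readable report and a machine-readable
manifest with the participant accounting at every filtering step.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from datetime import date, datetime
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import generate_actigraphy, generate_cohort
from .config import RunConfig, StatsParams, save_config, _to_dict
from .phenotyping import phenotype_cohort
from .rhythm import compute_rhythm_metrics
from .sleep import categorize_sleep_duration, detect_all_nights, summarise_sleep
from .stats import (
    ComparisonResult,
    ModelSpec,
    apply_fdr,
    condense_categories,
    fisher_level_result,
    fit_group_logistic,
    make_quintiles,
    multinomial_discrepancy,
    sleep_discrepancy,
    sparse_levels,
)

__all__ = [
    "season_of_wear",
    "compute_participant_metrics",
    "compute_cohort_metrics",
    "prepare_analysis_variables",
    "run_comparisons",
    "run_pipeline",
]

log = logging.getLogger(__name__)

SEASONS = {12: "winter", 1: "winter", 2: "winter",
           3: "spring", 4: "spring", 5: "spring",
           6: "summer", 7: "summer", 8: "summer",
           9: "autumn", 10: "autumn", 11: "autumn"}


def season_of_wear(d) -> str:
    """Meteorological season of a date (Dec-Feb winter, Mar-May spring, ...)."""
    if isinstance(d, str):
        d = date.fromisoformat(d)
    if isinstance(d, (pd.Timestamp, datetime)):
        d = d.date()
    return SEASONS[d.month]


def compute_participant_metrics(series, detector_params, stats_params: StatsParams) -> dict:
    """Rhythm + sleep summary metrics for one epoch series."""
    rm = compute_rhythm_metrics(
        series,
        per_day_ra=stats_params.ra_per_day,
        hourly_completeness_min=stats_params.hourly_completeness_min,
        min_day_hours=stats_params.day_completeness_min_h,
    )
    sm = summarise_sleep(detect_all_nights(series, detector_params))
    return {
        "aa": rm.aa, "m10": rm.m10, "l5": rm.l5, "ra": rm.ra,
        "is_": rm.is_, "iv": rm.iv, "n_valid_days": rm.n_valid_days,
        "sleep_duration_h": sm.mean_sleep_duration,
        "sleep_efficiency": sm.mean_sleep_efficiency,
        "sleep_duration_cat": sm.duration_category,
        "n_valid_nights": sm.n_valid_nights,
    }


def compute_cohort_metrics(cohort: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Generate actigraphy for flagged participants and derive their metrics."""
    rows = []
    for row in cohort.itertuples(index=False):
        if not row.has_actigraphy:
            continue
        params = config.cohort.groups[row.group_truth].actigraphy
        series = generate_actigraphy(
            params, int(row.actigraphy_seed), start=f"{row.wear_start_date} 12:00:00"
        )
        m = compute_participant_metrics(series, config.detector, config.stats)
        m["id"] = row.id
        rows.append(m)
    if not rows:
        return pd.DataFrame(columns=["id"])
    return pd.DataFrame(rows)


NEURO_COLS = [f"neuro_{j:02d}" for j in range(1, 13)]


def prepare_analysis_variables(df: pd.DataFrame, stats_params: StatsParams) -> pd.DataFrame:
    """Derive every model-ready exposure column on the analysed sample.

    Quintile boundaries are computed on the pooled analysed sample (the three
    analysis groups together). RA, IS, AA and sleep efficiency are inverted
    before binning so a higher quintile is the more negative outcome; IV is
    not inverted.
    """
    out = df.copy()
    out["neuroticism"] = out[NEURO_COLS].sum(axis=1, skipna=False)
    out["chronotype_cat"] = condense_categories("chronotype", out["chronotype"])
    out["happiness_cat"] = condense_categories("happiness", out["happiness"])
    out["happiness_health_cat"] = condense_categories("happiness", out["happiness_health"])
    out["getting_up_cat"] = condense_categories("getting_up", out["getting_up"])
    out["sleeplessness_score"] = out["sleeplessness"].map(
        {"never_rarely": 1.0, "sometimes": 2.0, "usually": 3.0}
    )
    out["subjective_sleep_cat"] = out["subjective_sleep_h"].map(
        lambda h: categorize_sleep_duration(h) if pd.notna(h) else None
    )
    out["season"] = out["wear_start_date"].map(season_of_wear)

    for col, q, invert in [("ra", "ra_q", True), ("is_", "is_q", True),
                           ("aa", "aa_q", True), ("sleep_efficiency", "eff_q", True),
                           ("iv", "iv_q", False)]:
        if col in out.columns and out[col].notna().sum() >= 5 and out[col].dropna().nunique() >= 5:
            out[q] = make_quintiles(out[col], invert=invert)
        else:
            out[q] = np.nan

    if "sleep_duration_h" in out.columns:
        disc = [
            sleep_discrepancy(r.subjective_sleep_h, r.sleep_duration_h, r.napping)
            for r in out.itertuples(index=False)
        ]
        out["discrepancy_cat"] = [c for c, _ in disc]
        out["discrepancy_min"] = [m for _, m in disc]
    return out


# (exposure column, type, reference, objective?)
EXPOSURE_PLAN = [
    ("anxiety", "continuous", None, False),
    ("self_harm", "continuous", None, False),
    ("risk_taker", "continuous", None, False),
    ("neuroticism", "continuous", None, False),
    ("happiness_cat", "categorical", "happy", False),
    ("happiness_health_cat", "categorical", "happy", False),
    ("sleeplessness_score", "continuous", None, False),
    ("getting_up_cat", "categorical", "not_difficult", False),
    ("chronotype_cat", "categorical", "intermediate", False),
    ("subjective_sleep_cat", "categorical", "regular", False),
    ("aa_q", "continuous", None, True),
    ("ra_q", "continuous", None, True),
    ("is_q", "continuous", None, True),
    ("iv_q", "continuous", None, True),
    ("eff_q", "continuous", None, True),
    ("sleep_duration_cat", "categorical", "regular", True),
]


def run_comparisons(
    analysed: pd.DataFrame,
    stats_params: StatsParams,
    exposures: Optional[list] = None,
    include_multinomial: bool = True,
) -> List[ComparisonResult]:
    """All pairwise models over the exposure plan, with the exact-test
    fallback for sparse categorical cells and pooled FDR over the fully
    adjusted family."""
    plan = exposures if exposures is not None else EXPOSURE_PLAN
    results: List[ComparisonResult] = []
    for comparison in ("BD_vs_UM", "UM_vs_control", "BD_vs_control"):
        for exposure, etype, ref, objective in plan:
            if exposure not in analysed.columns or analysed[exposure].dropna().nunique() < 2:
                continue
            spec0 = ModelSpec(comparison=comparison, exposure=exposure, exposure_type=etype,
                              reference=ref, objective=objective, adjustment="partly")
            sparse = sparse_levels(analysed, spec0,
                                   min_expected=stats_params.fisher_min_expected)
            for level in sparse:
                results.append(fisher_level_result(analysed, spec0, level))
            for adjustment in ("partly", "fully"):
                spec = dataclasses.replace(spec0, adjustment=adjustment)
                for res in fit_group_logistic(analysed, spec):
                    if res.level is not None and str(res.level) in set(sparse):
                        continue  # reported via the exact test instead
                    results.append(res)
    if include_multinomial and "discrepancy_cat" in analysed.columns:
        for adjustment in ("partly", "fully"):
            try:
                results.extend(multinomial_discrepancy(analysed, adjustment=adjustment))
            except ValueError as exc:
                log.warning("multinomial discrepancy model skipped: %s", exc)
    apply_fdr(results, "fully")
    return results


def _descriptives(analysed: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for g in ("BD", "UM", "CONTROL"):
        sub = analysed[analysed["group"] == g]
        row = {"group": g, "n": len(sub)}
        for col in ("age", "townsend", "bmi", "neuroticism", "aa", "ra", "is_", "iv",
                    "sleep_duration_h", "sleep_efficiency", "subjective_sleep_h",
                    "discrepancy_min"):
            if col in sub.columns:
                mean, sd = sub[col].mean(), sub[col].std()
                row[f"{col}_mean"] = float(mean) if pd.notna(mean) else float("nan")
                row[f"{col}_sd"] = float(sd) if pd.notna(sd) else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the full pipeline into ``outdir``; deterministic given the seed.

    Returns a dict with the cohort, metrics, analysed tables, results list
    and the manifest. Raises with the failing stage named if any stage fails.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)

    stage = "simulate"
    try:
        cohort = generate_cohort(cohort_cfg)
        stage = "phenotype"
        cohort = phenotype_cohort(cohort)
        counts = cohort["group"].value_counts().to_dict()
        stage = "metrics"
        metrics = compute_cohort_metrics(cohort, config)
        merged = cohort.merge(metrics, on="id", how="left")
        stage = "compare"
        analysed = merged[merged["group"].isin(["BD", "UM", "CONTROL"])].copy()
        analysed = prepare_analysis_variables(analysed, config.stats)
        results = run_comparisons(analysed, config.stats)
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed at stage {stage!r} "
            f"(participants so far: {len(cohort) if 'cohort' in locals() else 0}): {exc}"
        ) from exc

    results_df = pd.DataFrame([r.as_row() for r in results])
    descr = _descriptives(analysed)

    cohort_path = outdir / "cohort.csv"
    metrics_path = outdir / "metrics.csv"
    results_path = outdir / "results.csv"
    cohort.to_csv(cohort_path, index=False)
    metrics.to_csv(metrics_path, index=False)
    results_df.to_csv(results_path, index=False)
    save_config(config, outdir / "config.yaml")

    config_yaml = yaml.safe_dump(_to_dict(config), sort_keys=True)
    n = len(cohort)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(config_yaml.encode()).hexdigest(),
        "n_input": n,
        "n_excluded": int(counts.get("EXCLUDED", 0)),
        "n_unclassifiable": int(counts.get("UNCLASSIFIABLE", 0)),
        "n_depression_only": int(counts.get("DEPRESSION_ONLY", 0)),
        "n_BD": int(counts.get("BD", 0)),
        "n_UM": int(counts.get("UM", 0)),
        "n_control": int(counts.get("CONTROL", 0)),
        "n_with_actigraphy_analysed": int(analysed["has_actigraphy"].sum()),
        "n_results": len(results),
        "n_fdr_significant": int(
            pd.to_numeric(results_df["p_fdr"], errors="coerce")
            .lt(config.stats.fdr_alpha).sum()
        ) if "p_fdr" in results_df else 0,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    assert manifest["n_input"] == (
        manifest["n_excluded"] + manifest["n_unclassifiable"] + manifest["n_depression_only"]
        + manifest["n_BD"] + manifest["n_UM"] + manifest["n_control"]
    ), "filtering ledger must conserve participants"
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    report_lines = [
        "# Rest-activity comparison report",
        "",
        f"Seed: {config.seed}; participants: {n}",
        "",
        "## Filtering ledger",
        "",
    ] + [f"- {k}: {manifest[k]}" for k in
         ("n_input", "n_excluded", "n_unclassifiable", "n_depression_only",
          "n_BD", "n_UM", "n_control")] + [
        "",
        "## Group descriptives",
        "",
        descr.round(3).to_string(index=False),
        "",
        "## Comparisons",
        "",
        (results_df.round(4).to_string(index=False) if len(results_df) else "(none)"),
        "",
    ]
    (outdir / "report.md").write_text("\n".join(report_lines))

    return {
        "cohort": cohort,
        "metrics": metrics,
        "analysed": analysed,
        "results": results,
        "results_df": results_df,
        "manifest": manifest,
        "outdir": outdir,
    }
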