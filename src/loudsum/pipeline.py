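"""End-to-end pipeline: simulate → scale → fit → prescribe → analyze.

Stages are plain functions over in-memory objects so the CLI subcommands
and tests can drive them individually; :func:`run_pipeline` chains them
and writes the CSV/JSON outputs.  Everything is derived from the master
seed, so a fixed seed yields byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as lio
from .cohort import CohortRecord, GROUPS, HI_GROUPS, generate_cohort
from .config import PipelineConfig
from .loudness import NarrowbandReferenceSet, SaturatedCategoryError
from .metrics import (
    NH_REFERENCE_L40_DB_SPL,
    adjusted_r2_multilinear,
    correlation_r2,
    delta_l40,
    group_ttests,
    mean_unsigned_gain_difference,
    prevalence_excess,
    pta,
)
from .prescription import (
    GainTable,
    broadband_correction,
    compression_ratio,
    narrowband_normalization_gains,
    stand_in_rule,
    trueloudness_gains,
)
from .scaling import (
    ScalingTrial,
    UnfittableDataError,
    UnusableDynamicRangeError,
    fit_loudness_function,
    run_adaptive_scaling,
)

__all__ = ["scale_cohort", "prescribe_cohort", "analyze_cohort", "run_pipeline"]

logger = logging.getLogger("loudsum")

_CR_RANGES = {"low_50_65": (50, 65), "high_65_80": (65, 80), "full_50_80": (50, 80)}


def scale_cohort(
    records: Sequence[CohortRecord], config: PipelineConfig
) -> tuple[dict[str, list[ScalingTrial]], pd.DataFrame]:
    """Run the simulated scaling measurement and fit on every participant.

    Returns the trial logs and a fits table (one row per participant with
    the fitted two-branch parameters, L40 and measured ΔL40; NaN where
    the run or fit failed).
    """
    ss = np.random.SeedSequence([config.seed, 1])
    children = ss.spawn(len(records))
    trials_by_pid: dict[str, list[ScalingTrial]] = {}
    rows = []
    for rec, child in zip(records, children):
        rng = np.random.default_rng(child)
        try:
            trials = run_adaptive_scaling(rec.listener, "IFnoise", config.scaling, rng)
            fit = fit_loudness_function(trials)
            l40 = fit.l40
            row = (rec.participant_id, "IFnoise", fit.l_cut, fit.m_lo, fit.m_hi,
                   l40, delta_l40(NH_REFERENCE_L40_DB_SPL, l40))
            trials_by_pid[rec.participant_id] = trials
        except (UnusableDynamicRangeError, UnfittableDataError, SaturatedCategoryError) as exc:
            logger.warning("scale: participant %s unusable: %s", rec.participant_id, exc)
            trials_by_pid[rec.participant_id] = []
            row = (rec.participant_id, "IFnoise", np.nan, np.nan, np.nan, np.nan, np.nan)
        rows.append(row)
    fits = pd.DataFrame(rows, columns=lio._FIT_COLUMNS)
    return trials_by_pid, fits


def prescribe_cohort(
    records: Sequence[CohortRecord],
    fits: pd.DataFrame,
    config: PipelineConfig,
    refs: NarrowbandReferenceSet | None = None,
) -> dict[str, dict[str, GainTable]]:
    """Compute per-participant gain tables for each rule.

    ``trueLOUDNESS`` combines the narrowband-normalization initial gains
    with the broadband correction from the fitted aided loudness
    function; ``standin-halfgain`` is the generic threshold-based
    comparison rule.  Participants without a usable fit get only the
    stand-in table.
    """
    refs = refs or NarrowbandReferenceSet.default()
    reference = refs.broadband_reference("IFnoise")
    fits_by_pid = fits.set_index("participant_id")
    out: dict[str, dict[str, GainTable]] = {}
    for rec in records:
        tables: dict[str, GainTable] = {"standin-halfgain": stand_in_rule(rec.audiogram)}
        frow = fits_by_pid.loc[rec.participant_id]
        if np.isfinite(float(frow["l_cut_db"])):
            from .loudness import LoudnessFunction

            fitted = LoudnessFunction(float(frow["l_cut_db"]),
                                      float(frow["m_lo_cu_per_db"]),
                                      float(frow["m_hi_cu_per_db"]))
            initial = narrowband_normalization_gains(rec.audiogram, refs)
            correction = broadband_correction(fitted, reference)
            tables["trueLOUDNESS"] = trueloudness_gains(initial, correction)
        out[rec.participant_id] = tables
    return out


def _group_stats(deltas: np.ndarray, boundary: float) -> dict | None:
    deltas = deltas[np.isfinite(deltas)]
    if deltas.size == 0:
        return None
    return {
        "n": int(deltas.size),
        "mean_db": float(np.mean(deltas)),
        "sd_db": float(np.std(deltas, ddof=1)) if deltas.size > 1 else None,
        "median_db": float(np.median(deltas)),
        "prevalence_beyond_boundary": prevalence_excess(deltas, boundary),
    }


def analyze_cohort(
    records: Sequence[CohortRecord],
    fits: pd.DataFrame,
    gains: Mapping[str, Mapping[str, GainTable]],
    config: PipelineConfig,
) -> tuple[pd.DataFrame, dict]:
    """Assemble the per-participant results table and the summary statistics."""
    fits_by_pid = fits.set_index("participant_id")
    rows = []
    for rec in records:
        cov = rec.covariates
        measured = float(fits_by_pid.loc[rec.participant_id, "delta_l40_db"])
        tables = gains[rec.participant_id]
        tl = tables.get("trueLOUDNESS")
        si = tables["standin-halfgain"]
        if tl is not None:
            diff = mean_unsigned_gain_difference(
                tl, si, config.comparison_frequencies_hz,
                config.comparison_levels_db_spl, config.meaningful_difference_db)
            mean_tl = float(np.mean([tl.gains[e] for e in tl.ears]))
        else:
            diff = None
            mean_tl = np.nan
        rows.append({
            "participant_id": rec.participant_id,
            "group": rec.group,
            "latent_delta_l40_db": rec.latent_delta_l40,
            "delta_l40_db": measured,
            "pta_db_hl": pta(rec.audiogram, "both"),
            "pta_ucl_db_hl": cov.pta_ucl_db_hl,
            "speech_ucl_binaural_db_hl": cov.speech_ucl_binaural,
            "speech_ucl_min_monaural_db_hl": cov.speech_ucl_min_monaural,
            "ihs_score": cov.ihs_score,
            "age_years": cov.age_years,
            "mean_gain_trueloudness_db": mean_tl,
            "mean_gain_standin_db": float(np.mean([si.gains[e] for e in si.ears])),
            "mean_unsigned_gain_diff_db": diff.mean_unsigned_db if diff else np.nan,
            "meaningful_gain_diff": diff.meaningful if diff else None,
        })
    results = pd.DataFrame(rows)

    boundary = config.nh_boundary_db
    summary: dict = {"groups": {}, "pooled_hi": None}
    for group in GROUPS:
        deltas = results.loc[results["group"] == group, "delta_l40_db"].to_numpy()
        summary["groups"][group] = _group_stats(deltas, boundary)
    hi = results.loc[results["group"].isin(HI_GROUPS)]
    summary["pooled_hi"] = _group_stats(hi["delta_l40_db"].to_numpy(), boundary)
    if summary["pooled_hi"]:
        finite = hi["delta_l40_db"].to_numpy()
        finite = finite[np.isfinite(finite)]
        summary["pooled_hi"]["p2_5_db"] = float(np.percentile(finite, 2.5))
        summary["pooled_hi"]["p97_5_db"] = float(np.percentile(finite, 97.5))

    # predictor correlations against measured ΔL40 (hearing-impaired only)
    predictors = ["pta_db_hl", "pta_ucl_db_hl", "speech_ucl_binaural_db_hl",
                  "speech_ucl_min_monaural_db_hl", "ihs_score", "age_years"]
    hi_ok = hi.loc[np.isfinite(hi["delta_l40_db"])]
    correlations = {}
    if len(hi_ok) >= 3:
        for pred in predictors:
            try:
                r2, p = correlation_r2(hi_ok[pred], hi_ok["delta_l40_db"])
                correlations[pred] = {"r2": r2, "p": p}
            except ValueError:
                correlations[pred] = None
        try:
            summary["adjusted_r2_multilinear"] = adjusted_r2_multilinear(
                hi_ok[predictors].to_numpy(), hi_ok["delta_l40_db"].to_numpy())
        except ValueError:
            summary["adjusted_r2_multilinear"] = None
    summary["correlations_vs_delta_l40"] = correlations or None

    # pairwise group tests on measured ΔL40
    test_ok = results.loc[np.isfinite(results["delta_l40_db"])]
    counts = test_ok["group"].value_counts()
    testable = [g for g in GROUPS if counts.get(g, 0) >= 3]
    if len(testable) >= 2:
        sub = test_ok.loc[test_ok["group"].isin(testable)]
        tt = group_ttests(sub["delta_l40_db"].to_numpy(), sub["group"].to_numpy())
        summary["group_ttests"] = tt.to_dict(orient="records")
    else:
        summary["group_ttests"] = None

    # compression-ratio distributions for trueLOUDNESS (HAPF groups, both ears)
    cr_summary: dict = {}
    hapf_ids = [r.participant_id for r in records if r.group in ("New", "Experienced")]
    for name, (lo, hi_lv) in _CR_RANGES.items():
        per_freq = {}
        for f in config.comparison_frequencies_hz:
            vals = []
            for pid in hapf_ids:
                tl = gains[pid].get("trueLOUDNESS")
                if tl is None:
                    continue
                for ear in tl.ears:
                    cr = compression_ratio(tl.gain(ear, f, lo), tl.gain(ear, f, hi_lv),
                                           lo, hi_lv)
                    if cr.valid:
                        vals.append(cr.value)
            if vals:
                q1, med, q3 = np.percentile(vals, [25, 50, 75])
                per_freq[str(f)] = {"n": len(vals), "q1": float(q1),
                                    "median": float(med), "q3": float(q3)}
            else:
                per_freq[str(f)] = None
        cr_summary[name] = per_freq
    summary["compression_ratios_trueloudness"] = cr_summary

    # cumulative distribution of the mean unsigned gain difference
    diffs = results["mean_unsigned_gain_diff_db"].to_numpy()
    diffs = diffs[np.isfinite(diffs)]
    if diffs.size:
        grid = list(range(0, 21, 2))
        summary["gain_difference_cumulative"] = {
            "thresholds_db": grid,
            "fraction_exceeding": [float(np.mean(diffs > t)) for t in grid],
        }
        per_group = {}
        for group in GROUPS:
            gd = results.loc[results["group"] == group, "mean_unsigned_gain_diff_db"]
            gd = gd.to_numpy()
            gd = gd[np.isfinite(gd)]
            per_group[group] = (
                float(np.mean(gd > config.meaningful_difference_db)) if gd.size else None)
        summary["fraction_meaningful_difference"] = per_group
    else:
        summary["gain_difference_cumulative"] = None
        summary["fraction_meaningful_difference"] = None
    return results, summary


def _config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(repr(sorted(asdict(config).items())).encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage and write all outputs under ``outdir``.

    Writes the cohort CSV bundle, trials.csv, fits.csv, per-rule gain
    CSVs, results.csv and summary.json; returns the summary dict.
    Idempotent under a fixed seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline: seed=%d config=%s", config.seed, _config_hash(config))

    try:
        records = generate_cohort(dict(config.group_sizes), seed=config.seed,
                                  response_noise_sd=config.noise_sd_cu,
                                  smoothing_halfwidth=config.smoothing_halfwidth_db)
    except Exception as exc:
        raise RuntimeError(f"stage simulate-cohort failed: {exc}") from exc
    lio.write_cohort(records, outdir)

    try:
        trials, fits = scale_cohort(records, config)
    except Exception as exc:
        raise RuntimeError(f"stage scale failed: {exc}") from exc
    lio.write_trials(trials, outdir / "trials.csv")
    lio.write_fits(fits, outdir / "fits.csv")

    try:
        gains = prescribe_cohort(records, fits, config)
    except Exception as exc:
        raise RuntimeError(f"stage prescribe failed: {exc}") from exc
    _export_gains(gains, outdir)

    try:
        results, summary = analyze_cohort(records, fits, gains, config)
    except Exception as exc:
        raise RuntimeError(f"stage analyze failed: {exc}") from exc
    results_out = results.copy()
    for col in results_out.columns:
        if results_out[col].dtype == float:
            results_out[col] = results_out[col].map(
                lambda v: repr(float(v)) if np.isfinite(v) else "")
    results_out.to_csv(outdir / "results.csv", index=False)
    summary["seed"] = config.seed
    summary["config_hash"] = _config_hash(config)
    lio.write_summary_json(summary, outdir / "summary.json")
    return summary


def _export_gains(gains: Mapping[str, Mapping[str, GainTable]], outdir: Path) -> None:
    frames = {"trueLOUDNESS": [], "standin-halfgain": []}
    for pid in gains:
        for rule, table in gains[pid].items():
            rows = []
            for ear in table.ears:
                for i, f in enumerate(table.frequencies_hz):
                    for j, lv in enumerate(table.levels_db_spl):
                        rows.append((pid, ear, rule, repr(float(f)), repr(float(lv)),
                                     repr(float(table.gains[ear][i, j]))))
            frames[rule].extend(rows)
    cols = ["participant_id", "ear", "rule", "frequency_hz", "level_db_spl",
            "insertion_gain_db"]
    pd.DataFrame(frames["trueLOUDNESS"], columns=cols).to_csv(
        outdir / "gains_trueloudness.csv", index=False)
    pd.DataFrame(frames["standin-halfgain"], columns=cols).to_csv(
        outdir / "gains_standin.csv", index=False)
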