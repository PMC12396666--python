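"""CSV/JSON round-tripping for cohorts, trial logs, fits and summaries.

All writers are deterministic (fixed row order, ``repr``-formatted floats
that round-trip bit-exactly); readers validate schemas strictly, raising
:class:`SchemaError` with column/row diagnostics, and warn about unknown
columns instead of failing.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortRecord, Covariates, _make_listener
from .loudness import (
    AUDIOMETRIC_FREQUENCIES_HZ,
    PTA_FREQUENCIES_HZ,
    Audiogram,
    NarrowbandReferenceSet,
)
from .scaling import ScalingTrial

__all__ = [
    "SchemaError",
    "write_cohort",
    "read_cohort",
    "write_trials",
    "read_trials",
    "write_fits",
    "read_fits",
    "write_summary_json",
]


class SchemaError(ValueError):
    """A CSV file does not conform to its documented schema."""


def _check_columns(df: pd.DataFrame, required: Sequence[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing column(s) {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(f"{name}: ignoring unknown column(s) {extra}", stacklevel=3)


def _check_ears(df: pd.DataFrame, name: str, allowed=("L", "R")) -> None:
    bad = df.loc[~df["ear"].isin(allowed)]
    if not bad.empty:
        raise SchemaError(
            f"{name}: invalid ear label(s) {sorted(bad['ear'].astype(str).unique())} "
            f"in row(s) {list(bad.index[:5])}"
        )


def _r(x: float) -> str:
    return repr(float(x))


# ---------------------------------------------------------------------------
# cohort bundle: participants.csv, audiograms.csv, ucl.csv
# ---------------------------------------------------------------------------

_PARTICIPANT_COLUMNS = [
    "participant_id", "group", "age_years", "ihs_score", "latent_delta_l40_db",
    "speech_ucl_left_db_hl", "speech_ucl_right_db_hl", "speech_ucl_binaural_db_hl",
    "response_noise_sd_cu", "listener_smoothing_db",
]
_AUDIOGRAM_COLUMNS = ["participant_id", "ear", "frequency_hz",
                      "ac_threshold_db_hl", "bc_threshold_db_hl"]
_UCL_COLUMNS = ["participant_id", "ear", "frequency_hz", "ucl_db_hl"]


def write_cohort(records: Sequence[CohortRecord], outdir) -> None:
    """Write participants.csv, audiograms.csv and ucl.csv for a cohort."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prows, arows, urows = [], [], []
    for rec in records:
        cov = rec.covariates
        fn = rec.listener.true_function("IFnoise")
        prows.append((rec.participant_id, rec.group, _r(cov.age_years), _r(cov.ihs_score),
                      _r(rec.latent_delta_l40), _r(cov.speech_ucl_left),
                      _r(cov.speech_ucl_right), _r(cov.speech_ucl_binaural),
                      _r(rec.listener.response_noise_sd), _r(fn.smoothing_halfwidth)))
        for ear in ("L", "R"):
            for f in AUDIOMETRIC_FREQUENCIES_HZ:
                bc = ""
                if rec.audiogram.bc_db_hl and f in rec.audiogram.bc_db_hl.get(ear, {}):
                    bc = _r(rec.audiogram.bc_db_hl[ear][f])
                arows.append((rec.participant_id, ear, f,
                              _r(rec.audiogram.threshold(ear, f)), bc))
            for f in PTA_FREQUENCIES_HZ:
                urows.append((rec.participant_id, ear, f, _r(cov.tone_ucl_db_hl[ear][f])))
    pd.DataFrame(prows, columns=_PARTICIPANT_COLUMNS).to_csv(
        outdir / "participants.csv", index=False)
    pd.DataFrame(arows, columns=_AUDIOGRAM_COLUMNS).to_csv(
        outdir / "audiograms.csv", index=False)
    pd.DataFrame(urows, columns=_UCL_COLUMNS).to_csv(outdir / "ucl.csv", index=False)


def read_cohort(indir, refs: NarrowbandReferenceSet | None = None) -> list[CohortRecord]:
    """Reconstruct a cohort from the CSV bundle written by :func:`write_cohort`."""
    indir = Path(indir)
    refs = refs or NarrowbandReferenceSet.default()
    participants = pd.read_csv(indir / "participants.csv", float_precision="round_trip")
    audiograms = pd.read_csv(indir / "audiograms.csv", float_precision="round_trip")
    ucls = pd.read_csv(indir / "ucl.csv", float_precision="round_trip")
    _check_columns(participants, _PARTICIPANT_COLUMNS, "participants.csv")
    _check_columns(audiograms, _AUDIOGRAM_COLUMNS, "audiograms.csv")
    _check_columns(ucls, _UCL_COLUMNS, "ucl.csv")
    _check_ears(audiograms, "audiograms.csv")
    _check_ears(ucls, "ucl.csv")

    records = []
    for _, row in participants.iterrows():
        pid = row["participant_id"]
        sub = audiograms.loc[audiograms["participant_id"] == pid]
        ac: dict[str, dict[int, float]] = {"L": {}, "R": {}}
        bc: dict[str, dict[int, float]] = {"L": {}, "R": {}}
        for _, arow in sub.iterrows():
            ac[arow["ear"]][int(arow["frequency_hz"])] = float(arow["ac_threshold_db_hl"])
            if pd.notna(arow["bc_threshold_db_hl"]) and arow["bc_threshold_db_hl"] != "":
                bc[arow["ear"]][int(arow["frequency_hz"])] = float(arow["bc_threshold_db_hl"])
        audiogram = Audiogram(ac, bc if any(bc.values()) else None)
        usub = ucls.loc[ucls["participant_id"] == pid]
        tone = {"L": {}, "R": {}}
        for _, urow in usub.iterrows():
            tone[urow["ear"]][int(urow["frequency_hz"])] = float(urow["ucl_db_hl"])
        cov = Covariates(
            tone_ucl_db_hl=tone,
            speech_ucl_left=float(row["speech_ucl_left_db_hl"]),
            speech_ucl_right=float(row["speech_ucl_right_db_hl"]),
            speech_ucl_binaural=float(row["speech_ucl_binaural_db_hl"]),
            ihs_score=float(row["ihs_score"]),
            age_years=float(row["age_years"]),
        )
        delta = float(row["latent_delta_l40_db"])
        listener = _make_listener(delta, refs,
                                  float(row["response_noise_sd_cu"]),
                                  float(row["listener_smoothing_db"]))
        records.append(CohortRecord(pid, str(row["group"]), audiogram, cov, delta, listener))
    return records


# ---------------------------------------------------------------------------
# trial logs and fitted functions
# ---------------------------------------------------------------------------

_TRIAL_COLUMNS = ["participant_id", "stimulus_id", "trial_index", "level_db_spl",
                  "response_cu"]
_FIT_COLUMNS = ["participant_id", "stimulus_id", "l_cut_db", "m_lo_cu_per_db",
                "m_hi_cu_per_db", "l40_db_spl", "delta_l40_db"]


def write_trials(trials_by_participant: Mapping[str, Sequence[ScalingTrial]], path) -> None:
    rows = []
    for pid, trials in trials_by_participant.items():
        for i, t in enumerate(trials):
            rows.append((pid, t.stimulus_id, i, _r(t.presentation_level), t.response))
    pd.DataFrame(rows, columns=_TRIAL_COLUMNS).to_csv(path, index=False)


def read_trials(path) -> dict[str, list[ScalingTrial]]:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, _TRIAL_COLUMNS, "trials.csv")
    out: dict[str, list[ScalingTrial]] = {}
    for pid, sub in df.groupby("participant_id", sort=False):
        sub = sub.sort_values("trial_index")
        out[str(pid)] = [
            ScalingTrial(str(r["stimulus_id"]), float(r["level_db_spl"]),
                         int(r["response_cu"]))
            for _, r in sub.iterrows()
        ]
    return out


def write_fits(fits: pd.DataFrame, path) -> None:
    df = fits.copy()
    for col in df.columns:
        if col in _FIT_COLUMNS[2:]:
            df[col] = df[col].map(lambda v: repr(float(v)) if pd.notna(v) else "")
    df.to_csv(path, index=False)


def read_fits(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, _FIT_COLUMNS, "fits.csv")
    return df


# ---------------------------------------------------------------------------
# summary JSON
# ---------------------------------------------------------------------------


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return round(float(obj), ndigits) if np.isfinite(obj) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def write_summary_json(summary: dict, path) -> None:
    """Write the analysis summary, rounded and key-sorted for stable bytes."""
    with open(path, "w") as fh:
        json.dump(_round_floats(summary), fh, indent=2, sort_keys=True)
        fh.write("\n")
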