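"""CSV readers and writers for the pipeline's tabular formats.

Column contracts (all files are comma-separated with a header row):

``production table`` (window-averaged, one row per token)
    participant_id, vowel (EH|AE), trial_index, f1_init, f2_init,
    f1_mid, f2_mid (mel), duration_ms, excluded (true|false; optional,
    defaults to false).  Excluded tokens are carried with their flag so
    exclusion counts stay reportable; their formant fields may be empty.

``track table`` (per-frame, long format; one row per frame)
    participant_id, vowel, trial_index, time_ms, f1_hz, f2_hz.

``identification table`` (one row per trial)
    participant_id, step (1..n_steps), response (head|had,
    case-insensitive).

``measures table`` (one row per participant)
    participant_id, labeling_consistency, log_contrast_distance,
    log_ellipse_area, centering_ratio.

Readers validate eagerly and raise typed errors naming the offending
column or row; malformed input never silently drops rows.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnalysisConfig, MEASURE_COLUMNS
from .errors import (DataValidationError, RangeError, SampleSizeError,
                     SchemaError)
from .types import (VOWELS, FormantTrack, ParticipantMeasures)

PRODUCTION_COLUMNS = ("participant_id", "vowel", "trial_index", "f1_init",
                      "f2_init", "f1_mid", "f2_mid", "duration_ms")
TRACK_COLUMNS = ("participant_id", "vowel", "trial_index", "time_ms",
                 "f1_hz", "f2_hz")
IDENTIFICATION_COLUMNS = ("participant_id", "step", "response")
MEASURES_TABLE_COLUMNS = ("participant_id",) + MEASURE_COLUMNS

_TRUTHY = {"true": True, "1": True, "yes": True,
           "false": False, "0": False, "no": False}


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _numeric(df: pd.DataFrame, col: str, path) -> pd.Series:
    out = pd.to_numeric(df[col], errors="coerce")
    bad = out.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
    if bad.any():
        row = int(bad.idxmax()) + 2  # header is line 1
        raise DataValidationError(
            f"{path}: non-numeric value {df[col][bad.idxmax()]!r} in column "
            f"{col!r} at line {row}")
    return out


def is_track_table(path: str | Path) -> bool:
    """Sniff whether a production CSV is per-frame (track) or per-token."""
    header = pd.read_csv(path, nrows=0).columns
    return "time_ms" in header and "f1_hz" in header


def read_production_table(path: str | Path,
                          config: AnalysisConfig = AnalysisConfig()) -> pd.DataFrame:
    """Read a window-averaged production token table.

    Returns a validated DataFrame with the production columns plus the
    boolean ``excluded`` flag.  Non-excluded rows must carry strictly
    positive finite formant values; (participant_id, vowel, trial_index)
    must be unique.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"participant_id": str, "vowel": str},
                     float_precision="round_trip")
    _require_columns(df, PRODUCTION_COLUMNS, path)

    if "excluded" in df.columns:
        raw = df["excluded"]
        if raw.dtype == bool:
            excluded = raw
        else:
            norm = raw.astype(str).str.strip().str.lower()
            unknown = ~norm.isin(_TRUTHY)
            if unknown.any():
                row = int(unknown.idxmax()) + 2
                raise DataValidationError(
                    f"{path}: unparseable excluded flag {raw[unknown.idxmax()]!r} at line {row}")
            excluded = norm.map(_TRUTHY)
    else:
        excluded = pd.Series(False, index=df.index)
    df = df.assign(excluded=excluded.astype(bool))

    bad_vowel = ~df["vowel"].isin(VOWELS)
    if bad_vowel.any():
        row = int(bad_vowel.idxmax()) + 2
        raise DataValidationError(
            f"{path}: vowel must be one of {VOWELS}, got "
            f"{df['vowel'][bad_vowel.idxmax()]!r} at line {row}")

    df["trial_index"] = _numeric(df, "trial_index", path)
    if (df["trial_index"] < 1).any() or (df["trial_index"] % 1 != 0).any():
        raise DataValidationError(f"{path}: trial_index must be a positive integer")
    df["trial_index"] = df["trial_index"].astype(int)

    for col in ("f1_init", "f2_init", "f1_mid", "f2_mid", "duration_ms"):
        df[col] = _numeric(df, col, path)

    keep = ~df["excluded"]
    for col in ("f1_init", "f2_init", "f1_mid", "f2_mid"):
        vals = df.loc[keep, col]
        bad = ~np.isfinite(vals) | (vals <= 0)
        if bad.any():
            row = int(bad.idxmax()) + 2
            raise DataValidationError(
                f"{path}: {col} must be strictly positive and finite for "
                f"non-excluded tokens; offending value at line {row}")
    if (df.loc[keep, "duration_ms"] < 0).any():
        raise DataValidationError(f"{path}: duration_ms must be nonnegative")

    dup = df.duplicated(subset=["participant_id", "vowel", "trial_index"])
    if dup.any():
        key = df.loc[dup.idxmax(), ["participant_id", "vowel", "trial_index"]]
        raise DataValidationError(
            f"{path}: duplicate token key {tuple(key)}")
    return df[list(PRODUCTION_COLUMNS) + ["excluded"]]


def read_track_table(path: str | Path) -> list[FormantTrack]:
    """Read a per-frame formant track table into FormantTrack records."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"participant_id": str, "vowel": str},
                     float_precision="round_trip")
    _require_columns(df, TRACK_COLUMNS, path)
    for col in ("time_ms", "f1_hz", "f2_hz"):
        df[col] = _numeric(df, col, path)
    df["trial_index"] = _numeric(df, "trial_index", path).astype(int)

    tracks = []
    for (pid, vowel, trial), g in df.groupby(
            ["participant_id", "vowel", "trial_index"], sort=True):
        g = g.sort_values("time_ms")
        tracks.append(FormantTrack(
            participant_id=pid, vowel=vowel, trial_index=int(trial),
            frame_times_ms=tuple(g["time_ms"]),
            f1_hz=tuple(g["f1_hz"]), f2_hz=tuple(g["f2_hz"])))
    return tracks


def read_identification_table(path: str | Path,
                              config: AnalysisConfig = AnalysisConfig()) -> pd.DataFrame:
    """Read an identification-trial table, validated against n_steps."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"participant_id": str},
                     float_precision="round_trip")
    _require_columns(df, IDENTIFICATION_COLUMNS, path)

    df["step"] = _numeric(df, "step", path)
    if (df["step"] % 1 != 0).any():
        raise DataValidationError(f"{path}: step must be an integer")
    df["step"] = df["step"].astype(int)
    out_of_range = (df["step"] < 1) | (df["step"] > config.n_steps)
    if out_of_range.any():
        row = int(out_of_range.idxmax()) + 2
        raise RangeError(
            f"{path}: step {df['step'][out_of_range.idxmax()]} outside "
            f"[1, {config.n_steps}] at line {row}")

    norm = df["response"].astype(str).str.strip().str.upper()
    bad = ~norm.isin(("HEAD", "HAD"))
    if bad.any():
        row = int(bad.idxmax()) + 2
        raise DataValidationError(
            f"{path}: response must be 'head' or 'had', got "
            f"{df['response'][bad.idxmax()]!r} at line {row}")
    df["response"] = norm
    return df[list(IDENTIFICATION_COLUMNS)]


def write_measures_table(measures, path: str | Path) -> None:
    """Write participant measures to CSV (full float precision).

    ``measures`` may be a sequence of :class:`ParticipantMeasures` or a
    DataFrame with the measures columns.  Empty input and non-finite
    values are refused.
    """
    path = Path(path)
    if isinstance(measures, pd.DataFrame):
        df = measures
    else:
        df = pd.DataFrame([{
            "participant_id": m.participant_id,
            "labeling_consistency": m.labeling_consistency,
            "log_contrast_distance": m.log_contrast_distance,
            "log_ellipse_area": m.log_ellipse_area,
            "centering_ratio": m.centering_ratio,
        } for m in measures])
    if len(df) == 0:
        raise SampleSizeError("refusing to write an empty measures table")
    missing = [c for c in MEASURES_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"measures table missing column(s) {missing}")
    vals = df[list(MEASURE_COLUMNS)].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise DataValidationError("measures contain non-finite values; refusing to write")
    # default float formatting is shortest-roundtrip, i.e. lossless
    df[list(MEASURES_TABLE_COLUMNS)].to_csv(path, index=False)


def read_measures_table(path: str | Path) -> pd.DataFrame:
    """Read a participant measures table (inverse of the writer)."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"participant_id": str},
                     float_precision="round_trip")
    _require_columns(df, MEASURES_TABLE_COLUMNS, path)
    for col in MEASURE_COLUMNS:
        df[col] = _numeric(df, col, path)
        if not np.all(np.isfinite(df[col])):
            raise DataValidationError(f"{path}: non-finite value in {col}")
    dup = df["participant_id"].duplicated()
    if dup.any():
        raise DataValidationError(
            f"{path}: duplicate participant_id {df['participant_id'][dup.idxmax()]!r}")
    return df[list(MEASURES_TABLE_COLUMNS)]


def measures_to_records(df: pd.DataFrame) -> list[ParticipantMeasures]:
    """Convert a measures DataFrame to validated typed records."""
    return [ParticipantMeasures(
        participant_id=str(r.participant_id),
        labeling_consistency=float(r.labeling_consistency),
        log_contrast_distance=float(r.log_contrast_distance),
        log_ellipse_area=float(r.log_ellipse_area),
        centering_ratio=float(r.centering_ratio),
    ) for r in df.itertuples(index=False)]
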