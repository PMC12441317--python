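"""CSV interchange for trials, ratings, true parameters and fit results.

All tables are plain CSV with fixed headers.  The trial table uses the
schema in :data:`aalearn.task.TRIAL_COLUMNS`; missing outcomes on invalid
trials are written as empty fields.  Loading validates the schema, value
ranges and per-participant trial ordering, and reports violations with row
numbers (1-based, counting the header as row 1).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .task import ARMS, SYMBOLS, TRIAL_COLUMNS


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table in the fixed-column CSV schema."""
    missing = set(TRIAL_COLUMNS) - set(trials.columns)
    if missing:
        raise ValueError(f"trial table lacks columns {sorted(missing)}")
    out = trials[TRIAL_COLUMNS].copy()
    out.to_csv(path, index=False, float_format="%.10g")


class SchemaError(ValueError):
    """A loaded table violates the interchange schema."""


def load_trials(path) -> pd.DataFrame:
    """Load and validate a trial CSV.

    Raises :class:`SchemaError` naming the missing column or the first
    offending row for range and ordering violations.
    """
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(sorted(missing))}")
    df = df[TRIAL_COLUMNS].copy()
    df["valid"] = df["valid"].astype(bool)

    def _bad(mask, message):
        if mask.any():
            row = int(np.flatnonzero(mask.to_numpy())[0]) + 2  # header is row 1
            raise SchemaError(f"{message} (first at file row {row})")

    _bad(~df["arm"].isin(ARMS), f"arm outside {ARMS}")
    _bad(~df["symbol"].isin(SYMBOLS), f"symbol outside {SYMBOLS}")
    _bad(df["block"] < 1, "block index < 1")
    _bad(df["trial"] < 1, "trial index < 1")
    yv = df["y_value"]
    _bad(df["valid"] & (yv.isna() | (yv < 0) | (yv > 1)),
         "y_value of a valid trial outside [0, 1]")
    _bad(df["valid"] & ~df["outcome_r"].isin([0, 1]),
         "outcome_r of a valid trial not 0/1")
    _bad(~df["valid"] & (df["outcome_eur"] != 0),
         "invalid trial with nonzero outcome_eur")
    _bad(~df["valid"] & df["outcome_r"].notna(),
         "invalid trial with an outcome")
    dup = df.duplicated(subset=["participant_id", "trial"], keep=False)
    _bad(dup, "duplicate (participant_id, trial)")
    for pid, sub in df.groupby("participant_id"):
        t = sub["trial"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise SchemaError(f"trials of {pid} not strictly increasing")
    return df


def write_ratings(ratings: pd.DataFrame, path) -> None:
    ratings[["participant_id", "group", "time", "rating"]].to_csv(path, index=False)


def load_ratings(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"participant_id", "group", "time", "rating"} - set(df.columns)
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(sorted(missing))}")
    return df


def write_true_params(true_params: pd.DataFrame, path) -> None:
    true_params[["participant_id", "model", "param", "value"]].to_csv(path, index=False)


def load_true_params(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"participant_id", "model", "param", "value"} - set(df.columns)
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(sorted(missing))}")
    return df


def write_fits(fits: pd.DataFrame, path) -> None:
    fits.to_csv(path, index=False, float_format="%.10g")


def load_fits(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"participant_id", "model", "sse", "n_obs", "bic", "r2"} - set(df.columns)
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(sorted(missing))}")
    return df


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
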