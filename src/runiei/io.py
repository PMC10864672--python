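"""Validated CSV input/output for trial and participant tables.

CSV dialect: comma-separated, UTF-8, dot decimal; categorical fields are
lowercase tokens. Validation errors name the offending file line (header is
line 1).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .questionnaires import EHI_WEIGHTS
from .stiat import BLOCK_CONDITION, BLOCKS, STIMULUS_TYPES

__all__ = [
    "TRIALS_COLUMNS",
    "read_trials_csv",
    "write_trials_csv",
    "read_participants_csv",
    "write_participants_csv",
]

TRIALS_COLUMNS = (
    "participant_id",
    "block",
    "trial_index",
    "condition",
    "stimulus_type",
    "rt_ms",
    "correct",
)

PARTICIPANT_REQUIRED = (
    "participant_id",
    "explicit_ft",
    "intention",
    "effort",
    "past_experience",
    "running_behavior",
) + tuple(f"ssk_{i:02d}" for i in range(1, 13))


class CsvValidationError(ValueError):
    pass


def _lines(mask: np.ndarray) -> str:
    """Format offending 1-based file line numbers (data starts at line 2)."""
    lines = (np.flatnonzero(mask) + 2).tolist()
    shown = ", ".join(map(str, lines[:5]))
    return shown + (", ..." if len(lines) > 5 else "")


def _check(mask: np.ndarray, path, message: str) -> None:
    mask = np.asarray(mask)
    if mask.any():
        raise CsvValidationError(f"{path}: {message} (line {_lines(mask)})")


def read_trials_csv(path) -> pd.DataFrame:
    """Read and validate a trials CSV against the documented schema."""
    path = Path(path)
    df = pd.read_csv(path)
    unknown = set(df.columns) - set(TRIALS_COLUMNS)
    missing = set(TRIALS_COLUMNS) - set(df.columns)
    if unknown or missing:
        raise CsvValidationError(
            f"{path}: column mismatch (unknown: {sorted(unknown)}, "
            f"missing: {sorted(missing)})"
        )
    _check(~df["block"].isin(BLOCKS), path, "unknown block label")
    expected_cond = df["block"].map(BLOCK_CONDITION)
    _check(df["condition"] != expected_cond, path, "condition inconsistent with block")
    _check(~df["stimulus_type"].isin(STIMULUS_TYPES), path, "unknown stimulus type")
    _check(
        (df["stimulus_type"] == "runner") & (df["block"] == "B1"),
        path,
        "runner stimulus in block B1",
    )
    _check(~(df["rt_ms"] > 0), path, "rt_ms must be > 0")
    if not df["correct"].isin([True, False]).all():
        _check(~df["correct"].isin([True, False]), path, "correct must be boolean")
    dup = df.duplicated(subset=["participant_id", "block", "trial_index"])
    _check(dup.to_numpy(), path, "duplicated (participant, block, trial) key")
    df["correct"] = df["correct"].astype(bool)
    return df


def write_trials_csv(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False, columns=list(TRIALS_COLUMNS))


def read_participants_csv(path) -> pd.DataFrame:
    """Read and validate a participants CSV (one row per participant)."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(PARTICIPANT_REQUIRED) - set(df.columns)
    if missing:
        raise CsvValidationError(f"{path}: missing columns: {sorted(missing)}")
    _check(
        df["participant_id"].duplicated().to_numpy(), path, "duplicated participant_id"
    )
    _check(~df["explicit_ft"].between(0, 10), path, "explicit_ft outside 0-10")
    for col in ("intention", "effort"):
        _check(~df[col].between(1, 10), path, f"{col} outside 1-10")
    for i in range(1, 13):
        _check(~df[f"ssk_{i:02d}"].between(1, 6), path, f"ssk_{i:02d} outside 1-6")
    _check(~df["past_experience"].between(1, 5), path, "past_experience outside 1-5")
    _check(
        ~df["running_behavior"].isin(["regular", "irregular", "non"]),
        path,
        "unknown running_behavior category",
    )
    ehi_cols = [f"ehi_{i}" for i in range(1, 9) if f"ehi_{i}" in df.columns]
    for col in ehi_cols:
        _check(~df[col].isin(list(EHI_WEIGHTS)), path, f"unknown {col} response")
    return df


def write_participants_csv(participants: pd.DataFrame, path) -> None:
    participants.to_csv(path, index=False)
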