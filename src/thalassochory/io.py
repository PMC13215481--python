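"""Delimited-text readers and writers for pipeline artifacts.

All matrices are stored as labelled square tables (island labels as the
header row and first column), matching the layout of the study's
supplementary dispersal / connectivity tables; everything round-trips.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def write_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a labelled square matrix as CSV (labels in header and index)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    matrix.to_csv(path, index_label="island")


def read_matrix(path) -> pd.DataFrame:
    """Read a labelled square matrix written by :func:`write_matrix`."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_trial_records(path) -> pd.DataFrame:
    """Read per-fruit trial records (sink/removal days may be blank)."""
    df = pd.read_csv(path)
    need = {"species", "fruit_id", "method", "sink_day", "removal_day", "end_of_study_day"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"trial records missing columns: {sorted(missing)}")
    for c in ("sink_day", "removal_day"):
        df[c] = pd.to_numeric(df[c], errors="coerce").astype("Int64")
    df["end_of_study_day"] = df["end_of_study_day"].astype(int)
    return df


def read_tetrazolium(path) -> pd.DataFrame:
    """Read tetrazolium test results (one row per tested fruit)."""
    df = pd.read_csv(path)
    need = {"species", "fruit_id", "test_day", "viable"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"tetrazolium results missing columns: {sorted(missing)}")
    df["test_day"] = df["test_day"].astype(int)
    df["viable"] = df["viable"].astype(bool)
    return df
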