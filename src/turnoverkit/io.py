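"""Tabular I/O for the analysis pipeline.

TSV is the canonical on-disk format (CSV accepted on read). The time-course
schema carries one row per observation: dataset_id, group (PF/EF),
animal_id, time_days, parent_id, parent_kind (protein/acetyl_site/
metabolite), peptide_id, and either an ``E`` column or raw isotopomer
columns M0..Mn (in which case E is computed on read as 1 - M0 / sum Mj).
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .isotopomer import labeling_from_mid, normalize_mid
from .kinetics import PeptideTimeCourse

__all__ = [
    "MANDATORY_COLUMNS",
    "read_timecourse",
    "write_timecourse",
    "time_courses_from_table",
]

MANDATORY_COLUMNS = (
    "dataset_id", "group", "animal_id", "time_days",
    "parent_id", "parent_kind", "peptide_id",
)

_MID_RE = re.compile(r"^M(\d+)$")
_VALID_GROUPS = {"PF", "EF"}
_VALID_KINDS = {"protein", "acetyl_site", "metabolite"}


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep)


def _mid_columns(df: pd.DataFrame) -> list[str]:
    found = [(int(m.group(1)), c) for c in df.columns if (m := _MID_RE.match(c))]
    found.sort()
    if found and [j for j, _ in found] != list(range(len(found))):
        raise SchemaError("isotopomer columns must be contiguous M0..Mn")
    return [c for _, c in found]


def read_timecourse(path: str | Path) -> pd.DataFrame:
    """Read and validate a time-course TSV/CSV; returns a typed table with E.

    Rows carrying M0..Mn isotopomer columns get E computed from the
    normalized distribution. Schema violations raise :class:`SchemaError`
    naming the offending column; row-level faults (negative times, E outside
    [0, 1]) are reported with 1-based file line numbers.
    """
    df = _read_table(path)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column: {col!r}")
    mid_cols = _mid_columns(df)
    if "E" not in df.columns and not mid_cols:
        raise SchemaError("table needs either an 'E' column or M0..Mn columns")

    df = df.copy()
    df["time_days"] = pd.to_numeric(df["time_days"], errors="coerce")
    bad_time = df.index[df["time_days"].isna() | (df["time_days"] < 0)]
    if len(bad_time):
        line = int(bad_time[0]) + 2  # header + 1-based
        raise SchemaError(f"invalid time_days at file line {line}")

    bad_group = set(df["group"].astype(str)) - _VALID_GROUPS
    if bad_group:
        raise SchemaError(f"unknown group labels: {sorted(bad_group)} (expected PF/EF)")
    bad_kind = set(df["parent_kind"].astype(str)) - _VALID_KINDS
    if bad_kind:
        raise SchemaError(f"unknown parent_kind values: {sorted(bad_kind)}")

    if mid_cols:
        need = df["E"].isna() if "E" in df.columns else pd.Series(True, index=df.index)
        if "E" not in df.columns:
            df["E"] = np.nan
        for idx in df.index[need]:
            intensities = df.loc[idx, mid_cols].to_numpy(dtype=float)
            try:
                df.loc[idx, "E"] = labeling_from_mid(normalize_mid(intensities)).E
            except Exception as exc:
                raise SchemaError(
                    f"invalid isotopomer row at file line {int(idx) + 2}: {exc}"
                ) from exc

    df["E"] = pd.to_numeric(df["E"], errors="coerce")
    bad_e = df.index[df["E"].isna() | (df["E"] < 0) | (df["E"] > 1)]
    if len(bad_e):
        raise SchemaError(f"E outside [0, 1] at file line {int(bad_e[0]) + 2}")
    return df


def write_timecourse(df: pd.DataFrame, path: str | Path) -> None:
    """Write a time-course table as TSV (round-trips with read_timecourse)."""
    sep = "," if Path(path).suffix.lower() == ".csv" else "\t"
    df.to_csv(path, sep=sep, index=False)


def time_courses_from_table(
    df: pd.DataFrame,
) -> dict[tuple[str, str], list[PeptideTimeCourse]]:
    """Group a validated table into PeptideTimeCourse objects.

    Returns {(parent_id, group): [series per peptide]}, insertion-ordered by
    first appearance for deterministic downstream iteration.
    """
    out: dict[tuple[str, str], list[PeptideTimeCourse]] = {}
    for (parent, group, pep), sub in df.groupby(
        ["parent_id", "group", "peptide_id"], sort=True
    ):
        series = PeptideTimeCourse(
            peptide_id=str(pep),
            parent_id=str(parent),
            group=str(group),
            times=sub["time_days"].to_numpy(dtype=float),
            values=sub["E"].to_numpy(dtype=float),
            animal_ids=[str(a) for a in sub["animal_id"]],
        )
        out.setdefault((str(parent), str(group)), []).append(series)
    return out
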