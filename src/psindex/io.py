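"""Reading birth-record tables and writing PSI result tables.

Input CSVs carry a ``mother_id`` column, a ``date`` column (bare integer
day numbers or ISO-8601 calendar dates — one convention per file), and an
optional ``group`` column.  Calendar dates are converted to day numbers by
offset from the earliest date within each group, which handles seasons
spanning a year boundary.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core import psi_all_fast, summarize, to_relative_dates

__all__ = ["read_birth_table", "compute_psi_tables", "write_tables"]

_UNGROUPED = "__all__"


def _dates_to_days(raw: pd.Series, date_format: str) -> pd.Series:
    """Convert a date column to integer day numbers.

    ``date_format`` is 'day' (bare integers) or 'iso' (YYYY-MM-DD); the
    caller resolves 'auto' over the whole file so one file carries one
    convention.
    """
    as_str = raw.astype(str).str.strip()
    looks_int = as_str.str.fullmatch(r"[+-]?\d+")
    if date_format == "day":
        if not looks_int.all():
            raise ValueError("non-integer value in integer-day date column")
        return as_str.astype(np.int64)
    if date_format == "iso":
        parsed = pd.to_datetime(as_str, format="%Y-%m-%d", errors="coerce")
        if parsed.isna().any():
            bad = as_str[parsed.isna()].iloc[0]
            raise ValueError(f"unparseable ISO-8601 date: {bad!r}")
        # day number = days since the earliest date in the series, +1;
        # per-group anchoring happens later via to_relative_dates
        return (parsed - parsed.min()).dt.days.astype(np.int64) + 1
    raise ValueError(f"unknown date_format {date_format!r}")


def read_birth_table(path, date_format: str = "auto") -> pd.DataFrame:
    """Read a birth-record CSV into a tidy frame.

    Returns a frame with columns ``group``, ``mother_id`` and ``date``
    (integer day numbers).  Duplicate mother ids within a group raise;
    groups with fewer than two mothers are dropped with a warning (PSI is
    undefined for them).
    """
    df = pd.read_csv(path, dtype={"mother_id": str})
    missing = {"mother_id", "date"} - set(df.columns)
    if missing:
        raise ValueError(f"missing required column(s): {sorted(missing)}")
    if "group" not in df.columns:
        df["group"] = _UNGROUPED
    df["group"] = df["group"].astype(str)
    if df["mother_id"].isna().any() or (df["mother_id"].str.len() == 0).any():
        raise ValueError("empty mother_id")

    dup = df.duplicated(subset=["group", "mother_id"])
    if dup.any():
        g, m = df.loc[dup, ["group", "mother_id"]].iloc[0]
        raise ValueError(f"duplicate mother_id {m!r} in group {g!r}")

    if date_format == "auto":
        looks_int = df["date"].astype(str).str.strip().str.fullmatch(r"[+-]?\d+")
        if looks_int.all():
            date_format = "day"
        elif not looks_int.any():
            date_format = "iso"
        else:
            raise ValueError(
                "mixed integer and calendar dates in one file; "
                "use a single convention"
            )

    out = []
    for gname, sub in df.groupby("group", sort=False):
        if len(sub) < 2:
            warnings.warn(
                f"group {gname!r} has fewer than 2 mothers; skipped "
                "(PSI needs at least 2)",
                stacklevel=2,
            )
            continue
        sub = sub.copy()
        sub["date"] = _dates_to_days(sub["date"], date_format).values
        out.append(sub[["group", "mother_id", "date"]])
    if not out:
        raise ValueError("no group with >= 2 mothers in input")
    return pd.concat(out, ignore_index=True)


def compute_psi_tables(
    births: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute per-mother PSI and per-group summaries.

    ``births`` is the frame produced by :func:`read_birth_table`.  Returns
    (per-mother table with ``t_relative`` and ``psi`` columns appended,
    per-group summary table).
    """
    mother_parts = []
    group_rows = []
    for gname, sub in births.groupby("group", sort=False):
        sub = sub.copy()
        t = to_relative_dates(sub["date"].to_numpy())
        psi = psi_all_fast(t)
        sub["t_relative"] = t
        sub["psi"] = psi
        mother_parts.append(sub)
        s = summarize(psi)
        group_rows.append(
            {
                "group": gname,
                "n": s.n,
                "mean_psi": s.mean,
                "median_psi": s.median,
                "min_psi": s.min,
                "max_psi": s.max,
                "sd_psi": s.sd,
                "cv_psi_percent": s.cv_percent,
            }
        )
    return pd.concat(mother_parts, ignore_index=True), pd.DataFrame(group_rows)


def write_tables(
    mothers: pd.DataFrame,
    groups: pd.DataFrame,
    mothers_path,
    groups_path,
    digits: int | None = 6,
) -> None:
    """Write the per-mother and per-group tables as CSV.

    ``digits`` controls significant digits for floating columns (None =
    full precision).
    """
    fmt = f"%.{digits}g" if digits else None
    mothers.to_csv(mothers_path, index=False, float_format=fmt)
    groups.to_csv(groups_path, index=False, float_format=fmt)
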