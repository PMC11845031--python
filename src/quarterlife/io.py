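"""Readers and writers for microdata and summary-table schemas.

All tables are delimited text with a header.  Quarter grids round-trip
through :func:`write_grid` / :func:`read_grid` with full numeric
fidelity; incomplete grids on disk are zero-completed with a warning and
duplicate (age, r, s) keys are an error.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

from . import grid


def read_microdata(
    path: str | Path,
    columns: list[str] | None = None,
    sep: str = ",",
) -> pd.DataFrame:
    """Read an event-microdata table of timestamp columns.

    Values must parse as ``yyyy-mm-dd`` or ``yyyy-mm-dd hh:mm:ss``;
    unparseable rows are reported by row number.  Requested *columns*
    (default: every column whose name starts with ``date.``) are
    returned as strings so the time-of-day resolution policy stays with
    the caller.
    """
    frame = pd.read_csv(path, sep=sep, dtype="string")
    if columns is None:
        columns = [c for c in frame.columns if c.startswith("date.")]
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in columns:
        parsed = pd.to_datetime(frame[col].str.strip(), format="mixed", errors="coerce")
        if parsed.isna().any():
            rows = frame.index[parsed.isna()].tolist()[:20]
            raise ValueError(f"{path}: unparseable {col!r} at rows {rows}")
    return frame[columns]


def write_grid(grid_frame: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    """Write a quarter grid (or rate/SAI table) as delimited text."""
    grid_frame.to_csv(path, sep=sep, index=False, float_format="%.15g")


def read_grid(path: str | Path, sep: str = ",") -> pd.DataFrame:
    """Read a quarter grid, completing missing cells with zeros."""
    frame = pd.read_csv(path, sep=sep)
    missing = [c for c in grid.KEY_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing key columns {missing}")
    col = grid.value_column(frame)
    expected = 16 * (int(frame["age"].max()) + 1)
    out = grid.complete_grid(frame)  # raises on duplicate keys
    if len(frame) < expected:
        warnings.warn(
            f"{path}: grid had {len(frame)} of {expected} cells; "
            "missing cells completed with zeros",
            stacklevel=2,
        )
    return out


def read_rate_table(path: str | Path, sep: str = ",") -> pd.DataFrame:
    """Read a crude-rate table (age, quarter.age, quarter.calendar,
    exposed, deaths, mx)."""
    frame = pd.read_csv(path, sep=sep)
    need = ["age", "quarter.age", "quarter.calendar", "exposed", "deaths"]
    missing = [c for c in need if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return frame


def read_annual_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a reference annual life table.

    Columns: ``age`` plus either ``qx`` (optionally ``ax``) or ``mx``.
    The separator is sniffed between ";" and "," when not given.
    """
    if sep is None:
        head = Path(path).read_text().splitlines()[0]
        sep = ";" if head.count(";") >= head.count(",") else ","
    frame = pd.read_csv(path, sep=sep)
    if "age" not in frame.columns or not ({"qx", "mx"} & set(frame.columns)):
        raise ValueError(
            f"{path}: annual life table needs 'age' and one of 'qx'/'mx'"
        )
    return frame
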