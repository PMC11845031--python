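"""The quarter grid: values indexed by (age, age-quarter, season-quarter).

A grid is stored as a plain :class:`pandas.DataFrame` with columns
``age``, ``quarter.age``, ``quarter.calendar`` and one value column whose
name encodes the kind: ``number.events`` for counts, ``time.exposed`` for
person-years.  A grid is always *complete*: exactly ``16 * (max_age + 1)``
rows ordered by age, then age-quarter, then season-quarter.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

KEY_COLUMNS = ["age", "quarter.age", "quarter.calendar"]
VALUE_COLUMN = {"count": "number.events", "exposure": "time.exposed"}
_KIND_OF = {v: k for k, v in VALUE_COLUMN.items()}


def value_column(grid: pd.DataFrame) -> str:
    """Name of the value column of *grid* (raises on a malformed grid)."""
    extra = [c for c in grid.columns if c in _KIND_OF]
    if len(extra) != 1:
        raise ValueError(
            f"expected exactly one value column among {sorted(_KIND_OF)}, "
            f"got columns {list(grid.columns)}"
        )
    return extra[0]


def grid_kind(grid: pd.DataFrame) -> str:
    return _KIND_OF[value_column(grid)]


def empty_grid(max_age: int, kind: str = "exposure") -> pd.DataFrame:
    """Complete all-zero grid for ages ``0..max_age``."""
    if max_age < 0:
        raise ValueError("max_age must be >= 0")
    ages = np.repeat(np.arange(max_age + 1), 16)
    r = np.tile(np.repeat(np.arange(1, 5), 4), max_age + 1)
    s = np.tile(np.arange(1, 5), 4 * (max_age + 1))
    values = np.zeros(16 * (max_age + 1))
    if kind == "count":
        values = values.astype(int)
    return pd.DataFrame(
        {
            "age": ages,
            "quarter.age": r,
            "quarter.calendar": s,
            VALUE_COLUMN[kind]: values,
        }
    )


def from_array(values: np.ndarray, kind: str = "exposure") -> pd.DataFrame:
    """Build a grid from an array of shape ``(max_age + 1, 4, 4)``."""
    values = np.asarray(values)
    if values.ndim != 3 or values.shape[1:] != (4, 4):
        raise ValueError(f"expected shape (A+1, 4, 4), got {values.shape}")
    grid = empty_grid(values.shape[0] - 1, kind)
    grid[VALUE_COLUMN[kind]] = values.reshape(-1)
    return grid


def to_array(grid: pd.DataFrame) -> np.ndarray:
    """Grid values as an array of shape ``(max_age + 1, 4, 4)``."""
    col = value_column(grid)
    g = grid.sort_values(KEY_COLUMNS, kind="stable")
    max_age = int(g["age"].max())
    if len(g) != 16 * (max_age + 1):
        raise ValueError("incomplete grid; use complete_grid first")
    return g[col].to_numpy().reshape(max_age + 1, 4, 4)


def complete_grid(grid: pd.DataFrame, max_age: int | None = None) -> pd.DataFrame:
    """Zero-fill missing (age, r, s) cells and order rows canonically."""
    col = value_column(grid)
    if grid.duplicated(KEY_COLUMNS).any():
        dups = grid.loc[grid.duplicated(KEY_COLUMNS), KEY_COLUMNS]
        raise ValueError(f"duplicate grid keys:\n{dups.to_string(index=False)}")
    top = int(grid["age"].max()) if len(grid) else 0
    if max_age is not None:
        top = max(top, max_age)
    full = empty_grid(top, _KIND_OF[col])
    merged = full.merge(grid, on=KEY_COLUMNS, how="left", suffixes=("_z", ""))
    out = full.copy()
    filled = merged[col].fillna(0)
    # keep integer counts integer; never truncate fractional values
    if pd.api.types.is_integer_dtype(grid[col]):
        filled = filled.astype(int)
    out[col] = filled
    return out


def pad_to_common_age(*grids: pd.DataFrame) -> list[pd.DataFrame]:
    """Zero-pad every grid to the maximum age present in any of them."""
    top = max(int(g["age"].max()) for g in grids)
    return [complete_grid(g, top) for g in grids]


def accumulate(cells: np.ndarray, max_age: int, kind: str = "exposure") -> pd.DataFrame:
    """Sum (age, r, s, value) rows into a complete grid.

    *cells* is a float array of shape (n, 4) with columns age, r, s, value.
    """
    arr = np.zeros((max_age + 1, 4, 4))
    if len(cells):
        x = cells[:, 0].astype(int)
        r = cells[:, 1].astype(int) - 1
        s = cells[:, 2].astype(int) - 1
        np.add.at(arr, (x, r, s), cells[:, 3])
    return from_array(arr, kind)
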