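"""Event counting per quarter cell and registration-artifact correction.

Includes the correction for the January-1 birth-date artifact: when exact
birth dates of migrants are unknown, registries often record Jan 1, which
inflates that day's count far above the daily mean and biases the
quarterly placement of lifelines.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from . import chronos, grid

logger = logging.getLogger(__name__)


def count_events_quarter(points: pd.DataFrame) -> pd.DataFrame:
    """Number of events in each (age, r, s) cell.

    *points* is a table as produced by
    :func:`quarterlife.lexis.quarterly_variables`.  The result is a
    complete count grid spanning ages 0 to the maximum observed age.
    """
    need = {"age", "quarter.age", "quarter.calendar"}
    if not need.issubset(points.columns):
        raise ValueError(f"points table must have columns {sorted(need)}")
    if len(points) == 0:
        return grid.empty_grid(0, "count")
    counted = (
        points.groupby(["age", "quarter.age", "quarter.calendar"])
        .size()
        .rename("number.events")
        .reset_index()
    )
    return grid.complete_grid(counted)


def distribute_excess(
    birth_dates: Sequence[str] | pd.Series,
    event_dates: Sequence[str] | pd.Series | None = None,
    target_day: tuple[int, int] = (1, 1),
    maximum_excess: float = 50.0,
    rng: np.random.Generator | None = None,
    max_redraws: int = 1000,
) -> pd.Series:
    """Spread an artificial birth-date spike over the rest of the year.

    For each birth year, let ``c`` be the count on the target day (Jan 1
    by default) and ``ybar`` the mean daily count over the year's other
    days.  When ``c`` exceeds ``(1 + maximum_excess/100) * ybar``, a
    uniformly chosen subsample of ``c - round(ybar)`` of that day's
    records receives new birth dates drawn uniformly over the year's
    other days.  When *event_dates* is given, redraws enforce
    birth <= event (after ``max_redraws`` failures the birth is clamped
    to the event date).  All other records pass through unchanged.
    """
    if rng is None:
        raise ValueError("distribute_excess requires an explicit rng")
    births = pd.Series(birth_dates).astype("string").str.strip().reset_index(drop=True)
    parsed = pd.to_datetime(births, format="mixed", errors="coerce")
    if parsed.isna().any():
        bad = births[parsed.isna()].head(20)
        raise ValueError(f"unparseable birth dates:\n{bad.to_string()}")
    events = None
    if event_dates is not None:
        if len(event_dates) != len(births):
            raise ValueError("event_dates not aligned with birth_dates")
        events = pd.to_datetime(
            pd.Series(event_dates).astype("string").str.strip().reset_index(drop=True),
            format="mixed",
            errors="coerce",
        )
        if events.isna().any():
            raise ValueError("unparseable event dates")
    out = births.copy()
    tmonth, tday = target_day
    for year, idx in parsed.groupby(parsed.dt.year).groups.items():
        sub = parsed.loc[idx]
        on_target = (sub.dt.month == tmonth) & (sub.dt.day == tday)
        c = int(on_target.sum())
        if c == 0:
            continue
        n_days = chronos.year_length(int(year))
        ybar = (len(sub) - c) / (n_days - 1)
        if c <= (1.0 + maximum_excess / 100.0) * ybar:
            continue
        excess = c - round(ybar)
        if excess <= 0:
            continue
        target_idx = np.asarray(idx)[on_target.to_numpy()]
        chosen = rng.choice(target_idx, size=excess, replace=False)
        # candidate days: every day of the year except the target day
        days = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
        days = days[~((days.month == tmonth) & (days.day == tday))]
        for i in chosen:
            limit = events.loc[i] if events is not None else None
            new = None
            for _ in range(max_redraws):
                cand = days[int(rng.integers(0, len(days)))]
                if limit is None or cand <= limit:
                    new = cand
                    break
            if new is None:
                new = pd.Timestamp(limit.date())
                logger.warning(
                    "row %d: no admissible redraw before event %s; "
                    "clamped birth to the event date",
                    i,
                    limit,
                )
            out.loc[i] = new.strftime("%Y-%m-%d")
    return out


def quarter_matrix(
    source: pd.DataFrame,
    min_age: int | None = None,
    max_age: int | None = None,
    decimal_digits: int | None = None,
) -> pd.DataFrame:
    """4x4 (r, s) summary of a quarter grid over an age range.

    Entry (r, s) is the sum of the grid values for ages in
    ``[min_age, max_age]``.  This is the data behind the raster summary
    plot of events/exposure by quarter.
    """
    col = grid.value_column(source)
    lo = int(source["age"].min()) if min_age is None else min_age
    hi = int(source["age"].max()) if max_age is None else max_age
    if lo > hi:
        raise ValueError(f"empty age range [{lo}, {hi}]")
    sel = source[(source["age"] >= lo) & (source["age"] <= hi)]
    if len(sel) == 0:
        raise ValueError(f"age range [{lo}, {hi}] outside the grid")
    mat = sel.pivot_table(
        index="quarter.age", columns="quarter.calendar", values=col, aggfunc="sum"
    ).reindex(index=[1, 2, 3, 4], columns=[1, 2, 3, 4], fill_value=0)
    if decimal_digits is not None:
        mat = mat.round(decimal_digits)
    mat.index.name = "quarter.age"
    mat.columns.name = "quarter.calendar"
    mat.attrs["age_range"] = (lo, hi)
    return mat
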