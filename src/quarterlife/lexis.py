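"""Placing events on the quarterly Lexis grid.

An event is located by its season (calendar) coordinate — the fraction of
the calendar year elapsed — and its age coordinate — the fractional part
of the exact age.  Both quarter indices come from the floor formulas
``r = floor(4 * coord_age) + 1`` and ``s = floor(4 * coord_time) + 1``
with lower-closed/upper-open quarter intervals, so every event maps to
exactly one (r, s) cell.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import chronos
from .chronos import DAY_SECONDS

#: column layout of the per-event table
COLUMNS = [
    "year",
    "coord.age",
    "coord.time",
    "exact.age",
    "age",
    "quarter.age",
    "quarter.calendar",
]


def mod4bar(n: int | np.ndarray) -> int | np.ndarray:
    """Modified modulo-4: the unique value in 1..4 congruent to *n* mod 4."""
    n = np.asarray(n)
    if np.any(n < 1):
        raise ValueError("mod4bar is defined for integers >= 1")
    out = (n - 1) % 4 + 1
    return int(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class LexisPoint:
    """One event on the quarterly Lexis grid."""

    year: int
    coord_age: float
    coord_time: float
    exact_age: float
    age: int
    age_quarter: int
    season_quarter: int


def _quarter(frac: float | np.ndarray) -> np.ndarray:
    """floor(4*frac)+1 clamped to 1..4 (frac in [0,1) up to rounding)."""
    q = np.floor(4.0 * np.asarray(frac)).astype(int) + 1
    return np.clip(q, 1, 4)


def locate_event(
    t_b: chronos.TimestampLike,
    t_e: chronos.TimestampLike,
    constant_year: bool = False,
) -> LexisPoint:
    """Locate a single birth/event pair on the quarterly Lexis grid."""
    t_b, t_e = chronos.as_instant(t_b), chronos.as_instant(t_e)
    age = chronos.exact_age(t_b, t_e, constant_year)
    x = int(np.floor(age))
    coord_age = age - x
    coord_time = chronos.time_coordinate(t_e)
    return LexisPoint(
        year=t_e.year,
        coord_age=coord_age,
        coord_time=coord_time,
        exact_age=age,
        age=x,
        age_quarter=int(_quarter(coord_age)),
        season_quarter=int(_quarter(coord_time)),
    )


def _parse_timestamps(
    values: Sequence[str] | pd.Series | np.ndarray,
    random: bool,
    rng: np.random.Generator | None,
    fixed_time: dt.time,
) -> np.ndarray:
    """Parse date strings to datetime64[s], resolving missing times of day.

    Entries already carrying a time ("yyyy-mm-dd hh:mm:ss") are kept as
    given; date-only entries get a uniformly random time (``random``) or
    the configured fixed time of day.  Datetime-typed input bypasses
    resolution entirely.
    """
    series = pd.Series(values).reset_index(drop=True)
    if pd.api.types.is_datetime64_any_dtype(series):
        return series.to_numpy().astype("datetime64[s]")
    text = series.astype("string").str.strip()
    parsed = pd.to_datetime(text, format="mixed", errors="coerce")
    if parsed.isna().any():
        bad = series[parsed.isna()].head(20)
        raise ValueError(f"unparseable dates at rows:\n{bad.to_string()}")
    ts = parsed.to_numpy().astype("datetime64[s]")
    dateonly = (text.str.len() <= 10).to_numpy()
    if dateonly.any():
        n = int(dateonly.sum())
        if random:
            if rng is None:
                raise ValueError("randomised time-of-day requires an rng")
            secs = rng.uniform(0.0, DAY_SECONDS, size=n).astype("int64")
        else:
            secs = np.full(
                n,
                fixed_time.hour * 3600 + fixed_time.minute * 60 + fixed_time.second,
                dtype="int64",
            )
        ts = ts.copy()
        ts[dateonly] = ts[dateonly] + secs.astype("timedelta64[s]")
    return ts


def quarterly_variables(
    birth_dates: Sequence[str] | pd.Series,
    event_dates: Sequence[str] | pd.Series,
    random_b: bool = True,
    random_e: bool = True,
    constant_year: bool = False,
    rng: np.random.Generator | None = None,
    fixed_time: dt.time = chronos.NOON,
) -> pd.DataFrame:
    """Lexis coordinates and quarter indices for a vector of events.

    Parameters
    ----------
    birth_dates, event_dates
        Equal-length vectors of timestamps, ``yyyy-mm-dd`` or
        ``yyyy-mm-dd hh:mm:ss``.  Date-only entries have their time of day
        resolved per ``random_b`` / ``random_e`` (birth first, then event,
        in record order, from the single *rng* stream).
    constant_year
        Use the constant 365.25-day year for ages instead of the
        pair-dependent (subjective) year length.

    Returns
    -------
    DataFrame with columns ``year, coord.age, coord.time, exact.age, age,
    quarter.age, quarter.calendar`` — one row per input record, in order.
    """
    if len(birth_dates) != len(event_dates):
        raise ValueError("birth_dates and event_dates differ in length")
    if len(birth_dates) == 0:
        return pd.DataFrame(columns=COLUMNS).astype(
            {"year": int, "age": int, "quarter.age": int, "quarter.calendar": int}
        )
    t_b = _parse_timestamps(birth_dates, random_b, rng, fixed_time)
    t_e = _parse_timestamps(event_dates, random_e, rng, fixed_time)
    if np.any(t_b > t_e):
        bad = np.nonzero(t_b > t_e)[0]
        raise ValueError(
            f"birth after event at rows {bad.tolist()[:50]}"
            + ("..." if len(bad) > 50 else "")
        )
    age = chronos.exact_age_vec(t_b, t_e, constant_year)
    x = np.floor(age).astype(int)
    coord_age = age - x
    coord_time = chronos.time_coordinate_vec(t_e)
    year = t_e.astype("datetime64[Y]").astype(int) + 1970
    return pd.DataFrame(
        {
            "year": year,
            "coord.age": coord_age,
            "coord.time": coord_time,
            "exact.age": age,
            "age": x,
            "quarter.age": _quarter(coord_age),
            "quarter.calendar": _quarter(coord_time),
        }
    )
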