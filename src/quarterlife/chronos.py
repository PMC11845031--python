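"""Calendar arithmetic for demographic event data.

Ages and within-year time coordinates are computed at second resolution on
the Gregorian calendar.  Two conventions for the length of an age year are
supported:

* **constant** — every year is 365.25 days long, so an exact age is simply
  the elapsed time in days divided by 365.25;
* **subjective** (default) — the length of the age year is specific to each
  birth/event pair: the weighted mean of the calendar-year lengths spanned
  by the interval, each year weighted by the fraction of it the interval
  encloses.  Under this convention the exact age equals the sum of those
  enclosed fractions, which keeps age and calendar time congruent inside
  every calendar year and makes anniversaries land on whole numbers except
  when the birth falls in a leap year.

Days are exactly 86 400 s; leap seconds are ignored (timestamps are civil).
"""

from __future__ import annotations

import calendar
import datetime as dt
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DAY_SECONDS = 86_400.0
CONSTANT_YEAR_DAYS = 365.25
#: default time-of-day used when a date carries no time information
NOON = dt.time(12, 0, 0)

TimestampLike = dt.datetime | pd.Timestamp | str


def year_length(year: int) -> int:
    """Length of a Gregorian calendar year in days (365 or 366)."""
    return 366 if calendar.isleap(year) else 365


def as_instant(value: TimestampLike) -> dt.datetime:
    """Coerce a timestamp-like value to a ``datetime`` at second resolution.

    Accepts ``datetime``, ``pandas.Timestamp`` or a string in
    ``yyyy-mm-dd`` / ``yyyy-mm-dd hh:mm:ss`` form.  Date-only strings map
    to midnight; use :func:`resolve_instant` to assign a time of day.
    """
    if isinstance(value, pd.Timestamp):
        return value.to_pydatetime().replace(microsecond=0)
    if isinstance(value, dt.datetime):
        return value.replace(microsecond=0)
    if isinstance(value, dt.date):
        return dt.datetime.combine(value, dt.time())
    if isinstance(value, str):
        text = value.strip()
        for fmt in ("%Y-%m-%d %H:%M:%S", "%Y-%m-%d"):
            try:
                return dt.datetime.strptime(text, fmt)
            except ValueError:
                continue
        raise ValueError(f"unparseable timestamp: {value!r}")
    raise TypeError(f"cannot interpret {type(value).__name__} as an instant")


def _check_order(t0: dt.datetime, t1: dt.datetime) -> None:
    if t0 > t1:
        raise ValueError(f"start instant {t0} is after end instant {t1}")


def elapsed_days(t0: TimestampLike, t1: TimestampLike) -> float:
    """Exact elapsed time between two instants, in days."""
    t0, t1 = as_instant(t0), as_instant(t1)
    _check_order(t0, t1)
    return (t1 - t0).total_seconds() / DAY_SECONDS


def time_coordinate(t: TimestampLike) -> float:
    """Fraction of the calendar year elapsed at instant *t*, in [0, 1).

    This is the calendar-axis (season) coordinate on the Lexis diagram:
    elapsed days since Jan 1 00:00:00 divided by the year's length.
    """
    t = as_instant(t)
    start = dt.datetime(t.year, 1, 1)
    return (t - start).total_seconds() / DAY_SECONDS / year_length(t.year)


def year_fractions(t0: TimestampLike, t1: TimestampLike) -> pd.DataFrame:
    """Decompose the interval [t0, t1] into per-calendar-year fractions.

    Returns a frame with one row per spanned calendar year ``a`` holding
    the year length ``l_a`` (days) and the fraction ``f_a`` of year ``a``
    enclosed in the interval.  The identity ``sum(l_a * f_a) ==
    elapsed_days(t0, t1)`` holds exactly up to float rounding.
    """
    t0, t1 = as_instant(t0), as_instant(t1)
    _check_order(t0, t1)
    rows = []
    for a in range(t0.year, t1.year + 1):
        start = max(t0, dt.datetime(a, 1, 1))
        end = min(t1, dt.datetime(a + 1, 1, 1))
        la = year_length(a)
        fa = max(0.0, (end - start).total_seconds()) / DAY_SECONDS / la
        rows.append((a, la, fa))
    return pd.DataFrame(rows, columns=["year", "length", "fraction"])


def pair_year_length(t_b: TimestampLike, t_e: TimestampLike) -> float:
    """Length (days) of the age year subjective to a birth/event pair.

    Weighted mean of the spanned calendar-year lengths, weights being the
    enclosed fractions of each year.  For a zero-length interval the birth
    year's calendar length is returned (the weighted mean is 0/0 there).
    """
    dec = year_fractions(t_b, t_e)
    total = float(dec["fraction"].sum())
    if total == 0.0:
        return float(year_length(as_instant(t_b).year))
    return float((dec["length"] * dec["fraction"]).sum()) / total


def exact_age(
    t_b: TimestampLike, t_e: TimestampLike, constant_year: bool = False
) -> float:
    """Exact age in years at the event instant.

    With ``constant_year`` the age is elapsed days over 365.25.  Otherwise
    the subjective (pair-dependent) year length applies; algebraically the
    result then equals the sum of the per-year enclosed fractions
    ``f_a``, computed here in closed form from the two time coordinates.
    """
    t_b, t_e = as_instant(t_b), as_instant(t_e)
    _check_order(t_b, t_e)
    if constant_year:
        return elapsed_days(t_b, t_e) / CONSTANT_YEAR_DAYS
    return (t_e.year - t_b.year) + time_coordinate(t_e) - time_coordinate(t_b)


def resolve_instant(
    date: TimestampLike,
    mode: str = "random",
    rng: np.random.Generator | None = None,
    fixed_time: dt.time = NOON,
) -> dt.datetime:
    """Assign a time of day to a calendar date.

    ``mode="random"`` draws the seconds within the day uniformly from
    *rng*; ``mode="fixed"`` uses *fixed_time* (noon by default).  A value
    that already carries a non-midnight time is returned unchanged only by
    callers that check for it — this function always (re)assigns.
    """
    date = as_instant(date)
    day = dt.datetime(date.year, date.month, date.day)
    if mode == "fixed":
        return dt.datetime.combine(day.date(), fixed_time)
    if mode == "random":
        if rng is None:
            raise ValueError("random mode requires an explicit rng")
        secs = float(rng.uniform(0.0, DAY_SECONDS))
        return day + dt.timedelta(seconds=int(secs))
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# vectorised counterparts (numpy datetime64[s]); used by the lexis layer
# ---------------------------------------------------------------------------

def _years_of(ts: np.ndarray) -> np.ndarray:
    return ts.astype("datetime64[Y]").astype(int) + 1970


def year_length_vec(years: np.ndarray) -> np.ndarray:
    years = np.asarray(years)
    leap = (years % 4 == 0) & ((years % 100 != 0) | (years % 400 == 0))
    return np.where(leap, 366, 365)


def time_coordinate_vec(ts: np.ndarray) -> np.ndarray:
    """Vectorised :func:`time_coordinate` over a datetime64[s] array."""
    ts = np.asarray(ts, dtype="datetime64[s]")
    starts = ts.astype("datetime64[Y]").astype("datetime64[s]")
    secs = (ts - starts) / np.timedelta64(1, "s")
    return secs / DAY_SECONDS / year_length_vec(_years_of(ts))


def exact_age_vec(
    t_b: np.ndarray, t_e: np.ndarray, constant_year: bool = False
) -> np.ndarray:
    """Vectorised :func:`exact_age` over datetime64[s] arrays."""
    t_b = np.asarray(t_b, dtype="datetime64[s]")
    t_e = np.asarray(t_e, dtype="datetime64[s]")
    if np.any(t_b > t_e):
        bad = np.nonzero(t_b > t_e)[0]
        raise ValueError(f"birth after event at rows {bad.tolist()[:20]}")
    if constant_year:
        days = (t_e - t_b) / np.timedelta64(1, "s") / DAY_SECONDS
        return days / CONSTANT_YEAR_DAYS
    return (
        (_years_of(t_e) - _years_of(t_b))
        + time_coordinate_vec(t_e)
        - time_coordinate_vec(t_b)
    )
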