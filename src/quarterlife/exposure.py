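"""Person-years at risk per (age, age-quarter, season-quarter) cell.

A lifeline is a unit-slope segment in the (calendar-time, age) plane: when
both axes are measured in fractions of the current calendar year, age and
time advance at the same rate.  The time a lifeline spends in each 1x1
quarter cell is obtained by splitting the segment at every crossing of an
age or time multiple of 1/4 and attributing the pieces to cells.  A full
calendar year therefore traverses eight quarter cells whose within-cell
times alternate between ``r0/4 - coord_age`` and ``coord_age - (r0-1)/4``,
where ``r0`` is the age quarter occupied at the start of the year.

Exposure grids are built for population stocks (anchored at either end of
the year), for events followed to the end of the year ("ins"), for events
preceded from the start of the year ("outs"), and for newborns followed
from birth; :func:`combine_exposures` assembles them into the total
exposure-to-risk grid.
"""

from __future__ import annotations

import datetime as dt
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import chronos, grid, lexis

_EPS = 1e-12
#: tolerance below which a boundary-touching cell visit is dropped
_MIN_VISIT = 1e-12


def traverse_segment(
    coord_time0: float,
    coord_age0: float,
    coord_time1: float,
    base_age: int,
) -> list[tuple[int, int, int, float]]:
    """Split a lifeline segment at quarter boundaries.

    The segment runs from calendar-time fraction ``coord_time0`` (where
    the individual has exact age ``base_age + coord_age0``) to
    ``coord_time1``, within a single calendar year.  Returns a list of
    ``(age, r, s, time)`` visits; the times sum to
    ``coord_time1 - coord_time0``.  Zero-length visits at touched
    boundaries are dropped.
    """
    if not (
        -_EPS <= coord_time0 <= coord_time1 + _EPS and coord_time1 <= 1.0 + _EPS
    ):
        raise ValueError(
            f"malformed time coordinates ({coord_time0}, {coord_time1})"
        )
    if not (-_EPS <= coord_age0 < 1.0 + _EPS):
        raise ValueError(f"malformed age coordinate {coord_age0}")
    t = float(coord_time0)
    t1 = float(coord_time1)
    g0 = base_age + float(coord_age0)  # total exact age at t
    out: list[tuple[int, int, int, float]] = []
    while t1 - t > _MIN_VISIT:
        g = g0 + (t - coord_time0)
        next_t = (math.floor(t / 0.25 + 1e-9) + 1) * 0.25
        next_g = (math.floor(g / 0.25 + 1e-9) + 1) * 0.25
        t_next = min(t1, next_t, t + (next_g - g))
        if t_next - t > _MIN_VISIT:
            tm = 0.5 * (t + t_next)
            gm = g0 + (tm - coord_time0)
            x = int(gm)
            r = min(int(4.0 * (gm - x)), 3) + 1
            s = min(int(4.0 * tm), 3) + 1
            out.append((x, r, s, t_next - t))
        t = t_next
    return out


def _accumulate_paths(
    paths: Sequence[list[tuple[int, int, int, float]]],
) -> pd.DataFrame:
    cells = [c for p in paths for c in p]
    if not cells:
        return grid.empty_grid(0, "exposure")
    arr = np.asarray(cells, dtype=float)
    max_age = int(arr[:, 0].max())
    return grid.accumulate(arr, max_age, "exposure")


def _full_year_grid(start_ages: np.ndarray) -> pd.DataFrame:
    """Vectorised full-year traversal for exact ages at the year start.

    Implements the eight-quarter alternation in closed form: person with
    start-of-year age quarter ``r0`` visits ``(r0, 1), (r0+1, 1),
    (r0+1, 2), ...`` (mod-4 on the quarter index, the integer age rolling
    forward when the quarter wraps), the visit lengths alternating between
    ``r0/4 - coord_age`` and ``coord_age - (r0-1)/4``.
    """
    y = np.asarray(start_ages, dtype=float)
    if len(y) == 0:
        return grid.empty_grid(0, "exposure")
    if np.any(y < -_EPS):
        raise ValueError("negative exact age in stock")
    x0 = np.floor(y).astype(int)
    c = y - x0
    r0 = np.minimum(np.floor(4.0 * c).astype(int), 3) + 1
    a = r0 / 4.0 - c
    b = 0.25 - a
    max_age = int((x0 + (c > _MIN_VISIT)).max())
    arr = np.zeros((max_age + 1, 4, 4))
    for k in range(8):
        s_k = k // 2 + 1
        off = (k + 1) // 2
        rr = r0 + off
        r_k = (rr - 1) % 4 + 1
        x_k = x0 + (rr > 4)
        length = a if k % 2 == 0 else b
        np.add.at(arr, (x_k, r_k - 1, s_k - 1), length)
    return grid.from_array(arr, "exposure")


def time_exposed_stock(
    birth_dates: Sequence[str] | pd.Series,
    year: int,
    anchoring: str = "forward",
    constant_year: bool = False,
    random_b: bool = True,
    rng: np.random.Generator | None = None,
    fixed_time: dt.time = chronos.NOON,
) -> pd.DataFrame:
    """Exposure grid of a population stock over a calendar year.

    ``anchoring="forward"`` assumes the stock was counted at 00:00 Jan 1
    of *year* and accumulates a full year forward for every member.
    ``anchoring="backward"`` assumes a count at 24:00 Dec 31; members born
    before the year contribute the full year, members born within it
    contribute from their birth instant.
    """
    if anchoring not in ("forward", "backward"):
        raise ValueError(f"unknown anchoring {anchoring!r}")
    t_b = lexis._parse_timestamps(birth_dates, random_b, rng, fixed_time)
    if len(t_b) == 0:
        return grid.empty_grid(0, "exposure")
    anchor_year = year if anchoring == "forward" else year + 1
    anchor = np.datetime64(f"{anchor_year}-01-01T00:00:00", "s")
    if np.any(t_b > anchor):
        bad = np.nonzero(t_b > anchor)[0]
        raise ValueError(f"births after the anchor instant at rows {bad.tolist()[:20]}")
    anchors = np.full(len(t_b), anchor)
    ages = chronos.exact_age_vec(t_b, anchors, constant_year)
    if anchoring == "forward":
        return _full_year_grid(ages)
    # backward: age at year end; lifeline within the year starts at age-1,
    # or at birth for those born during the year
    g0 = ages - 1.0
    whole = g0 >= -_EPS
    grids = [_full_year_grid(np.clip(g0[whole], 0.0, None))]
    partial_paths = [
        traverse_segment(1.0 - age, 0.0, 1.0, 0) for age in ages[~whole]
    ]
    if partial_paths:
        grids.append(_accumulate_paths(partial_paths))
    padded = grid.pad_to_common_age(*grids)
    out = padded[0]
    for g in padded[1:]:
        out["time.exposed"] = out["time.exposed"] + g["time.exposed"]
    return out


def _points_rows(points: pd.DataFrame) -> np.ndarray:
    need = {"coord.age", "coord.time", "age"}
    if not need.issubset(points.columns):
        raise ValueError(f"points table must have columns {sorted(need)}")
    return points[["coord.time", "coord.age", "age"]].to_numpy(dtype=float)


def time_exposed_ins(points: pd.DataFrame) -> pd.DataFrame:
    """Exposure from each event instant to the end of its calendar year."""
    paths = [
        traverse_segment(t, ca, 1.0, int(x)) for t, ca, x in _points_rows(points)
    ]
    return _accumulate_paths(paths)


def time_exposed_outs(points: pd.DataFrame) -> pd.DataFrame:
    """Exposure from the start of the calendar year to each event instant.

    For individuals born within the year (age coordinate smaller than the
    time coordinate at age 0) the lifeline is followed from birth instead
    of Jan 1 — there is no pre-birth exposure.
    """
    paths = []
    for t, ca, x in _points_rows(points):
        g_start = x + ca - t
        if g_start >= -_EPS:
            g_start = max(g_start, 0.0)
            base = int(g_start)
            paths.append(traverse_segment(0.0, g_start - base, t, base))
        else:
            paths.append(traverse_segment(t - ca, 0.0, t, 0))
    return _accumulate_paths(paths)


def time_exposed_newborns(
    birth_dates: Sequence[str] | pd.Series,
    random_b: bool = True,
    rng: np.random.Generator | None = None,
    fixed_time: dt.time = chronos.NOON,
) -> pd.DataFrame:
    """Exposure of newborns from birth to the end of their birth year.

    All births must fall in the same calendar year; the grid is nonzero
    only at age 0.
    """
    t_b = lexis._parse_timestamps(birth_dates, random_b, rng, fixed_time)
    if len(t_b) == 0:
        return grid.empty_grid(0, "exposure")
    years = t_b.astype("datetime64[Y]")
    if len(np.unique(years)) > 1:
        raise ValueError("newborn births span more than one calendar year")
    coords = chronos.time_coordinate_vec(t_b)
    paths = [traverse_segment(t, 0.0, 1.0, 0) for t in coords]
    return _accumulate_paths(paths)


@dataclass
class ExposureComponents:
    """The exposure grids combined into the total exposure-to-risk L.

    With forward anchoring the immigrant/emigrant/death grids are
    "ins"-type (event to year end) and a newborn grid is required; with
    backward anchoring they are "outs"-type (year start to event) and
    newborns are implicit in the year-end stock.
    """

    stock: pd.DataFrame
    immigrants: pd.DataFrame | None = None
    emigrants: pd.DataFrame | None = None
    deaths: pd.DataFrame | None = None
    newborns: pd.DataFrame | None = None
    anchoring: str = "forward"


def combine_exposures(components: ExposureComponents) -> pd.DataFrame:
    """Total exposure grid from its stock/flow components.

    forward:  L = L(P) + L(I) - L(E) - L(D) + L(B)
    backward: L = L(P) - L(I) + L(E) + L(D)

    Grids are zero-padded to the common maximum age before combining.
    Negative resulting cells (internally inconsistent inputs) trigger a
    warning listing the offending cells.
    """
    anch = components.anchoring
    if anch not in ("forward", "backward"):
        raise ValueError(f"unknown anchoring {anch!r}")
    zero = grid.empty_grid(0, "exposure")
    parts = {
        "P": components.stock,
        "I": components.immigrants if components.immigrants is not None else zero,
        "E": components.emigrants if components.emigrants is not None else zero,
        "D": components.deaths if components.deaths is not None else zero,
        "B": components.newborns if components.newborns is not None else zero,
    }
    padded = dict(zip(parts, grid.pad_to_common_age(*parts.values())))
    arrs = {k: grid.to_array(v) for k, v in padded.items()}
    if anch == "forward":
        total = arrs["P"] + arrs["I"] - arrs["E"] - arrs["D"] + arrs["B"]
    else:
        total = arrs["P"] - arrs["I"] + arrs["E"] + arrs["D"]
    if np.any(total < -1e-9):
        bad = np.argwhere(total < -1e-9)
        cells = [(int(x), int(r) + 1, int(s) + 1) for x, r, s in bad[:20]]
        warnings.warn(
            f"negative exposure in cells (age, r, s): {cells}; "
            "input grids are internally inconsistent",
            stacklevel=2,
        )
    return grid.from_array(total, "exposure")
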