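"""Crude death rates, seasonal-ageing indexes and quarterly life tables.

The crude central death rate of a quarter cell is deaths over
person-years of exposure, m^{s,r}_x = D^{s,r}_x / L^{s,r}_x; the annual
rate at age x is the same ratio of the cell sums and is therefore the
exposure-weighted mean of the sixteen quarterly rates.

Seasonal-ageing indexes (SAIs) gamma_rs(x) model the multiplicative
deviation of each quarterly rate from the annual rate of the same age,

    log(m^{s,r}_{x,a} / m_{x,a}) = log(gamma_rs(x)) + noise ,

fitted over several years a.  After estimation the indexes are rescaled
so that, at every age, the exposure-weighted mean over the sixteen cells
is one (which makes annual rates recoverable from quarterly ones), and
optionally graduated across ages.  Applying the SAIs to a reference
annual life table yields four quarterly life tables, one per season of
birth: an individual born in season s0 who is in age quarter r lives it
during calendar season mod4bar(s0 + r - 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import grid
from .exposure import ExposureComponents, combine_exposures
from .lexis import mod4bar

RATE_COLUMNS = [
    "age",
    "quarter.age",
    "quarter.calendar",
    "exposed",
    "deaths",
    "mx",
]


def crude_mx(
    components: ExposureComponents | pd.DataFrame,
    death_counts: pd.DataFrame,
) -> pd.DataFrame:
    """Crude quarterly death rates from exposure components and deaths.

    *components* is either an :class:`ExposureComponents` bundle (total
    exposure is assembled internally) or an already-combined exposure
    grid.  Returns a complete table with columns ``age, quarter.age,
    quarter.calendar, exposed, deaths, mx``; ``mx`` is NaN where the cell
    has no exposure (flagged with a warning when deaths were recorded
    there).
    """
    if isinstance(components, ExposureComponents):
        total = combine_exposures(components)
    else:
        total = components
    total, deaths = grid.pad_to_common_age(total, death_counts)
    out = total.rename(columns={"time.exposed": "exposed"})
    out["deaths"] = deaths["number.events"].to_numpy()
    L = out["exposed"].to_numpy(dtype=float)
    D = out["deaths"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.where(L > 0, D / np.where(L > 0, L, 1.0), np.nan)
    orphan = (L == 0) & (D > 0)
    if orphan.any():
        cells = out.loc[orphan, ["age", "quarter.age", "quarter.calendar"]]
        warnings.warn(
            f"deaths recorded in cells with zero exposure; rate undefined:\n"
            f"{cells.to_string(index=False)}",
            stacklevel=2,
        )
    out["mx"] = m
    return out[RATE_COLUMNS]


def annual_rates(rate_table: pd.DataFrame) -> pd.DataFrame:
    """Annual exposure, deaths and central rate by age (cell sums)."""
    agg = rate_table.groupby("age", as_index=False)[["exposed", "deaths"]].sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        agg["mx"] = np.where(agg["exposed"] > 0, agg["deaths"] / agg["exposed"], np.nan)
    return agg


@dataclass
class SAITable:
    """Estimated seasonal-ageing indexes.

    ``cells`` holds the age x age-quarter x season-quarter indexes
    (columns ``age, quarter.age, quarter.calendar, SAI``); the optional
    marginal tables collapse the grid over the season (``margin_age``,
    by (age, r)) or over the age quarter (``margin_season``, by (age, s)).
    """

    cells: pd.DataFrame
    margin_age: pd.DataFrame | None = None
    margin_season: pd.DataFrame | None = None
    years: tuple = ()
    smooth_window: int = 1

    def values(self) -> np.ndarray:
        """SAIs as an array of shape (n_ages, 4, 4)."""
        n = len(self.cells) // 16
        return self.cells["SAI"].to_numpy().reshape(n, 4, 4)


def _adjust(loggamma: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Rescale per age so the weighted mean of gamma over cells is 1."""
    g = np.exp(loggamma)
    w = weights.reshape(g.shape[0], -1)
    g2 = g.reshape(g.shape[0], -1)
    wsum = w.sum(axis=1, keepdims=True)
    wn = np.where(wsum > 0, w / np.where(wsum > 0, wsum, 1.0), 1.0 / w.shape[1])
    mean = (wn * g2).sum(axis=1, keepdims=True)
    return loggamma - np.log(mean).reshape(-1, *([1] * (loggamma.ndim - 1)))


def _smooth_ages(loggamma: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average across ages (axis 0), truncated at ends."""
    if window <= 1:
        return loggamma
    half = window // 2
    n = loggamma.shape[0]
    out = np.empty_like(loggamma)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = loggamma[lo:hi].mean(axis=0)
    return out


def _sai_from_arrays(
    rates: np.ndarray,  # (T, A, k) quarterly-level rates
    annual: np.ndarray,  # (T, A) annual rates
    exposure: np.ndarray,  # (T, A, k) exposures
    smooth_window: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw-fit, adjust and smooth SAIs; returns (gamma, pooled weights)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        logratio = np.log(rates / annual[:, :, None])
    valid = np.isfinite(logratio)
    n_valid = valid.sum(axis=0)
    summed = np.where(valid, logratio, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        loggamma = np.where(n_valid > 0, summed / np.maximum(n_valid, 1), 0.0)
    if np.any(n_valid == 0):
        warnings.warn(
            f"{int((n_valid == 0).sum())} cells had no year with a defined "
            "positive rate; their SAI is imputed as 1 before smoothing",
            stacklevel=3,
        )
    pooled = exposure.sum(axis=0)
    loggamma = _adjust(loggamma, pooled)
    if smooth_window > 1:
        loggamma = _smooth_ages(loggamma, smooth_window)
        loggamma = _adjust(loggamma, pooled)
    return np.exp(loggamma), pooled


def _stack(tables: list[pd.DataFrame], by: list[str]) -> tuple[np.ndarray, ...]:
    """Aggregate rate tables over the omitted quarter axis and stack years."""
    rates, annual, exposure = [], [], []
    for t in tables:
        agg = t.groupby(["age"] + by, as_index=False)[["exposed", "deaths"]].sum()
        piv_L = agg.pivot_table(index="age", columns=by, values="exposed").to_numpy()
        piv_D = agg.pivot_table(index="age", columns=by, values="deaths").to_numpy()
        ann = annual_rates(t)
        with np.errstate(divide="ignore", invalid="ignore"):
            rates.append(np.where(piv_L > 0, piv_D / np.where(piv_L > 0, piv_L, 1), np.nan))
        annual.append(ann["mx"].to_numpy())
        exposure.append(piv_L)
    return np.stack(rates), np.stack(annual), np.stack(exposure)


def compute_SAI(
    rate_tables: Sequence[pd.DataFrame],
    margins: bool = False,
    smooth_window: int = 5,
) -> SAITable:
    """Estimate seasonal-ageing indexes from yearly crude-rate tables.

    Parameters
    ----------
    rate_tables
        At least two tables as produced by :func:`crude_mx`, one per
        year, on a common age range (shorter tables are zero-padded).
    margins
        Also estimate the marginal SAIs by (age, age-quarter) and by
        (age, season-quarter), from rates aggregated over the other axis.
    smooth_window
        Width (in ages) of the centered geometric moving average used to
        graduate the indexes across ages; ``1`` disables smoothing.

    The raw index of a cell is the geometric mean over years of the
    ratio of the quarterly to the annual rate, excluding years where
    either is zero or undefined; indexes are then rescaled per age to
    pooled-exposure-weighted mean one (re-applied after smoothing).
    """
    tables = list(rate_tables)
    if len(tables) < 2:
        raise ValueError("compute_SAI requires at least two yearly rate tables")
    years = tuple(t.attrs.get("year", i) for i, t in enumerate(tables))
    top = max(int(t["age"].max()) for t in tables)
    padded = []
    for t in tables:
        base = grid.empty_grid(top, "exposure").drop(columns=["time.exposed"])
        m = base.merge(t, on=grid.KEY_COLUMNS, how="left")
        m[["exposed", "deaths"]] = m[["exposed", "deaths"]].fillna(0.0)
        padded.append(m)
    rates, annual, L = _stack(padded, ["quarter.age", "quarter.calendar"])
    gamma, pooled = _sai_from_arrays(rates, annual, L, smooth_window)
    cells = grid.empty_grid(top, "exposure").drop(columns=["time.exposed"])
    cells["SAI"] = gamma.reshape(-1)
    result = SAITable(cells=cells, years=years, smooth_window=smooth_window)
    if margins:
        for by, attr in (
            (["quarter.age"], "margin_age"),
            (["quarter.calendar"], "margin_season"),
        ):
            r, a, e = _stack(padded, by)
            g, _ = _sai_from_arrays(r, a, e, smooth_window)
            frame = pd.DataFrame(
                {
                    "age": np.repeat(np.arange(top + 1), 4),
                    by[0]: np.tile(np.arange(1, 5), top + 1),
                    "SAI": g.reshape(-1),
                }
            )
            setattr(result, attr, frame)
    return result


def qx_to_mx(q_x: float | np.ndarray, a_x: float | np.ndarray = 0.5):
    """Central death rate from an annual death probability.

    Standard actuarial conversion ``m = q / (1 - (1 - a) q)`` where *a*
    is the average fraction of the year lived by those dying.
    """
    q = np.asarray(q_x, dtype=float)
    a = np.asarray(a_x, dtype=float)
    if np.any((q < 0) | (q >= 1)):
        raise ValueError("q_x must lie in [0, 1)")
    if np.any((a <= 0) | (a > 1)):
        raise ValueError("a_x must lie in (0, 1]")
    out = q / (1.0 - (1.0 - a) * q)
    return float(out) if out.ndim == 0 else out


def quarterly_q_from_m(m: float | np.ndarray):
    """Quarterly death probability from a quarterly central rate.

    ``q = m / (4 + m/2)``: the dying contribute half a quarter of
    exposure.  The probability is below one for every rate under 8
    per person-year; rates at or above 8 are flagged and clamped.
    """
    m = np.asarray(m, dtype=float)
    if np.any(m < 0):
        raise ValueError("quarterly rate must be non-negative")
    if np.any(m >= 8.0):
        warnings.warn(
            "quarterly central rate >= 8/person-year implies a death "
            "probability >= 1; clamping",
            stacklevel=2,
        )
        m = np.minimum(m, 8.0 - 1e-9)
    out = m / (4.0 + 0.5 * m)
    return float(out) if out.ndim == 0 else out


def annual_to_quarterly(annual: pd.DataFrame, sais: SAITable) -> pd.DataFrame:
    """Four birth-season quarterly life tables from an annual life table.

    *annual* has columns ``age`` plus either ``mx`` or ``qx`` (optionally
    with ``ax``, the average fraction of the year lived by the dying;
    0.5 when absent).  For each age x and age quarter r the quarterly
    rate in the table of birth season s0 is ``m_x * gamma_rs(x)`` with
    ``s = mod4bar(s0 + r - 1)``, and the probability follows from
    :func:`quarterly_q_from_m`.

    Returns the ten-column layout: ``age, quarter.age``, then ``mx.s1`` …
    ``mx.s4`` and ``qx.s1`` … ``qx.s4`` (one column per season of birth).
    """
    annual = annual.copy()
    if "mx" in annual.columns:
        m_x = annual["mx"].to_numpy(dtype=float)
    elif "qx" in annual.columns:
        a_x = (
            annual["ax"].to_numpy(dtype=float)
            if "ax" in annual.columns
            else np.full(len(annual), 0.5)
        )
        m_x = qx_to_mx(annual["qx"].to_numpy(dtype=float), a_x)
    else:
        raise ValueError("annual life table needs an 'mx' or 'qx' column")
    ages = annual["age"].to_numpy(dtype=int)
    gam = sais.values()
    sai_ages = sais.cells["age"].unique()
    missing = set(ages) - set(int(a) for a in sai_ages)
    if missing:
        raise ValueError(f"SAI table does not cover ages {sorted(missing)[:10]}")
    rows = []
    for age, mx in zip(ages, m_x):
        g_age = gam[int(age)]
        for r in range(1, 5):
            row = {"age": int(age), "quarter.age": r}
            for s0 in range(1, 5):
                s = mod4bar(s0 + r - 1)
                m_q = mx * g_age[r - 1, s - 1]
                row[f"mx.s{s0}"] = m_q
                row[f"qx.s{s0}"] = quarterly_q_from_m(m_q)
            rows.append(row)
    cols = (
        ["age", "quarter.age"]
        + [f"mx.s{s0}" for s0 in range(1, 5)]
        + [f"qx.s{s0}" for s0 in range(1, 5)]
    )
    return pd.DataFrame(rows, columns=cols)
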