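"""Synthetic demographic microdata with known seasonal-ageing structure.

The generator emulates one calendar year of event registration for a
population whose mortality follows piecewise-constant quarterly hazards
``m_x * gamma_rs(x)`` along each lifeline — the exact data-generating
model under which quarterly central rates are deaths over exposure cell
by cell.  Stock members are placed so that their exact ages at the start
of the year match a prescribed age schedule; deaths are drawn by
inverting the cumulative hazard along the eight quarter cells each
lifeline traverses; migrations (optional) are uniform within the year.
Every draw comes from a single seeded generator, so a bundle is fully
reproducible.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from . import chronos
from .exposure import traverse_segment

_FMT = "%Y-%m-%d %H:%M:%S"

#: quarterly multipliers (r, s) with excess winter (s=1) and deficit
#: summer (s=3) mortality; exposure-weighted mean 1 at every age
SEASONAL_PATTERN = np.tile(np.array([1.2, 1.0, 0.8, 1.0]), (4, 1))


@dataclass
class SimulationConfig:
    """Study conditions for one simulated calendar year.

    ``ages``/``stock_by_age`` give the integer ages and sizes of the
    year-start stock; ``annual_mx`` the annual hazard at each age of
    ``ages`` (the hazard is clamped to the schedule ends for ages just
    outside it, e.g. the year into which the oldest members age).
    ``gamma`` is a (4, 4) array of quarterly multipliers indexed (r, s),
    or a callable age -> (4, 4) array; its exposure-weighted mean per age
    must be ~1 for the rates to aggregate back to ``annual_mx``.
    """

    year: int = 2006
    ages: np.ndarray = field(default_factory=lambda: np.arange(75, 85))
    stock_by_age: np.ndarray = field(default_factory=lambda: np.full(10, 20_000))
    annual_mx: np.ndarray = field(
        default_factory=lambda: 0.15 * np.exp(0.08 * np.arange(10))
    )
    gamma: np.ndarray | Callable[[int], np.ndarray] = field(
        default_factory=lambda: SEASONAL_PATTERN.copy()
    )
    n_births: int = 0
    birth_mx: float = 0.004
    immigration_rate: float = 0.0
    emigration_rate: float = 0.0
    seed: int = 0

    def gamma_at(self, age: int) -> np.ndarray:
        g = self.gamma(age) if callable(self.gamma) else self.gamma
        return np.asarray(g, dtype=float)

    def mx_at(self, age: int | np.ndarray) -> np.ndarray:
        ages = np.asarray(self.ages)
        idx = np.clip(
            np.searchsorted(ages, np.asarray(age)), 0, len(ages) - 1
        )
        return np.asarray(self.annual_mx)[idx]

    def validate(self) -> None:
        if np.any(np.asarray(self.stock_by_age) < 0) or self.n_births < 0:
            raise ValueError("population sizes must be non-negative")
        if len(self.ages) != len(self.stock_by_age) or len(self.ages) != len(
            self.annual_mx
        ):
            raise ValueError("ages, stock_by_age and annual_mx must align")
        if min(self.immigration_rate, self.emigration_rate) < 0:
            raise ValueError("migration intensities must be non-negative")


@dataclass
class MicrodataBundle:
    """One simulated year of event microdata (all dates as strings)."""

    stock: pd.DataFrame  # year-start stock: date.birth
    births: pd.DataFrame  # newborns of the year: date.birth
    deaths: pd.DataFrame  # date.birth, date.event
    immigrants: pd.DataFrame  # date.birth, date.event
    emigrants: pd.DataFrame  # date.birth, date.event
    end_stock: pd.DataFrame  # alive at year end: date.birth
    config: SimulationConfig | None = None


def _instant_in_year(year: int, frac: np.ndarray) -> np.ndarray:
    """Calendar-year fractions to datetime64[s] instants within *year*."""
    start = np.datetime64(f"{year}-01-01T00:00:00", "s")
    total = chronos.year_length(year) * chronos.DAY_SECONDS
    secs = np.floor(np.asarray(frac) * total).astype("int64")
    return start + secs.astype("timedelta64[s]")


def _fmt(ts: np.ndarray) -> pd.Series:
    return pd.Series(pd.DatetimeIndex(ts).strftime(_FMT))


def _segments_full_year(start_age: np.ndarray):
    """Vectorised eight-cell segment geometry for full-year lifelines.

    Returns (lengths, x, r, s) arrays of shape (n, 8) following the
    quarter-cell alternation from the start-of-year age quarter.
    """
    y = np.asarray(start_age, dtype=float)
    x0 = np.floor(y).astype(int)
    c = y - x0
    r0 = np.minimum(np.floor(4.0 * c).astype(int), 3) + 1
    a = r0 / 4.0 - c
    b = 0.25 - a
    k = np.arange(8)
    s = k // 2 + 1
    off = (k + 1) // 2
    rr = r0[:, None] + off[None, :]
    r = (rr - 1) % 4 + 1
    x = x0[:, None] + (rr > 4)
    lengths = np.where(k % 2 == 0, a[:, None], b[:, None])
    s = np.broadcast_to(s, lengths.shape)
    return lengths, x, r, s


def _death_times(
    lengths: np.ndarray,
    hazards: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Death time (year fraction from segment start) or inf if surviving.

    Inverts the piecewise-constant cumulative hazard along the segments
    against a unit-exponential draw per person.
    """
    H = lengths * hazards
    cum = np.cumsum(H, axis=1)
    E = rng.exponential(1.0, size=lengths.shape[0])
    total = cum[:, -1]
    died = E < total
    kdx = np.minimum((cum < E[:, None]).sum(axis=1), lengths.shape[1] - 1)
    prev = np.where(kdx > 0, np.take_along_axis(cum, (kdx - 1)[:, None], 1)[:, 0], 0.0)
    lam = np.take_along_axis(hazards, kdx[:, None], 1)[:, 0]
    seg_start = np.cumsum(lengths, axis=1) - lengths
    start_k = np.take_along_axis(seg_start, kdx[:, None], 1)[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        within = np.where(lam > 0, (E - prev) / np.where(lam > 0, lam, 1.0), np.inf)
    t = np.where(died, start_k + within, np.inf)
    return t


def _hazards_for(config: SimulationConfig, x: np.ndarray, r: np.ndarray, s: np.ndarray):
    base = config.mx_at(x)
    gam = np.empty_like(base, dtype=float)
    for age in np.unique(x):
        g = config.gamma_at(int(age))
        mask = x == age
        gam[mask] = g[r[mask] - 1, s[mask] - 1]
    return base * gam


def simulate_population(config: SimulationConfig) -> MicrodataBundle:
    """Simulate one year of births, deaths and (optional) migrations."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    year = config.year

    # --- year-start stock: births placed so year-start age is in [x, x+1)
    birth_ts = []
    for age, n in zip(config.ages, config.stock_by_age):
        b_year = year - int(age) - 1
        u = rng.uniform(0.0, 1.0, size=int(n))
        total = chronos.year_length(b_year) * chronos.DAY_SECONDS
        secs = 1 + np.floor(u * (total - 2)).astype("int64")
        start = np.datetime64(f"{b_year}-01-01T00:00:00", "s")
        birth_ts.append(start + secs.astype("timedelta64[s]"))
    stock_ts = (
        np.concatenate(birth_ts) if birth_ts else np.empty(0, "datetime64[s]")
    )
    anchor = np.full(len(stock_ts), np.datetime64(f"{year}-01-01T00:00:00", "s"))
    start_age = (
        chronos.exact_age_vec(stock_ts, anchor) if len(stock_ts) else np.empty(0)
    )

    deaths_b, deaths_e = [], []
    emi_b, emi_e = [], []
    survivors = np.ones(len(stock_ts), dtype=bool)

    if len(stock_ts):
        lengths, x, r, s = _segments_full_year(start_age)
        hazards = _hazards_for(config, x, r, s)
        t_death = _death_times(lengths, hazards, rng)
        if config.emigration_rate > 0:
            t_emi = rng.exponential(1.0 / config.emigration_rate, len(stock_ts))
        else:
            t_emi = np.full(len(stock_ts), np.inf)
        dies = (t_death < 1.0) & (t_death <= t_emi)
        leaves = (t_emi < 1.0) & ~dies
        survivors = ~(dies | leaves)
        deaths_b.append(stock_ts[dies])
        deaths_e.append(_instant_in_year(year, t_death[dies]))
        emi_b.append(stock_ts[leaves])
        emi_e.append(_instant_in_year(year, t_emi[leaves]))

    # --- newborns of the year
    births_ts = np.empty(0, "datetime64[s]")
    newborn_alive = np.empty(0, dtype=bool)
    if config.n_births > 0:
        u = rng.uniform(0.0, 1.0, size=config.n_births)
        births_ts = _instant_in_year(year, u)
        tc = chronos.time_coordinate_vec(births_ts)
        newborn_alive = np.ones(config.n_births, dtype=bool)
        g0 = config.gamma_at(0)
        for i, t0 in enumerate(tc):
            segs = traverse_segment(float(t0), 0.0, 1.0, 0)
            lens = np.array([[c[3] for c in segs]])
            lam = np.array(
                [[config.birth_mx * g0[c[1] - 1, c[2] - 1] for c in segs]]
            )
            td = _death_times(lens, lam, rng)[0]
            if np.isfinite(td):
                newborn_alive[i] = False
                deaths_b.append(births_ts[i : i + 1])
                deaths_e.append(_instant_in_year(year, np.array([t0 + td])))

    # --- immigrants: uniform arrival, ages uniform over the stock range
    immi_b = np.empty(0, "datetime64[s]")
    immi_e = np.empty(0, "datetime64[s]")
    immi_alive = np.empty(0, dtype=bool)
    if config.immigration_rate > 0 and len(stock_ts):
        n_immi = rng.poisson(config.immigration_rate * len(stock_ts))
        arr_t = rng.uniform(0.0, 1.0, n_immi)
        age_at = rng.uniform(config.ages[0], config.ages[-1] + 1.0, n_immi)
        immi_e = _instant_in_year(year, arr_t)
        tc_e = chronos.time_coordinate_vec(immi_e)
        x_im = np.floor(age_at).astype(int)
        tc_b = tc_e - (age_at - x_im)
        b_year = year - x_im
        wrap = tc_b < 0
        tc_b = np.where(wrap, tc_b + 1.0, tc_b)
        b_year = np.where(wrap, b_year - 1, b_year)
        immi_b = np.array(
            [
                _instant_in_year(int(by), np.array([tb]))[0]
                for by, tb in zip(b_year, tc_b)
            ],
            dtype="datetime64[s]",
        )
        immi_alive = np.ones(n_immi, dtype=bool)
        for i in range(n_immi):
            segs = traverse_segment(float(tc_e[i]), float(age_at[i] % 1.0), 1.0, int(x_im[i]))
            if not segs:
                continue
            lens = np.array([[c[3] for c in segs]])
            lam = np.array(
                [
                    [
                        config.mx_at(c[0]) * config.gamma_at(c[0])[c[1] - 1, c[2] - 1]
                        for c in segs
                    ]
                ]
            )
            td = _death_times(lens, lam, rng)[0]
            if np.isfinite(td):
                immi_alive[i] = False
                deaths_b.append(immi_b[i : i + 1])
                deaths_e.append(_instant_in_year(year, np.array([tc_e[i] + td])))

    death_b = (
        np.concatenate(deaths_b) if deaths_b else np.empty(0, "datetime64[s]")
    )
    death_e = (
        np.concatenate(deaths_e) if deaths_e else np.empty(0, "datetime64[s]")
    )
    emib = np.concatenate(emi_b) if emi_b else np.empty(0, "datetime64[s]")
    emie = np.concatenate(emi_e) if emi_e else np.empty(0, "datetime64[s]")

    end_ts = np.concatenate(
        [stock_ts[survivors], births_ts[newborn_alive], immi_b[immi_alive]]
    )
    return MicrodataBundle(
        stock=pd.DataFrame({"date.birth": _fmt(stock_ts)}),
        births=pd.DataFrame({"date.birth": _fmt(births_ts)}),
        deaths=pd.DataFrame(
            {"date.birth": _fmt(death_b), "date.event": _fmt(death_e)}
        ),
        immigrants=pd.DataFrame(
            {"date.birth": _fmt(immi_b), "date.event": _fmt(immi_e)}
        ),
        emigrants=pd.DataFrame(
            {"date.birth": _fmt(emib), "date.event": _fmt(emie)}
        ),
        end_stock=pd.DataFrame({"date.birth": _fmt(end_ts)}),
        config=config,
    )


def spiked_birth_dates(
    year: int = 2005,
    base_per_day: int = 10,
    spike: int = 390,
    target_day: tuple[int, int] = (1, 1),
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Birth dates uniform over a year plus a target-day registration spike.

    Every day of *year* receives exactly ``base_per_day`` births, and the
    target day ``spike`` extra ones — the artifact that
    :func:`quarterlife.events.distribute_excess` removes.  The order of
    the records is shuffled with *rng* (or left grouped when ``None``).
    """
    days = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    dates = np.repeat(days.strftime("%Y-%m-%d").to_numpy(), base_per_day)
    target = f"{year}-{target_day[0]:02d}-{target_day[1]:02d}"
    dates = np.concatenate([dates, np.repeat(target, spike)])
    if rng is not None:
        rng.shuffle(dates)
    return pd.Series(dates)
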