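"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from quarterlife import grid


@pytest.fixture
def rng():
    return np.random.default_rng(20_060_101)


def integrate_lifeline(
    coord_time0: float,
    coord_age0: float,
    coord_time1: float,
    base_age: int,
    step: float = 1e-6,
) -> dict[tuple[int, int, int], float]:
    """Numerical-integration oracle for lifeline cell times.

    Samples the lifeline at midpoints of a uniform grid of the given step
    and bins the elapsed time by (age, r, s) cell — independent of the
    analytic boundary-splitting traversal it checks.
    """
    span = coord_time1 - coord_time0
    if span <= 0:
        return {}
    n = max(1, int(round(span / step)))
    h = span / n
    tm = coord_time0 + (np.arange(n) + 0.5) * h
    g = base_age + coord_age0 + (tm - coord_time0)
    x = np.floor(g).astype(np.int64)
    r = np.minimum((4.0 * (g - x)).astype(np.int64), 3)
    s = np.minimum((4.0 * tm).astype(np.int64), 3)
    key = x * 16 + r * 4 + s
    binned = np.bincount(key)
    out = {}
    for k in np.nonzero(binned)[0]:
        out[(int(k) // 16, (int(k) % 16) // 4 + 1, int(k) % 4 + 1)] = (
            binned[k] * h
        )
    return out


def grid_cells(frame: pd.DataFrame) -> dict[tuple[int, int, int], float]:
    """Nonzero cells of a quarter grid as a dict keyed (age, r, s)."""
    col = grid.value_column(frame)
    sel = frame[frame[col] != 0]
    return {
        (int(a), int(r), int(s)): float(v)
        for a, r, s, v in sel[
            ["age", "quarter.age", "quarter.calendar", col]
        ].itertuples(index=False)
    }


def cells_close(
    got: dict, want: dict, tol: float = 1e-9, drop_below: float = 0.0
) -> None:
    """Assert two cell dicts agree within *tol* on every key."""
    keys = set(got) | set(want)
    for k in keys:
        a, b = got.get(k, 0.0), want.get(k, 0.0)
        if max(abs(a), abs(b)) <= drop_below:
            continue
        assert abs(a - b) <= tol, f"cell {k}: {a} vs {b}"
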