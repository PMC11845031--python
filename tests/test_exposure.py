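"""Lifeline traversal and exposure accounting."""

import numpy as np
import pandas as pd
import pytest

from quarterlife import exposure, grid, lexis
from conftest import cells_close, grid_cells, integrate_lifeline


def test_full_year_traversal_alternates_cell_times():
    """Start-of-year age quarter 2 (coord age 0.3): the eight quarter
    cells in traversal order with times alternating 0.2 and 0.05."""
    cells = exposure.traverse_segment(0.0, 0.3, 1.0, 5)
    want = [
        (5, 2, 1, 0.2), (5, 3, 1, 0.05), (5, 3, 2, 0.2), (5, 4, 2, 0.05),
        (5, 4, 3, 0.2), (6, 1, 3, 0.05), (6, 1, 4, 0.2), (6, 2, 4, 0.05),
    ]
    assert [(c[:3]) for c in cells] == [(w[:3]) for w in want]
    np.testing.assert_allclose([c[3] for c in cells], [w[3] for w in want], atol=1e-12)


def test_full_year_traversal_degenerate_diagonal():
    cells = exposure.traverse_segment(0.0, 0.0, 1.0, 0)
    assert [(c[:3]) for c in cells] == [(0, 1, 1, ), (0, 2, 2), (0, 3, 3), (0, 4, 4)]
    np.testing.assert_allclose([c[3] for c in cells], 0.25, atol=1e-12)


def test_short_segment_without_boundary_crossing():
    cells = exposure.traverse_segment(0.9, 0.8, 1.0, 2)
    assert len(cells) == 1
    (x, r, s, t) = cells[0]
    assert (x, r, s) == (2, 4, 4)
    assert t == pytest.approx(0.1, abs=1e-12)


@pytest.mark.parametrize("r0", [1, 2, 3, 4])
def test_traversal_follows_the_eight_quarter_sequence(r0):
    """Cells visited over a full year follow (r,1), (mod4bar(r+1),1),
    (mod4bar(r+1),2), ... for every starting age quarter."""
    c0 = (r0 - 1) / 4 + 0.1
    cells = exposure.traverse_segment(0.0, c0, 1.0, 0)
    want_rs = [
        (lexis.mod4bar(r0 + (k + 1) // 2), k // 2 + 1) for k in range(8)
    ]
    assert [(r, s) for (_, r, s, _) in cells] == want_rs
    # age rolls forward exactly when the quarter index wraps
    ages = [x for (x, _, _, _) in cells]
    assert ages == sorted(ages) and ages[-1] == ages[0] + 1


def test_traversal_times_sum_to_segment_length(rng):
    for _ in range(200):
        t0, t1 = np.sort(rng.uniform(0, 1, 2))
        ca = rng.uniform(0, 1)
        cells = exposure.traverse_segment(t0, ca, t1, int(rng.integers(0, 100)))
        assert sum(c[3] for c in cells) == pytest.approx(t1 - t0, abs=1e-9)


def test_traversal_matches_integration_oracle(rng):
    """Analytic boundary splitting agrees with step-1e-5 numerical
    integration of the lifeline, cell by cell."""
    for _ in range(30):
        t0, t1 = np.sort(rng.uniform(0, 1, 2))
        ca = rng.uniform(0, 1)
        base = int(rng.integers(0, 90))
        got = {c[:3]: c[3] for c in exposure.traverse_segment(t0, ca, t1, base)}
        want = integrate_lifeline(t0, ca, t1, base, step=1e-5)
        cells_close(got, want, tol=1e-4)


def test_stock_forward_single_person():
    """Born 2005-07-01 12:00, stock of 2006: age quarter 3 at the anchor,
    eight cells alternating 0.75-c and c-0.5 with c = 183.5/365."""
    g = exposure.time_exposed_stock(
        ["2005-07-01 12:00:00"], year=2006, random_b=False
    )
    c = 183.5 / 365
    cells = grid_cells(g)
    assert cells[(0, 3, 1)] == pytest.approx(0.75 - c, abs=1e-12)
    assert cells[(0, 4, 1)] == pytest.approx(c - 0.5, abs=1e-12)
    assert cells[(1, 1, 2)] == pytest.approx(c - 0.5, abs=1e-12)
    assert cells[(1, 2, 4)] == pytest.approx(0.75 - c, abs=1e-12)
    assert len(cells) == 8
    assert g["time.exposed"].sum() == pytest.approx(1.0, abs=1e-9)


def test_stock_mass_equals_population_size(rng):
    n = 500
    days = rng.integers(0, 20 * 365, n)
    births = (
        np.datetime64("1980-01-01") + days.astype("timedelta64[D]")
    ).astype(str)
    g = exposure.time_exposed_stock(births, year=2006, rng=rng)
    assert g["time.exposed"].sum() == pytest.approx(n, abs=1e-9)
    # complete ordered grid
    assert len(g) == 16 * (int(g["age"].max()) + 1)
    assert (g["time.exposed"] >= 0).all()


def test_stock_forward_matches_generic_traversal(rng):
    """The vectorised eight-cell closed form agrees with the generic
    boundary-splitting traversal."""
    births = ["1999-03-15 06:30:00", "2001-11-02 18:00:00", "2005-12-31 23:59:59"]
    g = exposure.time_exposed_stock(births, year=2006, random_b=False)
    from quarterlife import chronos

    want = {}
    for b in births:
        age = chronos.exact_age(b, "2006-01-01 00:00:00")
        for (x, r, s, t) in exposure.traverse_segment(
            0.0, age - int(age), 1.0, int(age)
        ):
            want[(x, r, s)] = want.get((x, r, s), 0.0) + t
    cells_close(grid_cells(g), want, tol=1e-12)


def test_stock_backward_in_year_birth_counts_from_birth():
    # born mid-2006, in the stock counted at 24:00 Dec 31 2006
    g = exposure.time_exposed_stock(
        ["2006-07-01 00:00:00"], year=2006, anchoring="backward", random_b=False
    )
    assert g["time.exposed"].sum() == pytest.approx(184 / 365, abs=1e-9)
    assert (g[g["age"] > 0]["time.exposed"] == 0).all()


def test_stock_rejects_birth_after_anchor():
    with pytest.raises(ValueError, match="anchor"):
        exposure.time_exposed_stock(
            ["2006-05-01 00:00:00"], year=2006, random_b=False
        )


def _points(coord_time, coord_age, age):
    return pd.DataFrame(
        {
            "coord.time": coord_time,
            "coord.age": coord_age,
            "age": age,
        }
    )


def test_ins_mass_is_time_remaining_in_year():
    g = exposure.time_exposed_ins(_points([0.5], [0.5], [30]))
    assert g["time.exposed"].sum() == pytest.approx(0.5, abs=1e-12)
    g0 = exposure.time_exposed_ins(_points([0.0], [0.25], [30]))
    assert g0["time.exposed"].sum() == pytest.approx(1.0, abs=1e-12)


def test_ins_first_cell_splits_at_next_time_boundary():
    g = exposure.time_exposed_ins(_points([0.1], [0.3], [0]))
    cells = grid_cells(g)
    assert cells[(0, 2, 1)] == pytest.approx(0.15, abs=1e-12)


def test_ins_plus_outs_equals_full_year_traversal(rng):
    for _ in range(50):
        t = rng.uniform(0, 1)
        ca = rng.uniform(0, 1)
        age = int(rng.integers(1, 90))
        pts = _points([t], [ca], [age])
        ins = grid_cells(exposure.time_exposed_ins(pts))
        outs = grid_cells(exposure.time_exposed_outs(pts))
        start_age = age + ca - t
        base = int(start_age)
        full = {}
        for (x, r, s, dt_) in exposure.traverse_segment(
            0.0, start_age - base, 1.0, base
        ):
            full[(x, r, s)] = full.get((x, r, s), 0.0) + dt_
        combined = dict(outs)
        for k, v in ins.items():
            combined[k] = combined.get(k, 0.0) + v
        cells_close(combined, full, tol=1e-9)


def test_outs_of_event_at_year_start_is_zero():
    g = exposure.time_exposed_outs(_points([0.0], [0.6], [10]))
    assert g["time.exposed"].sum() == 0.0


def test_outs_of_in_year_birth_starts_at_birth():
    # newborn dying at coord_time 0.6 who was born at 0.2 (coord_age 0.4)
    g = exposure.time_exposed_outs(_points([0.6], [0.4], [0]))
    assert g["time.exposed"].sum() == pytest.approx(0.4, abs=1e-12)


def test_newborns_grid():
    g = exposure.time_exposed_newborns(["2006-01-01"], random_b=False,
                                       fixed_time=__import__("datetime").time(0))
    cells = grid_cells(g)
    assert cells == pytest.approx(
        {(0, 1, 1): 0.25, (0, 2, 2): 0.25, (0, 3, 3): 0.25, (0, 4, 4): 0.25}
    )
    late = exposure.time_exposed_newborns(["2006-11-26 12:00:00"])
    c = grid_cells(late)
    assert set(c) == {(0, 1, 4)}
    assert sum(c.values()) < 0.1 + 1e-9


def test_newborns_rejects_multiple_years():
    with pytest.raises(ValueError, match="calendar year"):
        exposure.time_exposed_newborns(["2005-06-01", "2006-06-01"], random_b=False)


def test_combine_identity_and_complementarity():
    stock = exposure.time_exposed_stock(
        ["1980-04-01 00:00:00"], year=2006, random_b=False
    )
    comp = exposure.ExposureComponents(stock=stock, anchoring="forward")
    out = exposure.combine_exposures(comp)
    pd.testing.assert_frame_equal(out, stock)
    # a stock person dying mid-year: P - ins(death) == outs(death) cellwise
    pts = lexis.quarterly_variables(
        ["1980-04-01 00:00:00"], ["2006-09-20 15:00:00"]
    )
    ins_d = exposure.time_exposed_ins(pts)
    outs_d = exposure.time_exposed_outs(pts)
    total = exposure.combine_exposures(
        exposure.ExposureComponents(stock=stock, deaths=ins_d, anchoring="forward")
    )
    a, b = grid.pad_to_common_age(total, outs_d)
    np.testing.assert_allclose(grid.to_array(a), grid.to_array(b), atol=1e-12)


def test_combine_warns_on_negative_cells():
    stock = grid.empty_grid(0, "exposure")
    deaths = grid.empty_grid(0, "exposure").assign(**{"time.exposed": 0.1})
    with pytest.warns(UserWarning, match="negative exposure"):
        exposure.combine_exposures(
            exposure.ExposureComponents(stock=stock, deaths=deaths)
        )


def test_combine_rejects_unknown_anchoring():
    with pytest.raises(ValueError, match="anchoring"):
        exposure.combine_exposures(
            exposure.ExposureComponents(
                stock=grid.empty_grid(0), anchoring="sideways"
            )
        )
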