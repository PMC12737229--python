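"""Gridding, the count weighting function and the CWT field."""

import numpy as np
import pandas as pd
import pytest

from cwtburden.cwt import CWTModel, compute_cwt, hourly_cwt_series, weight_factor
from cwtburden.grid import GridSpec, make_grid, residence_counts
from cwtburden.trajectory import TrajectoryEnsembleSet

from conftest import make_point_set, series_for


# ---------------------------------------------------------------------------
# grids
# ---------------------------------------------------------------------------

def test_make_grid_cell_counts():
    g = make_grid(108, 34, 120, 43, 0.25)
    assert (g.n_lon, g.n_lat) == (48, 36)
    g2 = make_grid(0, 0, 1, 1, 0.25)
    assert (g2.n_lon, g2.n_lat) == (4, 4)


def test_make_grid_rejects_bad_cell_size():
    with pytest.raises(ValueError):
        make_grid(0, 0, 1, 1, 0.0)


def test_cell_index_half_open_edges():
    g = make_grid(108, 34, 120, 43, 0.25)
    assert g.cell_index(108.0, 34.0) == (0, 0)
    assert g.cell_index(120.0, 40.0) is None   # upper edge is open
    assert g.cell_index(110.0, 43.0) is None


def test_cell_index_receptor_matches_brute_force():
    """Receptor cell on the default grid, checked by scanning cell bounds."""
    g = make_grid(108, 34, 120, 43, 0.25)
    lon, lat = 116.40, 39.98
    assert g.cell_index(lon, lat) == (33, 23)
    hits = [
        (i, j)
        for i in range(g.n_lon)
        for j in range(g.n_lat)
        if g.lon_min + i * g.cell_size <= lon < g.lon_min + (i + 1) * g.cell_size
        and g.lat_min + j * g.cell_size <= lat < g.lat_min + (j + 1) * g.cell_size
    ]
    assert hits == [(33, 23)]


# ---------------------------------------------------------------------------
# residence counts
# ---------------------------------------------------------------------------

def test_residence_counts_single_cell():
    tset = make_point_set([[(34.1, 108.1), (34.12, 108.15), (34.2, 108.2)]],
                          receptor=(34.1, 108.1))
    g = make_grid(108, 34, 110, 36, 0.25)
    f = residence_counts(tset, g)
    assert f.n[0, 0] == 3
    assert f.n.sum() == 3


def test_residence_conservation(small_scenario):
    g = make_grid(108, 34, 120, 43, 0.25)
    f = residence_counts(small_scenario.trajectories, g)
    assert f.n_total_inside + f.n_outside == small_scenario.trajectories.n_points


def test_residence_linearity_doubles_with_duplicate_trajectory():
    pts = [[(34.1, 108.1), (34.6, 108.6)]]
    g = make_grid(108, 34, 110, 36, 0.25)
    one = residence_counts(make_point_set(pts, receptor=(34.1, 108.1)), g)
    two = residence_counts(make_point_set(pts * 2, receptor=(34.1, 108.1)), g)
    np.testing.assert_array_equal(two.n, 2 * one.n)


def test_indicator_mode_caps_tau_at_one():
    tset = make_point_set([[(34.1, 108.1), (34.12, 108.15), (34.2, 108.2)]],
                          receptor=(34.1, 108.1))
    g = make_grid(108, 34, 110, 36, 0.25)
    f = residence_counts(tset, g, tau_mode="indicator")
    assert f.n[0, 0] == 1


# ---------------------------------------------------------------------------
# weighting function
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n_ij, n_ave, expected", [
    (4.0, 1.0, 1.00),    # above 3 n_ave
    (3.0, 1.0, 0.70),    # boundary: 3 n_ave belongs to the second bin
    (2.0, 1.0, 0.70),
    (1.5, 1.0, 0.42),    # boundary: 1.5 n_ave belongs to the third bin
    (1.2, 1.0, 0.42),
    (1.0, 1.0, 0.05),    # n_ij = n_ave falls in the sparse bin
    (0.5, 1.0, 0.05),
    (0.0, 2.5, 0.05),
    (301.0, 100.0, 1.00),
])
def test_weight_factor_bins_and_boundaries(n_ij, n_ave, expected):
    assert weight_factor(n_ij, n_ave) == expected


def test_weight_factor_rejects_nonpositive_mean():
    with pytest.raises(ValueError):
        weight_factor(1.0, 0.0)


# ---------------------------------------------------------------------------
# CWT field
# ---------------------------------------------------------------------------

def test_constant_concentration_gives_constant_field(small_scenario):
    tset = small_scenario.trajectories
    series = series_for(tset, np.full(tset.n_ensembles, 42.0))
    field = compute_cwt(tset, series, apply_weight=False)
    vals = field.c[field.defined]
    np.testing.assert_allclose(vals, 42.0)


def test_two_trajectory_shared_cell_weighted_mean():
    """tau (1, 3) with C = (10, 30) gives (10*1 + 30*3)/4 = 25 unweighted."""
    g = make_grid(108, 34, 110, 36, 1.0)
    tset = make_point_set([
        [(34.5, 108.5)],
        [(34.5, 108.4), (34.5, 108.5), (34.5, 108.6)],
    ], receptor=(34.5, 108.5))
    series = series_for(tset, [10.0, 30.0])
    field = compute_cwt(tset, series, grid=g, apply_weight=False)
    assert field.c[0, 0] == pytest.approx(25.0, rel=1e-12)
    # with weighting on, the single occupied cell has n = 4 = n_ave -> W=0.05
    weighted = compute_cwt(tset, series, grid=g, apply_weight=True)
    assert weighted.c[0, 0] == pytest.approx(25.0 * 0.05, rel=1e-12)


def test_top_weight_bin_leaves_value_unchanged():
    """A cell with n > 3 n_ave keeps its unweighted value (W = 1)."""
    g = make_grid(108, 34, 110, 36, 1.0)
    # cell counts (16, 1, 1, 1): n_ave = 19/4 = 4.75 and 16 > 3 * 4.75
    traj = [(34.5, 108.5)] * 16 + [(35.5, 108.5), (35.5, 109.5), (34.5, 109.5)]
    tset = make_point_set([traj], receptor=(34.5, 108.5))
    series = series_for(tset, [25.0])
    field = compute_cwt(tset, series, grid=g, apply_weight=True)
    assert field.n[0, 0] == 16
    assert field.w[0, 0] == 1.00
    assert field.c[0, 0] == pytest.approx(25.0, rel=1e-12)


def test_missing_arrival_concentration_is_reported():
    tset = make_point_set([[(34.5, 108.5)], [(34.5, 108.5)]],
                          receptor=(34.5, 108.5), start="2024-01-01 01:00")
    series = series_for(tset, [10.0, 20.0]).iloc[:1]
    with pytest.raises(ValueError, match="no matching concentration"):
        compute_cwt(tset, series, grid=make_grid(108, 34, 110, 36, 1.0))


def test_daily_series_inherited_by_hourly_arrivals():
    tset = make_point_set([[(34.5, 108.5)], [(34.5, 108.5)]], receptor=(34.5, 108.5))
    daily = pd.Series([40.0], index=pd.DatetimeIndex([pd.Timestamp("2024-01-01", tz="UTC")]))
    field = compute_cwt(tset, daily, grid=make_grid(108, 34, 110, 36, 1.0),
                        apply_weight=False)
    assert field.c[0, 0] == pytest.approx(40.0)


# ---------------------------------------------------------------------------
# oracle equivalence and invariances
# ---------------------------------------------------------------------------

def naive_cwt(tset, conc_by_arrival, grid, apply_weight=True, nave_mode="occupied"):
    """Brute-force per-cell loops over trajectories, independent of the
    vectorised implementation."""
    trajs = [
        (arr, grp)
        for (arr, _mid), grp in tset.points.groupby(["arrival_time", "member_id"])
    ]
    n = np.zeros((grid.n_lat, grid.n_lon))
    num = np.zeros_like(n)
    for arrival, grp in trajs:
        c_l = conc_by_arrival[arrival]
        for _, row in grp.iterrows():
            for i in range(grid.n_lon):
                for j in range(grid.n_lat):
                    lo_lon = grid.lon_min + i * grid.cell_size
                    lo_lat = grid.lat_min + j * grid.cell_size
                    if (lo_lon <= row["lon"] < lo_lon + grid.cell_size
                            and lo_lat <= row["lat"] < lo_lat + grid.cell_size):
                        n[j, i] += 1
                        num[j, i] += c_l
    occ = n > 0
    if nave_mode == "occupied":
        nave = n[occ].mean()
    else:
        nave = n.mean()
    c = np.full_like(num, np.nan)
    c[occ] = num[occ] / n[occ]
    if apply_weight:
        for j in range(grid.n_lat):
            for i in range(grid.n_lon):
                if not occ[j, i]:
                    continue
                x = n[j, i]
                if x > 3 * nave:
                    w = 1.00
                elif x > 1.5 * nave:
                    w = 0.70
                elif x > nave:
                    w = 0.42
                else:
                    w = 0.05
                c[j, i] *= w
    return c


def _random_instance(rng):
    n_lon = rng.integers(3, 11)
    n_lat = rng.integers(3, 11)
    grid = GridSpec(lon_min=0.0, lat_min=0.0, cell_size=1.0,
                    n_lon=int(n_lon), n_lat=int(n_lat))
    n_traj = int(rng.integers(1, 21))
    rows = []
    t0 = pd.Timestamp("2024-01-01", tz="UTC")
    conc = {}
    for k in range(n_traj):
        arrival = t0 + pd.Timedelta(hours=k)
        conc[arrival] = float(rng.uniform(5, 100))
        n_pts = int(rng.integers(1, 12))
        for a in range(n_pts):
            rows.append({
                "arrival_time": arrival, "member_id": 1, "age_h": -a,
                # some points deliberately off-grid
                "lat": float(rng.uniform(-1.0, n_lat + 1.0)),
                "lon": float(rng.uniform(-1.0, n_lon + 1.0)),
                "height": 100.0,
            })
    tset = TrajectoryEnsembleSet(pd.DataFrame(rows), receptor=(0.0, 0.0))
    series = pd.Series(conc)
    series.index = pd.DatetimeIndex(series.index)
    return tset, series, conc, grid


@pytest.mark.parametrize("n_instances", [10])
def test_cwt_matches_naive_oracle(n_instances):
    rng = np.random.default_rng(99)
    for _ in range(n_instances):
        tset, series, conc, grid = _random_instance(rng)
        if not any(grid.contains(lo, la)
                   for lo, la in zip(tset.points["lon"], tset.points["lat"])):
            continue
        for apply_weight in (False, True):
            fast = compute_cwt(tset, series, grid=grid, apply_weight=apply_weight)
            slow = naive_cwt(tset, conc, grid, apply_weight=apply_weight)
            np.testing.assert_allclose(fast.c, slow, rtol=1e-12, equal_nan=True)


def test_field_invariant_under_trajectory_permutation():
    rng = np.random.default_rng(5)
    tset, series, _, grid = _random_instance(rng)
    shuffled = TrajectoryEnsembleSet(
        tset.points.sample(frac=1.0, random_state=1).reset_index(drop=True),
        receptor=tset.receptor,
    )
    a = compute_cwt(tset, series, grid=grid)
    b = compute_cwt(shuffled, series, grid=grid)
    np.testing.assert_allclose(a.c, b.c, equal_nan=True)


def test_field_bounded_by_concentrations(small_scenario):
    tset = small_scenario.trajectories
    series = small_scenario.concentrations
    field = compute_cwt(tset, series, apply_weight=True)
    from cwtburden.cwt import match_concentrations
    c_l = match_concentrations(tset.arrival_times, series)
    vals = field.c[field.defined]
    assert vals.min() >= c_l.min() * 0.05 - 1e-9
    assert vals.max() <= c_l.max() + 1e-9


# ---------------------------------------------------------------------------
# hourly (per-arrival) view
# ---------------------------------------------------------------------------

def test_hourly_series_preserves_order_and_counts(small_scenario):
    tset = small_scenario.trajectories
    tw = hourly_cwt_series(tset, small_scenario.concentrations)
    assert len(tw) == tset.n_ensembles
    assert tw.arrival_times == list(tset.arrival_times)
    assert sum(len(g) for _, g in tw) == tset.n_points


def test_model_results_summary_mentions_settings(small_scenario):
    res = CWTModel(small_scenario.trajectories, small_scenario.concentrations).fit()
    text = res.summary()
    assert "n_ave" in text and "Sector shares" in text
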