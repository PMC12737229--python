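"""Sector geometry, tiling, CWT integrals and source attribution."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cwtburden.cwt import CWTModel, compute_cwt
from cwtburden.grid import make_grid
from cwtburden.sectors import (
    classify_point,
    classify_points,
    default_sectors,
    dominant_source_per_day,
    sector_integrals,
    timewise_fractions,
)
from cwtburden.simulate import ScenarioConfig, generate_scenario

from conftest import make_point_set, series_for


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def test_five_sectors_with_published_bounds():
    secs = {s.name: s for s in default_sectors()}
    assert len(secs) == 5
    assert secs["local"].lon_range == (115.3, 117.5)
    assert secs["local"].lat_range == (39.4, 41.0)
    assert secs["west"].lon_range == (108.0, 115.3)
    assert secs["north"].lat_range == (41.0, 43.0)
    assert secs["east"].lon_range == (117.5, 120.0)
    assert secs["south"].lat_range == (34.0, 39.4)


def test_receptor_lies_in_local_sector():
    assert classify_point(default_sectors(), 116.40, 39.98) == "local"


def test_sectors_tile_domain_analytically():
    """Pairwise-disjoint rectangles whose areas sum to the 12 x 9 domain."""
    secs = default_sectors()
    assert sum(s.area_sq_deg for s in secs) == pytest.approx(108.0)
    for a in secs:
        for b in secs:
            if a.name >= b.name:
                continue
            lon_overlap = min(a.lon_range[1], b.lon_range[1]) - max(a.lon_range[0], b.lon_range[0])
            lat_overlap = min(a.lat_range[1], b.lat_range[1]) - max(a.lat_range[0], b.lat_range[0])
            assert lon_overlap <= 0 or lat_overlap <= 0, (a.name, b.name)


@settings(max_examples=300, deadline=None, derandomize=True)
@given(
    lon=st.floats(min_value=108.0, max_value=120.0, exclude_max=True),
    lat=st.floats(min_value=34.0, max_value=43.0, exclude_max=True),
)
def test_every_domain_point_in_exactly_one_sector(lon, lat):
    hits = [s.name for s in default_sectors() if s.contains(lon, lat)]
    assert len(hits) == 1


@pytest.mark.parametrize("lon, lat, expected", [
    (116.0, 40.0, "local"),
    (115.3, 40.0, "local"),     # lower-closed western edge of local
    (117.5, 40.0, "east"),      # local's open upper edge belongs to east
    (110.0, 41.0, "north"),     # west/north shared edge belongs to north
    (121.0, 40.0, "outside"),
    (116.0, 33.0, "outside"),
])
def test_classify_point_half_open_rule(lon, lat, expected):
    assert classify_point(default_sectors(), lon, lat) == expected


# ---------------------------------------------------------------------------
# sector integrals
# ---------------------------------------------------------------------------

def _uniform_field(cell_size):
    """A CWT field that is exactly c everywhere on the default domain."""
    grid = make_grid(108, 34, 120, 43, cell_size)
    # one trajectory endpoint per cell, constant concentration
    lon_c, lat_c = np.meshgrid(grid.lon_centers, grid.lat_centers)
    pts = list(zip(lat_c.ravel(), lon_c.ravel()))
    tset = make_point_set([pts], receptor=pts[0])
    series = series_for(tset, [7.0])
    return compute_cwt(tset, series, grid=grid, apply_weight=False)


def test_uniform_field_shares_equal_area_ratios():
    """On a 0.1 deg grid (which divides every sector edge) the local share
    equals its area fraction 2.2*1.6/108."""
    field = _uniform_field(0.1)
    shares = sector_integrals(field).set_index("sector")["share"]
    assert shares.sum() == pytest.approx(1.0, abs=1e-9)
    assert shares["local"] == pytest.approx(2.2 * 1.6 / 108.0, abs=1e-9)
    assert shares["west"] == pytest.approx(7.3 * 7.0 / 108.0, abs=1e-9)
    assert shares["north"] == pytest.approx(9.5 * 2.0 / 108.0, abs=1e-9)
    assert shares["east"] == pytest.approx(2.5 * 3.6 / 108.0, abs=1e-9)
    assert shares["south"] == pytest.approx(4.7 * 5.4 / 108.0, abs=1e-9)


def test_field_confined_to_one_sector_gets_full_share():
    grid = make_grid(108, 34, 120, 43, 0.25)
    tset = make_point_set([[(42.0, 110.0), (42.1, 111.0)]], receptor=(42.0, 110.0))
    field = compute_cwt(tset, series_for(tset, [30.0]), grid=grid, apply_weight=False)
    shares = sector_integrals(field).set_index("sector")["share"]
    assert shares["north"] == pytest.approx(1.0)


def test_all_undefined_field_raises():
    grid = make_grid(108, 34, 120, 43, 0.25)
    tset = make_point_set([[(50.0, 116.0)]], receptor=(50.0, 116.0))
    with pytest.warns(UserWarning):
        field = compute_cwt(tset, series_for(tset, [5.0]), grid=grid)
    with pytest.raises(ValueError):
        sector_integrals(field)


# ---------------------------------------------------------------------------
# per-time fractions and daily labels
# ---------------------------------------------------------------------------

def test_single_sector_ensemble_gets_fraction_one():
    grid = make_grid(108, 34, 120, 43, 0.25)
    tset = make_point_set([[(42.0, 110.0), (42.1, 110.5)]], receptor=(42.0, 110.0))
    field = compute_cwt(tset, series_for(tset, [20.0]), grid=grid, apply_weight=False)
    groups = [(t, g.reset_index(drop=True))
              for t, g in tset.points.groupby("arrival_time")]
    rec = timewise_fractions(groups, field).iloc[0]
    assert rec["north"] == pytest.approx(1.0)
    assert rec["dominant"] == "north"
    assert not rec["tie"] and not rec["indeterminate"]


def test_exact_tie_flagged_and_broken_by_priority():
    grid = make_grid(108, 34, 120, 43, 0.25)
    # one endpoint in north, one in south, equal weights (count mode)
    tset = make_point_set([[(42.0, 110.0), (35.0, 116.0)]], receptor=(42.0, 110.0))
    field = compute_cwt(tset, series_for(tset, [20.0]), grid=grid, apply_weight=False)
    groups = [(t, g.reset_index(drop=True))
              for t, g in tset.points.groupby("arrival_time")]
    rec = timewise_fractions(groups, field, mode="count").iloc[0]
    assert rec["tie"]
    assert rec["dominant"] == "south"  # south precedes north in the priority


def test_all_zero_weights_flagged_indeterminate():
    grid = make_grid(108, 34, 120, 43, 0.25)
    tset = make_point_set([[(42.0, 110.0)], [(35.0, 116.0)]], receptor=(42.0, 110.0))
    field = compute_cwt(tset, series_for(tset, [20.0, 10.0]), grid=grid,
                        apply_weight=False)
    # second arrival's endpoint sits in a cell we blank out manually
    field.c[:, :] = np.nan
    groups = [(t, g.reset_index(drop=True))
              for t, g in tset.points.groupby("arrival_time")]
    recs = timewise_fractions(groups, field, mode="cwt")
    assert recs["indeterminate"].all()


def test_daily_label_follows_mean_fraction():
    times = pd.date_range("2024-01-01", periods=4, freq="6h", tz="UTC")
    recs = pd.DataFrame({
        "time": times,
        "local": [0.0, 0.0, 0.0, 0.0],
        "west": [0.0, 0.0, 0.0, 0.0],
        "north": [0.4, 0.4, 0.4, 0.4],
        "east": [0.0, 0.0, 0.0, 0.0],
        "south": [0.6, 0.6, 0.6, 0.6],
        "outside": [0.0] * 4,
        "dominant": ["south"] * 4,
        "tie": [False] * 4,
        "indeterminate": [False] * 4,
    })
    days = dominant_source_per_day(recs)
    assert len(days) == 1
    assert days.iloc[0]["source"] == "south"


def test_daily_labels_recover_generating_regimes():
    """A 10-day seeded scenario is relabelled (count mode) >= 9/10 correctly."""
    cfg = ScenarioConfig(n_days=10, seed=42)
    sc = generate_scenario(cfg)
    res = CWTModel(sc.trajectories, sc.concentrations).fit()
    days = res.daily_sources(mode="count")
    pred = days["source"].to_numpy()
    truth = np.array(sc.regime_sequence)
    assert (pred == truth).mean() >= 0.9


def test_classify_points_vectorized_matches_scalar():
    rng = np.random.default_rng(3)
    lon = rng.uniform(106, 122, size=50)
    lat = rng.uniform(32, 45, size=50)
    secs = default_sectors()
    vec = classify_points(secs, lon, lat)
    scalar = [classify_point(secs, lo, la) for lo, la in zip(lon, lat)]
    assert list(vec) == scalar
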