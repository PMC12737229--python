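"""Geographic source sectors, per-sector CWT integrals and air-mass fractions.

Five named rectangles tile the analysis domain [108, 120)E x [34, 43)N:
a local box around the receptor, plus west, north, east and south transport
regions.  Rectangles are half-open on both axes (min inclusive, max
exclusive), so the tiling is exact: every domain point belongs to exactly
one sector.

Two per-arrival-time attribution modes are provided, because "air-mass
fraction derived from CWT" admits both readings:

``mode='cwt'``
    each endpoint is weighted by the period CWT value of the cell it sits in
    (undefined cells weigh 0), so fractions reflect concentration-weighted
    origin;
``mode='count'``
    each in-domain endpoint counts 1 — pure residence fractions.

Concentration weighting is the default for reported fractions; daily
dominant-source *labels* default to count mode, since weighting by
concentration systematically outvotes clean sectors (a north-regime day's
endpoints sit in low-concentration cells and would lose to the handful of
near-receptor, high-concentration cells).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

OUTSIDE_LABEL = "outside"

SECTOR_NAMES = ("local", "west", "north", "east", "south")

#: Fixed order used to break exact ties in dominant-source decisions.
DOMINANCE_PRIORITY = ("local", "south", "east", "west", "north")


@dataclasses.dataclass(frozen=True)
class SectorDefinition:
    """A named half-open lon/lat rectangle."""

    name: str
    lon_range: tuple[float, float]
    lat_range: tuple[float, float]

    def __post_init__(self):
        if self.lon_range[0] >= self.lon_range[1] or self.lat_range[0] >= self.lat_range[1]:
            raise ValueError(f"sector {self.name}: min must be < max on both axes")

    def contains(self, lon, lat):
        """Half-open membership test; works on scalars or arrays."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        out = (
            (lon >= self.lon_range[0])
            & (lon < self.lon_range[1])
            & (lat >= self.lat_range[0])
            & (lat < self.lat_range[1])
        )
        if out.ndim == 0:
            return bool(out)
        return out

    @property
    def area_sq_deg(self) -> float:
        return (self.lon_range[1] - self.lon_range[0]) * (
            self.lat_range[1] - self.lat_range[0]
        )


def default_sectors() -> tuple[SectorDefinition, ...]:
    """The five source sectors tiling the default analysis domain.

    Central Beijing (local), western plateau, northern plateau, eastern
    coastal plain, and southern region.  Shared edges are half-open so the
    rectangles are pairwise disjoint and tile [108, 120) x [34, 43).
    """
    return (
        SectorDefinition("local", (115.3, 117.5), (39.4, 41.0)),
        SectorDefinition("west", (108.0, 115.3), (34.0, 41.0)),
        SectorDefinition("north", (108.0, 117.5), (41.0, 43.0)),
        SectorDefinition("east", (117.5, 120.0), (39.4, 43.0)),
        SectorDefinition("south", (115.3, 120.0), (34.0, 39.4)),
    )


def classify_points(sectors: Sequence[SectorDefinition], lon, lat) -> np.ndarray:
    """Sector name for each point (``'outside'`` if none matches).

    With tiling sectors at most one rectangle matches; if overlapping custom
    sectors are supplied, the first match in list order wins.
    """
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    out = np.full(lon.shape, OUTSIDE_LABEL, dtype=object)
    unassigned = np.ones(lon.shape, dtype=bool)
    for sec in sectors:
        hit = unassigned & sec.contains(lon, lat)
        out[hit] = sec.name
        unassigned &= ~hit
    return out


def classify_point(sectors: Sequence[SectorDefinition], lon: float, lat: float) -> str:
    """Sector name containing (lon, lat), or ``'outside'``."""
    return str(classify_points(sectors, [lon], [lat])[0])


def sector_of_cells(grid, sectors: Sequence[SectorDefinition]) -> np.ndarray:
    """Sector name per grid cell, shape ``(n_lat, n_lon)``.

    A cell belongs to the sector containing its *center* — unambiguous for
    cells straddling sector edges that are not multiples of the cell size.
    """
    lon_c, lat_c = np.meshgrid(grid.lon_centers, grid.lat_centers)
    return classify_points(sectors, lon_c.ravel(), lat_c.ravel()).reshape(lon_c.shape)


def _dominant(fracs: dict[str, float], priority=DOMINANCE_PRIORITY):
    """Argmax sector with fixed-priority tie-break; returns (name, tied?)."""
    best = max(fracs.values())
    winners = [s for s in priority if s in fracs and fracs[s] == best]
    extra = [s for s in fracs if fracs[s] == best and s not in priority]
    winners += extra
    return winners[0], len(winners) > 1


def sector_integrals(field, sectors: Sequence[SectorDefinition] | None = None) -> pd.DataFrame:
    """Integrate the CWT field over each sector.

    ``integral`` is the sum of defined cell values with centers in the
    sector; ``share`` normalises over the five sectors.  Cells outside all
    sectors are reported in the frame's ``attrs`` (``outside_integral``,
    ``outside_cells``), not folded into the shares.
    """
    if sectors is None:
        sectors = default_sectors()
    c = field.c
    defined = np.isfinite(c)
    if not defined.any():
        raise ValueError("CWT field has no defined cells")
    cell_sector = sector_of_cells(field.grid, sectors)
    rows = []
    for sec in sectors:
        mask = defined & (cell_sector == sec.name)
        rows.append({
            "sector": sec.name,
            "n_cells": int(mask.sum()),
            "integral": float(c[mask].sum()) if mask.any() else 0.0,
        })
    out = pd.DataFrame(rows)
    total = out["integral"].sum()
    out["share"] = out["integral"] / total if total > 0 else np.nan
    outside_mask = defined & (cell_sector == OUTSIDE_LABEL)
    out.attrs["outside_integral"] = float(c[outside_mask].sum()) if outside_mask.any() else 0.0
    out.attrs["outside_cells"] = int(outside_mask.sum())
    return out


def timewise_fractions(
    groups,
    field,
    sectors: Sequence[SectorDefinition] | None = None,
    mode: str = "cwt",
) -> pd.DataFrame:
    """Per-arrival-time air-mass fractions by sector.

    Parameters
    ----------
    groups : iterable of ``(arrival_time, points DataFrame)``
        Endpoints of each arrival's ensemble (columns ``lat, lon``).
    field : CWTField
        The full-period field supplying endpoint weights in ``'cwt'`` mode.
    mode : {'cwt', 'count'}
        Endpoint weighting (see module docstring).

    Returns
    -------
    DataFrame with one row per arrival time: the five sector fractions, an
    ``outside`` fraction, the ``dominant`` sector, and ``tie`` /
    ``indeterminate`` flags.  Fractions sum to 1 unless indeterminate.
    """
    if sectors is None:
        sectors = default_sectors()
    if mode not in ("cwt", "count"):
        raise ValueError(f"unknown fraction mode {mode!r}")
    names = [s.name for s in sectors]
    rows = []
    for arrival, pts in groups:
        lon = pts["lon"].to_numpy()
        lat = pts["lat"].to_numpy()
        labels = classify_points(sectors, lon, lat)
        if mode == "cwt":
            i, j, inside = field.grid.cell_indices(lon, lat)
            w = np.zeros(len(pts))
            cvals = field.c[j[inside], i[inside]]
            w[inside] = np.where(np.isfinite(cvals), cvals, 0.0)
        else:
            w = np.ones(len(pts))
            # endpoints outside every sector fall in the 'outside' bucket
        total = w.sum()
        row = {"time": arrival}
        if total <= 0:
            for nm in names:
                row[nm] = np.nan
            row.update(outside=np.nan, dominant=None, tie=False, indeterminate=True)
        else:
            fracs = {nm: float(w[labels == nm].sum() / total) for nm in names}
            row.update(fracs)
            row["outside"] = float(w[labels == OUTSIDE_LABEL].sum() / total)
            dom, tie = _dominant(fracs)
            row.update(dominant=dom, tie=tie, indeterminate=False)
        rows.append(row)
    return pd.DataFrame(rows)


def dominant_source_per_day(
    records: pd.DataFrame,
    sectors: Sequence[SectorDefinition] | None = None,
) -> pd.DataFrame:
    """Label each calendar day (UTC) with its dominant source sector.

    The day label is the sector with the largest *mean* fraction over the
    day's non-indeterminate records; exact ties break by the fixed priority
    order and are flagged.  Days with no usable record are skipped with a
    warning.
    """
    import warnings

    if sectors is None:
        sectors = default_sectors()
    names = [s.name for s in sectors]
    recs = records[~records["indeterminate"]].copy()
    recs["date"] = pd.to_datetime(recs["time"]).dt.floor("D")
    skipped = (
        set(pd.to_datetime(records["time"]).dt.floor("D"))
        - set(recs["date"])
    )
    if skipped:
        warnings.warn(f"{len(skipped)} day(s) had no usable attribution records")
    rows = []
    for date, grp in recs.groupby("date"):
        means = {nm: float(grp[nm].mean()) for nm in names}
        dom, tie = _dominant(means)
        rows.append({"date": date, "source": dom, "tie": tie})
    return pd.DataFrame(rows)
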