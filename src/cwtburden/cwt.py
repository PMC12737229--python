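"""Concentration-weighted trajectory (CWT) field computation.

The CWT receptor model assigns each grid cell the residence-weighted mean of
the receptor concentrations measured when trajectories crossed that cell:

    C_ij = [ sum_l C_l * tau_ijl / sum_l tau_ijl ] * W(n_ij)

where C_l is the receptor PM2.5 at trajectory l's arrival time, tau_ijl the
number of endpoints of trajectory l in cell (i, j), and W a piecewise
down-weighting of sparsely visited cells:

    W = 1.00  if n_ij > 3 n_ave
        0.70  if 1.5 n_ave < n_ij <= 3 n_ave
        0.42  if n_ave < n_ij <= 1.5 n_ave
        0.05  if n_ij <= n_ave

with n_ave the mean count over occupied cells by default (switchable to the
all-cells mean).  Cells never visited are undefined (NaN), not zero, so that
sector integrals are not biased by empty padding.

:class:`CWTModel` / :class:`CWTResults` wrap the computation statsmodels-style:
build the model from a trajectory set and a receptor series, ``fit()`` it,
then query the results object for the field, sector shares, per-time
air-mass fractions, daily dominant sources and a text summary.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from . import sectors as sectors_mod
from .grid import GridSpec, ResidenceField, default_grid, residence_counts
from .trajectory import TrajectoryEnsembleSet

#: The four weight values, in bin order from densest to sparsest cells.
WEIGHT_VALUES = (1.00, 0.70, 0.42, 0.05)


def weight_factor(n_ij, n_ave: float):
    """Piecewise-constant trajectory-count weight W(n_ij).

    Bin edges are strict below and inclusive above, exactly as in the
    model definition: n_ij = 3 n_ave still gets 0.70, n_ij = n_ave gets 0.05.
    Accepts scalars or arrays; ``n_ave`` must be positive.
    """
    if n_ave <= 0:
        raise ValueError(f"n_ave must be positive, got {n_ave}")
    n = np.asarray(n_ij, dtype=float)
    if (n < 0).any():
        raise ValueError("trajectory counts must be non-negative")
    w = np.where(
        n > 3.0 * n_ave, WEIGHT_VALUES[0],
        np.where(
            n > 1.5 * n_ave, WEIGHT_VALUES[1],
            np.where(n > n_ave, WEIGHT_VALUES[2], WEIGHT_VALUES[3]),
        ),
    )
    if w.ndim == 0:
        return float(w)
    return w


def match_concentrations(arrival_times: pd.DatetimeIndex, series) -> pd.Series:
    """Receptor concentration C_l for each arrival time.

    Exact timestamp match against the series index; if an arrival hour is
    absent but the series is coarser (daily values at midnight), the arrival
    inherits its day's value.  Any remaining gaps raise, listing the missing
    times.
    """
    if isinstance(series, pd.DataFrame):
        if "pm25" not in series.columns:
            raise ValueError("concentration table must have a 'pm25' column")
        series = series["pm25"]
    series = series.copy()
    series.index = pd.to_datetime(series.index, utc=True)
    out = series.reindex(arrival_times)
    missing = out.index[out.isna()]
    series_is_daily = (series.index == series.index.floor("D")).all()
    if len(missing) and series_is_daily:
        daily = series.copy()
        daily.index = daily.index.floor("D")
        daily = daily[~daily.index.duplicated()]
        fill = daily.reindex(missing.floor("D"))
        out.loc[missing] = fill.to_numpy()
    missing = out.index[out.isna()]
    if len(missing):
        shown = ", ".join(str(t) for t in missing[:5])
        raise ValueError(
            f"{len(missing)} arrival time(s) have no matching concentration: "
            f"{shown}{'...' if len(missing) > 5 else ''}"
        )
    return out


@dataclasses.dataclass
class CWTField:
    """A gridded CWT concentration field.

    ``c`` is ``(n_lat, n_lon)`` with NaN where the cell was never visited.
    ``n`` and ``w`` carry the per-cell counts and weights actually applied
    (``w`` is 1 everywhere when ``weighted`` is off).
    """

    grid: GridSpec
    c: np.ndarray
    n: np.ndarray
    w: np.ndarray
    weighted: bool
    m: int
    n_ave_value: float
    nave_mode: str
    n_outside: int

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.c)

    def value_at(self, lon: float, lat: float) -> float:
        idx = self.grid.cell_index(lon, lat)
        if idx is None:
            return float("nan")
        i, j = idx
        return float(self.c[j, i])

    def argmax(self) -> tuple[float, float]:
        """(lon, lat) center of the cell with the largest defined value."""
        c = np.where(self.defined, self.c, -np.inf)
        j, i = np.unravel_index(np.argmax(c), c.shape)
        return float(self.grid.lon_centers[i]), float(self.grid.lat_centers[j])

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: one row per visited cell (i, j, centers, n, W, C)."""
        j, i = np.nonzero(self.n > 0)
        return pd.DataFrame({
            "i": i,
            "j": j,
            "lon_center": self.grid.lon_centers[i],
            "lat_center": self.grid.lat_centers[j],
            "n": self.n[j, i],
            "W": self.w[j, i],
            "C": self.c[j, i],
        })


def compute_cwt(
    tset: TrajectoryEnsembleSet,
    series,
    grid: GridSpec | None = None,
    apply_weight: bool = True,
    nave_mode: str = "occupied",
    tau_mode: str = "endpoint",
    residence: ResidenceField | None = None,
) -> CWTField:
    """Compute the CWT field of a trajectory set against a receptor series.

    Each trajectory contributes its arrival-time concentration to every cell
    it visited, in proportion to its endpoint count there; the count-based
    weight W is then applied (unless ``apply_weight`` is off).
    """
    if grid is None:
        grid = default_grid()
    if residence is None:
        residence = residence_counts(tset, grid, tau_mode=tau_mode)
    arrivals = tset.arrival_times
    if len(arrivals) < 1:
        raise ValueError("trajectory set is empty")
    conc = match_concentrations(arrivals, series)

    tau = residence.tau
    num = np.zeros((grid.n_lat, grid.n_lon))
    if len(tau):
        traj_arrival = residence.trajectories["arrival_time"]
        c_per_traj = conc.loc[traj_arrival].to_numpy()
        c_rows = c_per_traj[tau["traj"].to_numpy()]
        np.add.at(
            num,
            (tau["j"].to_numpy(), tau["i"].to_numpy()),
            c_rows * tau["tau"].to_numpy(),
        )

    n = residence.n
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(n > 0, num / np.where(n > 0, n, 1), np.nan)
    if n.sum() == 0:
        warnings.warn("CWT field is entirely undefined (no endpoints in domain)")
        n_ave = float("nan")
        w = np.ones_like(c)
    else:
        n_ave = residence.n_ave(nave_mode)
        w = weight_factor(n, n_ave) if apply_weight else np.ones_like(c)
        c = c * w
    return CWTField(
        grid=grid, c=c, n=n, w=w, weighted=apply_weight, m=residence.m,
        n_ave_value=n_ave, nave_mode=nave_mode, n_outside=residence.n_outside,
    )


@dataclasses.dataclass
class TimewiseCWT:
    """Per-arrival-time endpoint groups referencing the full-period field."""

    field: CWTField
    groups: list  # [(arrival_time, points DataFrame), ...] in time order

    def __len__(self) -> int:
        return len(self.groups)

    def __iter__(self):
        return iter(self.groups)

    @property
    def arrival_times(self) -> list:
        return [t for t, _ in self.groups]


def hourly_cwt_series(
    tset: TrajectoryEnsembleSet,
    series,
    grid: GridSpec | None = None,
    **cwt_kwargs,
) -> TimewiseCWT:
    """Expose each arrival time's endpoints together with the period CWT field.

    The field is computed once over the whole set; per-time sector fractions
    downstream re-attribute each arrival's endpoints against it.
    """
    field = compute_cwt(tset, series, grid=grid, **cwt_kwargs)
    groups = [
        (t, grp.reset_index(drop=True))
        for t, grp in tset.points.groupby("arrival_time", sort=True)
    ]
    return TimewiseCWT(field=field, groups=groups)


class CWTModel:
    """Receptor model: trajectory set + receptor concentration series.

    Parameters
    ----------
    trajectories : TrajectoryEnsembleSet
    concentrations : Series or DataFrame (``pm25`` column), time-indexed.
    grid : GridSpec, optional
        Defaults to the 0.25 deg grid over the five-sector domain.
    sectors : sequence of SectorDefinition, optional
    apply_weight : bool
        Apply the count-based weighting W (default True).
    nave_mode : {'occupied', 'all'}
        Which cells enter the n_ave mean.
    tau_mode : {'endpoint', 'indicator'}
        Residence counting convention.

    Examples
    --------
    >>> res = CWTModel(tset, pm25).fit()       # doctest: +SKIP
    >>> res.sector_shares()                    # doctest: +SKIP
    """

    def __init__(
        self,
        trajectories: TrajectoryEnsembleSet,
        concentrations,
        grid: GridSpec | None = None,
        sectors: Sequence | None = None,
        apply_weight: bool = True,
        nave_mode: str = "occupied",
        tau_mode: str = "endpoint",
    ):
        self.trajectories = trajectories
        self.concentrations = concentrations
        self.grid = grid if grid is not None else default_grid()
        self.sectors = tuple(sectors) if sectors is not None else sectors_mod.default_sectors()
        self.apply_weight = apply_weight
        self.nave_mode = nave_mode
        self.tau_mode = tau_mode

    def fit(self) -> "CWTResults":
        residence = residence_counts(self.trajectories, self.grid, tau_mode=self.tau_mode)
        field = compute_cwt(
            self.trajectories,
            self.concentrations,
            grid=self.grid,
            apply_weight=self.apply_weight,
            nave_mode=self.nave_mode,
            residence=residence,
        )
        groups = [
            (t, grp.reset_index(drop=True))
            for t, grp in self.trajectories.points.groupby("arrival_time", sort=True)
        ]
        return CWTResults(self, field, residence, TimewiseCWT(field, groups))


class CWTResults:
    """Fitted CWT field plus attribution views."""

    def __init__(self, model: CWTModel, field: CWTField,
                 residence: ResidenceField, timewise: TimewiseCWT):
        self.model = model
        self.field = field
        self.residence = residence
        self.timewise = timewise

    def sector_shares(self) -> pd.DataFrame:
        """Per-sector CWT integrals and normalised shares."""
        return sectors_mod.sector_integrals(self.field, self.model.sectors)

    def timewise_fractions(self, mode: str = "cwt") -> pd.DataFrame:
        """Per-arrival-time air-mass fractions (see :mod:`cwtburden.sectors`)."""
        return sectors_mod.timewise_fractions(
            self.timewise.groups, self.field, self.model.sectors, mode=mode
        )

    def daily_sources(self, mode: str = "count") -> pd.DataFrame:
        """Dominant source sector per calendar day.

        Count mode by default: origin labels should reflect where the air
        resided, not how polluted the cells were.
        """
        return sectors_mod.dominant_source_per_day(
            self.timewise_fractions(mode=mode), self.model.sectors
        )

    def summary(self) -> str:
        f = self.field
        lines = [
            "Concentration-Weighted Trajectory results",
            "=" * 45,
            f"trajectories (M):        {f.m}",
            f"arrival times:           {len(self.timewise)}",
            f"grid:                    {f.grid.n_lon} x {f.grid.n_lat} cells "
            f"@ {f.grid.cell_size} deg",
            f"endpoints outside grid:  {f.n_outside}",
            f"count weighting:         {'on' if f.weighted else 'off'} "
            f"(n_ave = {f.n_ave_value:.3f}, {f.nave_mode} cells)",
            f"defined cells:           {int(f.defined.sum())} / {f.grid.n_cells}",
            "",
            "Sector shares of the CWT integral:",
        ]
        shares = self.sector_shares()
        for _, row in shares.iterrows():
            lines.append(
                f"  {row['sector']:<6s} integral {row['integral']:12.2f}  "
                f"share {row['share']:7.4f}  ({int(row['n_cells'])} cells)"
            )
        return "\n".join(lines)

    def plot_field(self, ax=None, show_sectors: bool = True):
        """Pcolormesh of the CWT field with sector outlines."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 6))
        g = self.field.grid
        lon_edges = g.lon_min + np.arange(g.n_lon + 1) * g.cell_size
        lat_edges = g.lat_min + np.arange(g.n_lat + 1) * g.cell_size
        pm = ax.pcolormesh(lon_edges, lat_edges, self.field.c, shading="flat")
        ax.figure.colorbar(pm, ax=ax, label="CWT PM$_{2.5}$ ($\\mu$g m$^{-3}$)")
        if show_sectors:
            for sec in self.model.sectors:
                ax.add_patch(plt.Rectangle(
                    (sec.lon_range[0], sec.lat_range[0]),
                    sec.lon_range[1] - sec.lon_range[0],
                    sec.lat_range[1] - sec.lat_range[0],
                    fill=False, edgecolor="k", linewidth=0.8,
                ))
                ax.annotate(sec.name, (sec.lon_range[0] + 0.15, sec.lat_range[1] - 0.45),
                            fontsize=8)
        rlat, rlon = self.model.trajectories.receptor
        ax.plot(rlon, rlat, "r^", markersize=8)
        ax.set_xlabel("longitude (deg E)")
        ax.set_ylabel("latitude (deg N)")
        return ax
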