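"""Regular lat/lon grids and trajectory residence (endpoint-count) fields.

The receptor model works on a regular grid (0.25 deg by default) covering the
analysis domain.  Cells are half-open: cell (i, j) covers
``[lon_min + i*s, lon_min + (i+1)*s) x [lat_min + j*s, lat_min + (j+1)*s)``,
so each point belongs to at most one cell and points on the upper/right
domain edge fall outside.

"Residence" follows the endpoint-counting convention: tau_ijl is the number
of hourly endpoints of trajectory l inside cell (i, j), replacing absolute
residence times; n_ij = sum_l tau_ijl.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd

from .trajectory import TrajectoryEnsembleSet

logger = logging.getLogger(__name__)

#: Sentinel returned by :meth:`GridSpec.cell_index` for points not in the domain.
OUTSIDE = None

#: Default analysis domain: the hull of the five source sectors.
DEFAULT_DOMAIN = (108.0, 34.0, 120.0, 43.0)
DEFAULT_CELL_SIZE = 0.25


@dataclasses.dataclass(frozen=True)
class GridSpec:
    """A regular half-open lat/lon grid."""

    lon_min: float
    lat_min: float
    cell_size: float
    n_lon: int
    n_lat: int

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        if self.n_lon < 1 or self.n_lat < 1:
            raise ValueError("grid must have at least one cell on each axis")

    @property
    def lon_max(self) -> float:
        return self.lon_min + self.n_lon * self.cell_size

    @property
    def lat_max(self) -> float:
        return self.lat_min + self.n_lat * self.cell_size

    @property
    def n_cells(self) -> int:
        return self.n_lon * self.n_lat

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon_min + (np.arange(self.n_lon) + 0.5) * self.cell_size

    @property
    def lat_centers(self) -> np.ndarray:
        return self.lat_min + (np.arange(self.n_lat) + 0.5) * self.cell_size

    def cell_index(self, lon: float, lat: float):
        """Cell (i, j) containing the point, or :data:`OUTSIDE`.

        Lower/left edges are inclusive, upper/right edges exclusive.
        """
        if not (np.isfinite(lon) and np.isfinite(lat)):
            return OUTSIDE
        i = int(np.floor((lon - self.lon_min) / self.cell_size))
        j = int(np.floor((lat - self.lat_min) / self.cell_size))
        if 0 <= i < self.n_lon and 0 <= j < self.n_lat:
            return (i, j)
        return OUTSIDE

    def cell_indices(self, lon, lat):
        """Vectorised cell lookup: arrays ``(i, j, inside)``."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        i = np.floor((lon - self.lon_min) / self.cell_size).astype(int)
        j = np.floor((lat - self.lat_min) / self.cell_size).astype(int)
        inside = (
            np.isfinite(lon)
            & np.isfinite(lat)
            & (i >= 0)
            & (i < self.n_lon)
            & (j >= 0)
            & (j < self.n_lat)
        )
        return i, j, inside

    def contains(self, lon: float, lat: float) -> bool:
        return self.cell_index(lon, lat) is not OUTSIDE


def make_grid(
    lon_min: float,
    lat_min: float,
    lon_max: float,
    lat_max: float,
    cell_size: float = DEFAULT_CELL_SIZE,
) -> GridSpec:
    """Build a :class:`GridSpec` covering ``[lon_min, lon_max) x [lat_min, lat_max)``.

    Extents that are not integer multiples of ``cell_size`` are expanded
    outward to the next cell boundary (logged).
    """
    if cell_size <= 0:
        raise ValueError(f"cell_size must be positive, got {cell_size}")
    if lon_max <= lon_min or lat_max <= lat_min:
        raise ValueError("domain max must exceed min on both axes")
    n_lon = (lon_max - lon_min) / cell_size
    n_lat = (lat_max - lat_min) / cell_size
    tol = 1e-9
    n_lon_i = int(np.ceil(n_lon - tol))
    n_lat_i = int(np.ceil(n_lat - tol))
    if abs(n_lon - round(n_lon)) > tol or abs(n_lat - round(n_lat)) > tol:
        logger.info(
            "domain extents not multiples of cell_size=%g; expanded to %d x %d cells",
            cell_size, n_lon_i, n_lat_i,
        )
    return GridSpec(lon_min=lon_min, lat_min=lat_min, cell_size=cell_size,
                    n_lon=n_lon_i, n_lat=n_lat_i)


def default_grid(cell_size: float = DEFAULT_CELL_SIZE) -> GridSpec:
    """The default analysis grid over [108, 120)E x [34, 43)N."""
    return make_grid(*DEFAULT_DOMAIN, cell_size=cell_size)


@dataclasses.dataclass
class ResidenceField:
    """Per-cell endpoint counts of a trajectory set on a grid.

    Attributes
    ----------
    grid : GridSpec
    tau : DataFrame with columns ``traj, i, j, tau`` — endpoint counts per
        trajectory per cell (sparse; only visited cells appear).
    n : int array of shape ``(n_lat, n_lon)`` — total counts n_ij = sum_l tau.
    trajectories : DataFrame mapping integer ``traj`` index to
        ``arrival_time, member_id``.
    n_outside : number of endpoints that fell outside the domain.
    """

    grid: GridSpec
    tau: pd.DataFrame
    n: np.ndarray
    trajectories: pd.DataFrame
    n_outside: int

    @property
    def n_total_inside(self) -> int:
        return int(self.n.sum())

    @property
    def m(self) -> int:
        """Number of trajectories."""
        return len(self.trajectories)

    def n_ave(self, mode: str = "occupied") -> float:
        """Mean trajectory count n_ave used by the weighting function.

        ``mode='occupied'`` (default) averages over cells with n_ij > 0 —
        the receptor-model convention, insensitive to domain padding.
        ``mode='all'`` averages over every domain cell.
        """
        if mode == "occupied":
            occ = self.n[self.n > 0]
            if occ.size == 0:
                raise ValueError("no occupied cells")
            return float(occ.mean())
        if mode == "all":
            return float(self.n.mean())
        raise ValueError(f"unknown n_ave mode {mode!r}")


def residence_counts(
    tset: TrajectoryEnsembleSet,
    grid: GridSpec,
    tau_mode: str = "endpoint",
) -> ResidenceField:
    """Grid a trajectory set into a :class:`ResidenceField`.

    ``tau_mode='endpoint'`` counts hourly endpoints per cell (default);
    ``tau_mode='indicator'`` counts each trajectory at most once per cell.
    Endpoints outside the domain are excluded and tallied in ``n_outside``.
    """
    if tau_mode not in ("endpoint", "indicator"):
        raise ValueError(f"unknown tau_mode {tau_mode!r}")
    pts = tset.points
    if pts.empty:
        raise ValueError("at least one trajectory is required")

    traj_keys = pts[["arrival_time", "member_id"]]
    codes, uniques = pd.factorize(
        pd.MultiIndex.from_frame(traj_keys), sort=True
    )
    trajectories = pd.DataFrame(
        list(uniques), columns=["arrival_time", "member_id"]
    )
    trajectories.index.name = "traj"

    i, j, inside = grid.cell_indices(pts["lon"].to_numpy(), pts["lat"].to_numpy())
    n_outside = int((~inside).sum())
    if not inside.any():
        warnings.warn("no trajectory endpoints fall inside the grid domain")
        tau = pd.DataFrame(columns=["traj", "i", "j", "tau"]).astype(int)
        n = np.zeros((grid.n_lat, grid.n_lon), dtype=int)
        return ResidenceField(grid, tau, n, trajectories, n_outside)

    tau = (
        pd.DataFrame({"traj": codes[inside], "i": i[inside], "j": j[inside]})
        .groupby(["traj", "i", "j"], sort=True)
        .size()
        .rename("tau")
        .reset_index()
    )
    if tau_mode == "indicator":
        tau["tau"] = 1

    n = np.zeros((grid.n_lat, grid.n_lon), dtype=int)
    np.add.at(n, (tau["j"].to_numpy(), tau["i"].to_numpy()), tau["tau"].to_numpy())
    return ResidenceField(grid, tau, n, trajectories, n_outside)
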