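"""Back-trajectory data model and HYSPLIT-style endpoint ("tdump") file I/O.

The pipeline consumes *endpoint files*: plain-text records of where an air
parcel that arrives at the receptor was at each hour of its backward run.
An *ensemble* is the group of (by default 27) perturbed-member trajectories
sharing one arrival time; a set collects the ensembles of a whole analysis
period, one arrival every few hours.

All timestamps are UTC.  Longitudes are normalised to [-180, 180).
Heights are carried through but not used by the planar CWT method.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

#: Beijing monitoring site the analysis is anchored to (lat, lon; 250 m a.s.l.)
RECEPTOR_LAT = 39.98
RECEPTOR_LON = 116.40
RECEPTOR = (RECEPTOR_LAT, RECEPTOR_LON)

POINT_COLUMNS = ["arrival_time", "member_id", "age_h", "lat", "lon", "height"]


class EndpointFormatError(ValueError):
    """An endpoint file violates the expected record layout."""


def normalize_lon(lon):
    """Normalise longitudes to the [-180, 180) convention.

    Accepts scalars or arrays; 360-periodic, lower-closed.
    """
    out = ((np.asarray(lon, dtype=float) + 180.0) % 360.0) - 180.0
    if out.ndim == 0:
        return float(out)
    return out


def _as_utc(ts) -> pd.Timestamp:
    ts = pd.Timestamp(ts)
    if ts.tzinfo is None:
        return ts.tz_localize("UTC")
    return ts.tz_convert("UTC")


@dataclasses.dataclass
class TrajectoryEnsemble:
    """All member trajectories arriving at the receptor at one time.

    Parameters
    ----------
    arrival_time : timestamp (UTC)
    points : DataFrame with columns ``member_id, age_h, lat, lon, height``;
        ``age_h`` runs 0 (arrival) down to ``-T`` (oldest position).
    receptor : (lat, lon) of the arrival point.
    """

    arrival_time: pd.Timestamp
    points: pd.DataFrame
    receptor: tuple[float, float] = RECEPTOR

    def __post_init__(self):
        self.arrival_time = _as_utc(self.arrival_time)

    @property
    def member_ids(self) -> np.ndarray:
        return np.sort(self.points["member_id"].unique())

    @property
    def n_members(self) -> int:
        return int(self.points["member_id"].nunique())

    def member(self, member_id: int) -> pd.DataFrame:
        out = self.points[self.points["member_id"] == member_id]
        if out.empty:
            raise KeyError(f"no member {member_id}")
        return out.sort_values("age_h", ascending=False)

    def validate(self, receptor_tol: float = 0.01, n_members: int | None = None) -> None:
        """Check structural invariants; raise ``EndpointFormatError`` on failure.

        Each member must have unique, contiguous ages 0, -1, ..., -T, and its
        age-0 point must coincide with the receptor within ``receptor_tol``
        degrees on both axes.
        """
        if n_members is not None and self.n_members != n_members:
            raise EndpointFormatError(
                f"ensemble {self.arrival_time}: {self.n_members} members, "
                f"expected {n_members}"
            )
        for mid, grp in self.points.groupby("member_id"):
            ages = np.sort(grp["age_h"].to_numpy())[::-1]
            expected = -np.arange(len(ages))
            if len(np.unique(ages)) != len(ages) or not np.array_equal(ages, expected):
                raise EndpointFormatError(
                    f"member {mid} of ensemble {self.arrival_time}: ages are not "
                    f"a contiguous descending sequence from 0 (got {ages.tolist()})"
                )
            p0 = grp[grp["age_h"] == 0].iloc[0]
            if (
                abs(p0["lat"] - self.receptor[0]) > receptor_tol
                or abs(p0["lon"] - self.receptor[1]) > receptor_tol
            ):
                raise EndpointFormatError(
                    f"member {mid} of ensemble {self.arrival_time}: arrival point "
                    f"({p0['lat']:.3f}, {p0['lon']:.3f}) is not at the receptor "
                    f"{self.receptor} (tol {receptor_tol} deg)"
                )


@dataclasses.dataclass
class TrajectoryEnsembleSet:
    """Ensembles for a whole analysis period, ordered by arrival time.

    ``points`` is one flat table with columns
    ``arrival_time, member_id, age_h, lat, lon, height`` — the vectorised
    representation every gridding step operates on.
    """

    points: pd.DataFrame
    receptor: tuple[float, float] = RECEPTOR
    arrival_spacing_h: int | None = None

    def __post_init__(self):
        pts = self.points
        missing = [c for c in POINT_COLUMNS if c not in pts.columns]
        if missing:
            raise ValueError(f"points table missing columns {missing}")
        pts = pts[POINT_COLUMNS].copy()
        pts["arrival_time"] = pd.to_datetime(pts["arrival_time"], utc=True)
        pts["lon"] = normalize_lon(pts["lon"].to_numpy())
        pts = pts.sort_values(["arrival_time", "member_id", "age_h"],
                              ascending=[True, True, False])
        self.points = pts.reset_index(drop=True)

    @classmethod
    def from_ensembles(
        cls,
        ensembles: Sequence[TrajectoryEnsemble],
        arrival_spacing_h: int | None = None,
    ) -> "TrajectoryEnsembleSet":
        if not ensembles:
            raise ValueError("no ensembles given")
        frames = []
        for ens in ensembles:
            f = ens.points.copy()
            f.insert(0, "arrival_time", ens.arrival_time)
            frames.append(f)
        return cls(
            pd.concat(frames, ignore_index=True),
            receptor=ensembles[0].receptor,
            arrival_spacing_h=arrival_spacing_h,
        )

    @property
    def arrival_times(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(np.sort(self.points["arrival_time"].unique()))

    @property
    def n_ensembles(self) -> int:
        return len(self.arrival_times)

    @property
    def n_points(self) -> int:
        return len(self.points)

    def ensembles(self) -> Iterator[TrajectoryEnsemble]:
        for t, grp in self.points.groupby("arrival_time", sort=True):
            yield TrajectoryEnsemble(
                arrival_time=t,
                points=grp.drop(columns="arrival_time").reset_index(drop=True),
                receptor=self.receptor,
            )

    def __iter__(self) -> Iterator[TrajectoryEnsemble]:
        return self.ensembles()

    def validate(self, receptor_tol: float = 0.01, n_members: int | None = None) -> None:
        times = self.points["arrival_time"]
        if times.isna().any():
            raise EndpointFormatError("missing arrival times")
        for ens in self.ensembles():
            ens.validate(receptor_tol=receptor_tol, n_members=n_members)


# ---------------------------------------------------------------------------
# Endpoint ("tdump") file layout
#
# header:   n_met_grids, then one line per met grid (model id, start time),
#           then "N BACKWARD OMEGA", then one start line per trajectory
#           (yy mm dd hh  lat lon height), then "k DIAG ..." naming the
#           per-record diagnostic columns.
# records:  traj# grid# yy mm dd hh mn fcsthr age lat lon height diag...
#
# Coordinates are written to 3 decimal places, heights to 1 — the format's
# native precision, and the precision at which round-trips are exact.
# ---------------------------------------------------------------------------

_MODEL_ID = "SYNT"


def _two_digit_year(ts: pd.Timestamp) -> int:
    return ts.year % 100


def _expand_year(yy: int) -> int:
    return 1900 + yy if yy >= 70 else 2000 + yy


def write_endpoint_file(tset: TrajectoryEnsembleSet, path) -> Path:
    """Write a trajectory ensemble set as a HYSPLIT-style endpoint file.

    Trajectories are numbered sequentially grouped by arrival time and
    member id, so ``read_endpoint_file`` reconstructs the set exactly at
    format precision.
    """
    if tset.points.empty:
        raise ValueError("cannot write an empty trajectory set")
    path = Path(path)

    pts = tset.points
    groups = list(pts.groupby(["arrival_time", "member_id"], sort=True))
    lines = []
    lines.append(f"{1:6d}{1:6d}")
    t0 = _as_utc(groups[0][0][0])
    lines.append(
        f"{_MODEL_ID:>8s}{_two_digit_year(t0):6d}{t0.month:6d}{t0.day:6d}"
        f"{t0.hour:6d}{0:6d}"
    )
    lines.append(f"{len(groups):6d} BACKWARD OMEGA")
    for (arrival, _mid), grp in groups:
        arrival = _as_utc(arrival)
        start = grp[grp["age_h"] == 0]
        if start.empty:
            raise ValueError(
                f"member {_mid} of ensemble {arrival} has no age-0 point"
            )
        s = start.iloc[0]
        lines.append(
            f"{_two_digit_year(arrival):6d}{arrival.month:6d}{arrival.day:6d}"
            f"{arrival.hour:6d}{s['lat']:9.3f}{s['lon']:9.3f}{s['height']:9.1f}"
        )
    lines.append(f"{1:6d} PRESSURE")
    for tnum, ((arrival, _mid), grp) in enumerate(groups, start=1):
        arrival = _as_utc(arrival)
        for _, row in grp.sort_values("age_h", ascending=False).iterrows():
            age = int(row["age_h"])
            ptime = arrival + pd.Timedelta(hours=age)
            lines.append(
                f"{tnum:6d}{1:6d}{_two_digit_year(ptime):6d}{ptime.month:6d}"
                f"{ptime.day:6d}{ptime.hour:6d}{ptime.minute:6d}{0:6d}"
                f"{float(age):8.1f}{row['lat']:9.3f}{row['lon']:9.3f}"
                f"{row['height']:9.1f}{0.0:9.1f}"
            )
    path.write_text("\n".join(lines) + "\n")
    return path


def read_endpoint_file(
    path,
    receptor: tuple[float, float] = RECEPTOR,
    arrival_spacing_h: int | None = None,
    validate: bool = True,
    receptor_tol: float = 0.01,
) -> TrajectoryEnsembleSet:
    """Parse a HYSPLIT-style endpoint file into a :class:`TrajectoryEnsembleSet`.

    Records are grouped by arrival time (position time minus signed age);
    member ids are assigned 1..k within each arrival group in trajectory-number
    order, which reproduces the writer's numbering.  Every data line becomes
    exactly one point — nothing is silently dropped.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    EndpointFormatError
        On an empty file, a malformed record (naming the line number), or —
        when ``validate`` — a member whose ages are not contiguous.
    """
    path = Path(path)
    raw = path.read_text().splitlines()
    lines = [(i + 1, ln) for i, ln in enumerate(raw) if ln.strip()]
    if not lines:
        raise EndpointFormatError(f"{path}: empty endpoint file")

    def _ints(lineno, text, n):
        toks = text.split()
        try:
            return [int(float(t)) for t in toks[:n]]
        except ValueError as exc:
            raise EndpointFormatError(
                f"{path}: line {lineno}: expected numeric fields, got {toks[:n]}"
            ) from exc

    pos = 0
    lineno, header = lines[pos]
    (n_grids,) = _ints(lineno, header, 1)
    pos += 1 + n_grids  # skip met grid headers
    if pos >= len(lines):
        raise EndpointFormatError(f"{path}: truncated header")
    lineno, ln = lines[pos]
    (n_traj,) = _ints(lineno, ln, 1)
    pos += 1 + n_traj  # skip trajectory start lines
    if pos >= len(lines):
        raise EndpointFormatError(f"{path}: truncated header (no diagnostics line)")
    pos += 1  # diagnostics declaration

    records = []
    for lineno, ln in lines[pos:]:
        toks = ln.split()
        if len(toks) < 12:
            raise EndpointFormatError(
                f"{path}: line {lineno}: endpoint record has {len(toks)} fields, "
                "expected at least 12"
            )
        try:
            vals = [float(t) for t in toks[:12]]
        except ValueError:
            raise EndpointFormatError(
                f"{path}: line {lineno}: non-numeric field in endpoint record"
            ) from None
        tnum = int(vals[0])
        yy, mo, da, hr, mn = (int(v) for v in vals[2:7])
        age = vals[8]
        if abs(age - round(age)) > 1e-6:
            raise EndpointFormatError(
                f"{path}: line {lineno}: non-integer trajectory age {age}"
            )
        age = int(round(age))
        try:
            ptime = pd.Timestamp(_expand_year(yy), mo, da, hr, mn, tz="UTC")
        except ValueError as exc:
            raise EndpointFormatError(
                f"{path}: line {lineno}: invalid timestamp"
            ) from exc
        arrival = ptime - pd.Timedelta(hours=age)
        records.append((arrival, tnum, age, vals[9], vals[10], vals[11]))

    if not records:
        raise EndpointFormatError(f"{path}: no endpoint records")

    df = pd.DataFrame(
        records, columns=["arrival_time", "tnum", "age_h", "lat", "lon", "height"]
    )
    # member ids: 1..k per arrival group, ordered by trajectory number
    df["member_id"] = 0
    for _, idx in df.groupby("arrival_time").groups.items():
        sub = df.loc[idx]
        order = {t: i + 1 for i, t in enumerate(np.sort(sub["tnum"].unique()))}
        df.loc[idx, "member_id"] = sub["tnum"].map(order)
    df = df.drop(columns="tnum")

    tset = TrajectoryEnsembleSet(
        df, receptor=receptor, arrival_spacing_h=arrival_spacing_h
    )
    if tset.n_points != len(records):  # pragma: no cover - reader contract
        raise EndpointFormatError(f"{path}: reader dropped records")
    if validate:
        tset.validate(receptor_tol=receptor_tol)
    return tset


# ---------------------------------------------------------------------------
# Concentration / meteorology CSV tables
# ---------------------------------------------------------------------------

MET_COLUMNS = ["ws", "rh", "t", "p"]


def read_series_csv(path) -> pd.DataFrame:
    """Read a receptor time-series CSV (columns ``time, pm25[, ws, rh, t, p]``).

    Returns a DataFrame indexed by UTC timestamps.
    """
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise ValueError(f"{path}: expected a 'time' column")
    df["time"] = pd.to_datetime(df["time"], utc=True)
    return df.set_index("time").sort_index()


def write_series_csv(data, path) -> Path:
    """Write a concentration (and optional meteorology) table to CSV."""
    path = Path(path)
    if isinstance(data, pd.Series):
        data = data.rename("pm25").to_frame()
    out = data.copy()
    out.insert(0, "time", out.index.strftime("%Y-%m-%dT%H:%M:%SZ"))
    out.to_csv(path, index=False, float_format="%.6f")
    return path
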