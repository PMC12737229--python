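"""Short-term PM2.5 relative risk and attributable fraction.

Daily health burden follows the standard log-linear concentration-response
model:

    RR = exp(beta_eff * (C - C0)),        AF = (RR - 1) / RR

with C the daily mean PM2.5 (ug m^-3), C0 a threshold concentration
(0 by default, i.e. no safe level), and beta_eff the concentration-response
slope per ug m^-3.

The nominal coefficient is quoted as beta = 0.38 (range 0.31-0.45) on an
unstated scale; applied literally per ug m^-3 it saturates AF at ~1 for any
realistic concentration.  The model therefore keeps the printed beta and an
explicit ``beta_scale`` divisor (default 100, i.e. beta per 100 ug m^-3,
a magnitude consistent with short-term exposure epidemiology), so
beta_eff = beta / beta_scale.  Every output records the scale used; no
single interpretation is hard-coded.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .summaries import group_stats


@dataclasses.dataclass
class HealthParams:
    """Concentration-response parameters.

    beta : printed coefficient (dimensionless as quoted; default 0.38)
    beta_range : (min, max) for sensitivity analysis, default (0.31, 0.45)
    c0 : threshold concentration, ug m^-3 (default 0)
    beta_scale : divisor mapping beta to per-(ug m^-3) units (default 100)
    """

    beta: float = 0.38
    beta_range: tuple[float, float] = (0.31, 0.45)
    c0: float = 0.0
    beta_scale: float = 100.0

    def __post_init__(self):
        if not (self.beta_range[0] <= self.beta <= self.beta_range[1]):
            raise ValueError(
                f"beta={self.beta} outside beta_range={self.beta_range}"
            )
        if self.c0 < 0:
            raise ValueError("c0 must be non-negative")
        if self.beta_scale <= 0:
            raise ValueError("beta_scale must be positive")

    @property
    def beta_eff(self) -> float:
        """Slope per ug m^-3 actually used in the exponent."""
        return self.beta / self.beta_scale

    def with_beta(self, beta: float) -> "HealthParams":
        return dataclasses.replace(self, beta=beta)


#: Days with fewer valid hours than this are flagged incomplete.
MIN_VALID_HOURS = 18


def daily_mean(series: pd.Series, min_hours: int = MIN_VALID_HOURS) -> pd.DataFrame:
    """Daily mean concentration from an hourly series.

    Returns a frame indexed by (UTC) date with columns ``pm25``, ``n_hours``
    and ``complete`` (at least ``min_hours`` of the 24 present).  Days with
    no valid hour at all are absent (warned about); incomplete days are kept
    but flagged.
    """
    if isinstance(series, pd.DataFrame):
        series = series["pm25"]
    series = series.dropna()
    if series.empty:
        raise ValueError("concentration series is empty")
    idx = pd.to_datetime(series.index, utc=True)
    by_day = series.groupby(idx.floor("D"))
    out = pd.DataFrame({
        "pm25": by_day.mean(),
        "n_hours": by_day.size(),
    })
    out["complete"] = out["n_hours"] >= min_hours
    full_range = pd.date_range(out.index.min(), out.index.max(), freq="D")
    missing = full_range.difference(out.index)
    if len(missing):
        warnings.warn(f"{len(missing)} day(s) in range have no valid hours and are absent")
    out.index.name = "date"
    return out


def relative_risk(c, params: HealthParams | None = None):
    """RR = exp(beta_eff * (C - C0)); equals 1 at C = C0. Scalar or array."""
    if params is None:
        params = HealthParams()
    c = np.asarray(c, dtype=float)
    rr = np.exp(params.beta_eff * (c - params.c0))
    if rr.ndim == 0:
        return float(rr)
    return rr


def attributable_fraction(rr):
    """AF = (RR - 1)/RR, the burden share attributable to the exposure.

    Strictly increasing in RR, always < 1; RR must be positive.
    """
    rr = np.asarray(rr, dtype=float)
    if (rr <= 0).any():
        raise ValueError("relative risk must be positive")
    af = (rr - 1.0) / rr
    if af.ndim == 0:
        return float(af)
    return af


def beta_sensitivity(daily_c, params: HealthParams | None = None):
    """Per-day AF under the minimum, nominal and maximum beta.

    Returns ``(frame, spread)``: a frame with columns ``af_low, af_mid,
    af_high`` and the maximum over days of ``|AF_extreme - AF_mid| / AF_mid``
    (days with AF_mid = 0 excluded; NaN if none remain).
    """
    if params is None:
        params = HealthParams()
    daily_c = pd.Series(np.asarray(daily_c, dtype=float),
                        index=getattr(daily_c, "index", None))
    lo, hi = params.beta_range
    out = pd.DataFrame({
        "af_low": attributable_fraction(relative_risk(daily_c, params.with_beta(lo))),
        "af_mid": attributable_fraction(relative_risk(daily_c, params)),
        "af_high": attributable_fraction(relative_risk(daily_c, params.with_beta(hi))),
    }, index=daily_c.index)
    mid = out["af_mid"]
    nz = mid != 0
    if nz.any():
        rel = np.maximum(
            (out.loc[nz, "af_mid"] - out.loc[nz, "af_low"]).abs() / mid[nz].abs(),
            (out.loc[nz, "af_high"] - out.loc[nz, "af_mid"]).abs() / mid[nz].abs(),
        )
        spread = float(rel.max())
    else:
        spread = float("nan")
    return out, spread


def burden_by_source(burden: pd.DataFrame, labels: pd.Series | None = None,
                     value: str = "af") -> pd.DataFrame:
    """Distribution statistics of a burden variable grouped by source sector.

    ``burden`` is a daily frame (as produced by :class:`HealthBurdenModel`);
    ``labels`` maps dates to sector names (omit if ``burden`` already has a
    ``source`` column).  Raises if any burden date lacks a label.
    """
    df = burden.copy()
    if labels is not None:
        labels = pd.Series(labels)
        labels.index = pd.to_datetime(labels.index, utc=True)
        df["source"] = labels.reindex(df.index)
    if "source" not in df.columns:
        raise ValueError("no source labels supplied")
    orphans = df.index[df["source"].isna()]
    if len(orphans):
        shown = ", ".join(str(d.date()) for d in orphans[:5])
        raise ValueError(
            f"{len(orphans)} burden day(s) have no source label: {shown}"
            f"{'...' if len(orphans) > 5 else ''}"
        )
    return group_stats(df[value], df["source"])


class HealthBurdenModel:
    """Daily RR/AF model over an hourly receptor concentration series.

    Parameters
    ----------
    concentrations : hourly Series (or frame with ``pm25``), time-indexed.
    params : HealthParams, optional
    source_labels : Series mapping dates to dominant-source names, optional.
    min_hours : daily completeness threshold (default 18 of 24).
    """

    def __init__(self, concentrations, params: HealthParams | None = None,
                 source_labels: pd.Series | None = None,
                 min_hours: int = MIN_VALID_HOURS):
        self.concentrations = concentrations
        self.params = params if params is not None else HealthParams()
        self.source_labels = source_labels
        self.min_hours = min_hours

    def fit(self) -> "HealthBurdenResults":
        daily = daily_mean(self.concentrations, min_hours=self.min_hours)
        burden = daily.copy()
        burden["rr"] = relative_risk(burden["pm25"], self.params)
        burden["af"] = attributable_fraction(burden["rr"])
        sens, spread = beta_sensitivity(burden["pm25"], self.params)
        burden = burden.join(sens[["af_low", "af_high"]])
        if self.source_labels is not None:
            labels = pd.Series(self.source_labels)
            labels.index = pd.to_datetime(labels.index, utc=True)
            burden["source"] = labels.reindex(burden.index)
        return HealthBurdenResults(self, burden, spread)


class HealthBurdenResults:
    """Daily burden table plus per-source summaries."""

    def __init__(self, model: HealthBurdenModel, burden: pd.DataFrame, spread: float):
        self.model = model
        self.burden = burden
        self.beta_spread = spread

    @property
    def params(self) -> HealthParams:
        return self.model.params

    def by_source(self, value: str = "af") -> pd.DataFrame:
        return burden_by_source(self.burden, value=value)

    def summary(self) -> str:
        p = self.params
        b = self.burden
        lines = [
            "Short-term PM2.5 health burden",
            "=" * 45,
            f"days:                 {len(b)} "
            f"({int(b['complete'].sum())} complete)",
            f"beta:                 {p.beta} (range {p.beta_range[0]}-{p.beta_range[1]}), "
            f"scale 1/{p.beta_scale:g} -> beta_eff = {p.beta_eff:.5f} per ug m^-3",
            f"threshold C0:         {p.c0} ug m^-3",
            f"mean daily PM2.5:     {b['pm25'].mean():.2f} ug m^-3",
            f"mean RR:              {b['rr'].mean():.4f}",
            f"mean AF:              {b['af'].mean():.4f} "
            f"[beta-range spread {self.beta_spread:.3f}]",
        ]
        if "source" in b.columns and b["source"].notna().any():
            lines.append("")
            lines.append("Mean AF by dominant source:")
            stats = self.by_source("af")
            for _, row in stats.iterrows():
                lines.append(
                    f"  {row['group']:<6s} n={int(row['n']):3d}  mean {row['mean']:.3f}  "
                    f"p10 {row['p10']:.3f}  p90 {row['p90']:.3f}"
                )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Daily AF (with beta-range band) and concentration time series."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 4))
        b = self.burden
        ax.fill_between(b.index, b["af_low"], b["af_high"], alpha=0.3,
                        label="AF (beta range)")
        ax.plot(b.index, b["af"], lw=1.2, label="AF")
        ax.set_ylabel("attributable fraction")
        ax2 = ax.twinx()
        ax2.plot(b.index, b["pm25"], color="gray", lw=0.8, alpha=0.7)
        ax2.set_ylabel("daily PM$_{2.5}$ ($\\mu$g m$^{-3}$)")
        ax.legend(loc="upper left", fontsize=8)
        return ax
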