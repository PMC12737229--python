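"""Per-group distribution summaries in the box-whisker convention.

Each group is summarised by its mean, the 25th/75th percentiles (box) and
the 10th/90th percentiles (whiskers).  Percentiles use linear interpolation
between closest ranks — the k-th of n sorted points sits at quantile
(k-1)/(n-1) — so a single-value group collapses to that value and the
statistics are deterministic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

PERCENTILES = (10, 25, 75, 90)


def group_stats(values, labels) -> pd.DataFrame:
    """Summarise ``values`` grouped by ``labels``.

    Returns one row per group with columns
    ``group, n, mean, p10, p25, p75, p90``; groups in sorted label order.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if len(values) != len(labels):
        raise ValueError("values and labels must be aligned")
    ok = np.isfinite(values)
    values, labels = values[ok], labels[ok]
    if len(values) == 0:
        raise ValueError("no finite values to summarise")
    rows = []
    for g in sorted(pd.unique(labels)):
        v = values[labels == g]
        p = np.percentile(v, PERCENTILES, method="linear")
        rows.append({
            "group": g, "n": len(v), "mean": float(v.mean()),
            "p10": float(p[0]), "p25": float(p[1]),
            "p75": float(p[2]), "p90": float(p[3]),
        })
    return pd.DataFrame(rows)
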