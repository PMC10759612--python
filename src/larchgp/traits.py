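"""Derived phenotypes and descriptive statistics.

Stem volume comes from an allometric equation for Japanese larch,

    V (dm^3) = 0.0592372 * DBH^2 * H^0.98098926

with DBH in cm and height H in m.  Competitive pressure on a tree is the
Hegyi index over its first-order grid neighbours,

    CI_i = sum_j (DBH_j / DBH_i) / D_ij

with D_ij = spacing for row/column neighbours and spacing * sqrt(2) on the
diagonal.  Edge and corner trees simply have fewer neighbours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DescriptiveStats", "stem_volume", "hegyi_ci", "hegyi_ci_grid", "describe_trait"]

_VOLUME_COEF = 0.0592372
_VOLUME_H_EXP = 0.98098926


def stem_volume(dbh, height):
    """Stem volume in dm^3 from DBH (cm) and height (m); vectorised."""
    dbh = np.asarray(dbh, dtype=float)
    height = np.asarray(height, dtype=float)
    if np.any(dbh <= 0) or np.any(height <= 0):
        raise ValueError("DBH and height must be strictly positive")
    out = _VOLUME_COEF * dbh**2 * height**_VOLUME_H_EXP
    return float(out) if out.ndim == 0 else out


def hegyi_ci(
    focal_dbh: float,
    neighbor_dbhs,
    neighbor_offsets,
    spacing: float = 2.0,
) -> float:
    """Hegyi competition index for one tree.

    *neighbor_offsets* are (d_row, d_col) grid offsets; each must be a
    first-order (Chebyshev distance 1) neighbour.
    """
    if focal_dbh <= 0:
        raise ValueError("focal DBH must be positive")
    neighbor_dbhs = np.asarray(neighbor_dbhs, dtype=float)
    if not 1 <= len(neighbor_dbhs) <= 8:
        raise ValueError("between 1 and 8 neighbours expected")
    total = 0.0
    for dbh_j, (dr, dc) in zip(neighbor_dbhs, neighbor_offsets):
        if max(abs(dr), abs(dc)) != 1:
            raise ValueError(f"offset {(dr, dc)} is not a first-order neighbour")
        dist = spacing * (math.sqrt(2.0) if dr != 0 and dc != 0 else 1.0)
        total += (dbh_j / focal_dbh) / dist
    return total


def hegyi_ci_grid(layout: pd.DataFrame, spacing: float = 2.0) -> pd.Series:
    """Hegyi index for every tree on a planting grid.

    *layout* needs columns ``id``, ``row``, ``col``, ``dbh``.  Neighbours are
    the up-to-eight trees at Chebyshev distance 1; absent positions are
    omitted from the sum.
    """
    pos = {(int(r), int(c)): (i, d) for i, r, c, d in
           zip(layout["id"], layout["row"], layout["col"], layout["dbh"])}
    offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    out = {}
    for (r, c), (iid, dbh_i) in pos.items():
        if dbh_i <= 0:
            raise ValueError(f"tree {iid!r} has non-positive DBH")
        ci = 0.0
        for dr, dc in offsets:
            hit = pos.get((r + dr, c + dc))
            if hit is None:
                continue
            dist = spacing * (math.sqrt(2.0) if dr != 0 and dc != 0 else 1.0)
            ci += (hit[1] / dbh_i) / dist
        out[iid] = ci
    ordered = pd.Series(out).loc[layout["id"]].to_numpy()
    return pd.Series(ordered, index=layout.index, name="CI")


@dataclass
class DescriptiveStats:
    mean: float
    sd: float
    min: float
    max: float
    cv_percent: float | None  # None when mean <= 0 makes CV undefined
    n: int

    def as_dict(self) -> dict:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "min": self.min,
            "max": self.max,
            "cv_percent": self.cv_percent,
            "n": self.n,
        }


def describe_trait(values) -> DescriptiveStats:
    """Mean, sample SD (n-1), min, max and CV% of a trait vector.

    Missing entries (NaN) are skipped.  CV% = sd / mean * 100 is flagged
    undefined (None) when the mean is not positive.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 2:
        raise ValueError("need at least 2 non-missing values")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    cv = sd / mean * 100.0 if mean > 0 else None
    return DescriptiveStats(mean, sd, float(x.min()), float(x.max()), cv, len(x))


def describe_table(pheno: pd.DataFrame, traits: list[str]) -> pd.DataFrame:
    """Descriptive-statistics table (one row per trait) for a phenotype frame."""
    rows = {t: describe_trait(pheno[t]).as_dict() for t in traits}
    return pd.DataFrame.from_dict(rows, orient="index")
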