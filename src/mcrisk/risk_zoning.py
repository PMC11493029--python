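"""Five-level source–sink risk classification of the MCR surface.

Natural-breaks (Fisher–Jenks) classification minimises the total
within-class sum of squared deviations over ordered partitions of the
sorted values.  The exact dynamic program is used (not the heuristic
iterative variant) so results are deterministic and checkable against
exhaustive enumeration.

Risk semantics invert the MCR ordering: the smaller the accumulated
resistance, the easier pollutants reach a cell from a source patch, so the
lowest-MCR class is *extremely high risk* (code 5) and the highest-MCR
class *extremely low risk* (code 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cost_distance import MCRSurface
from .grid_io import Raster

__all__ = ["RiskMap", "RISK_LABELS", "jenks_breaks", "classify_risk", "risk_shares"]

RISK_LABELS = {
    5: "extremely high risk",
    4: "high risk",
    3: "medium risk",
    2: "low risk",
    1: "extremely low risk",
}


@dataclass
class RiskMap:
    """Integer risk classes 1–5 on the grid, plus the MCR break values."""

    raster: Raster  # semantic "riskclass"
    breaks: list[float]
    labels: dict[int, str] = field(default_factory=lambda: dict(RISK_LABELS))
    source_type: str = "PFSL"

    def __post_init__(self) -> None:
        codes = np.unique(self.raster.values[self.raster.mask]).astype(int)
        if not set(codes) <= set(range(1, 6)):
            raise ValueError(f"risk codes outside 1..5: {sorted(set(codes))}")


def _ssq_table(x: np.ndarray):
    """Prefix sums for O(1) within-class sum of squared deviations."""
    s = np.concatenate(([0.0], np.cumsum(x)))
    s2 = np.concatenate(([0.0], np.cumsum(x * x)))

    def ssq(i: np.ndarray | int, j: np.ndarray | int):
        # inclusive 0-based range i..j
        n = np.asarray(j) - np.asarray(i) + 1
        tot = s[np.asarray(j) + 1] - s[np.asarray(i)]
        return (s2[np.asarray(j) + 1] - s2[np.asarray(i)]) - tot * tot / n

    return ssq


def jenks_breaks(values, k: int) -> list[float]:
    """Exact Fisher–Jenks natural breaks.

    Returns the k−1 interior break values (the maximum of each of the first
    k−1 classes) of the SSD-minimising ordered partition of the sorted
    data.  Ties between optimal partitions resolve to the earliest split
    positions.
    """
    x = np.sort(np.asarray(values, dtype=float).ravel())
    n = x.size
    if not np.all(np.isfinite(x)):
        raise ValueError("jenks_breaks requires finite values")
    if k < 2 or n < k:
        raise ValueError(f"need n ≥ k ≥ 2, got n={n}, k={k}")

    ssq = _ssq_table(x)
    idx = np.arange(n)
    # dp[i] = min SSD of partitioning x[0..i] into c classes
    dp = ssq(0, idx)
    # split[c][i] = last-class start index of the optimal c+1-class partition
    splits = np.zeros((k, n), dtype=np.int64)
    for c in range(1, k):
        new_dp = np.full(n, np.inf)
        for i in range(c, n):
            j = np.arange(c - 1, i)  # end of previous class
            cand = dp[j] + ssq(j + 1, i)
            best = int(np.argmin(cand))
            new_dp[i] = cand[best]
            splits[c, i] = j[best] + 1  # start index of the last class
        dp = new_dp

    # backtrack class boundaries
    bounds = []
    i = n - 1
    for c in range(k - 1, 0, -1):
        start = int(splits[c, i])
        bounds.append(start)
        i = start - 1
    bounds.reverse()  # start indices of classes 2..k
    return [float(x[b - 1]) for b in bounds]


def jenks_total_ssd(values, breaks) -> float:
    """Total within-class SSD of the partition induced by the breaks."""
    x = np.sort(np.asarray(values, dtype=float).ravel())
    cls = np.digitize(x, np.asarray(breaks), right=True)
    total = 0.0
    for c in np.unique(cls):
        v = x[cls == c]
        total += float(np.sum((v - v.mean()) ** 2))
    return total


def classify_risk(
    mcr: MCRSurface,
    k: int = 5,
    sample_cap: int = 5000,
    seed: int = 0,
) -> RiskMap:
    """Classify the MCR surface into k risk levels by natural breaks.

    Breaks are computed on all finite MCR cells, or on a seeded uniform
    subsample of ``sample_cap`` cells when the raster is larger (the exact
    dynamic program is quadratic in n).  Intervals are left-open /
    right-closed except the first, so exact break values fall in the lower
    class.  Class codes invert the MCR order: code k = lowest MCR.
    """
    r = mcr.raster
    vals = mcr.finite()
    finite = vals[np.isfinite(vals)]
    if np.unique(finite).size < k:
        raise ValueError(f"need at least {k} distinct finite MCR values")
    sample = finite
    if finite.size > sample_cap:
        rng = np.random.default_rng(seed)
        sample = rng.choice(finite, size=sample_cap, replace=False)
        # keep the global extremes so the outer intervals cover the data
        sample = np.concatenate((sample, [finite.min(), finite.max()]))
        if np.unique(sample).size < k:
            sample = finite
    breaks = jenks_breaks(sample, k)
    interval = np.digitize(vals, np.asarray(breaks), right=True)  # 0 = lowest MCR
    codes = (k - interval).astype(np.int64)  # lowest MCR -> code k (highest risk)
    codes_arr = np.where(np.isfinite(vals), codes, np.int64(r.nodata))
    return RiskMap(
        raster=r.like(codes_arr, semantic="riskclass"),
        breaks=list(breaks),
        source_type=mcr.source_type,
    )


def risk_shares(risk: RiskMap) -> pd.DataFrame:
    """Per-class cell counts and area fractions (fractions sum to 1)."""
    vals = risk.raster.values[risk.raster.mask].astype(int)
    counts = pd.Series(vals).value_counts().sort_index()
    df = pd.DataFrame({
        "risk_class": counts.index,
        "label": [risk.labels[c] for c in counts.index],
        "cell_count": counts.values,
    })
    df["fraction"] = df["cell_count"] / df["cell_count"].sum()
    return df.reset_index(drop=True)
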