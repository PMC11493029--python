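"""Zonal statistics and the multi-scale water-quality correlation.

The analysis question: does the mean accumulated resistance (MCR) of a
river's zone predict that river's pollutant concentrations?  Lower mean MCR
means pollutants from source patches reach the river more easily, so a
*negative* Pearson correlation between zonal mean MCR and concentration
across rivers is the expected signature of nonpoint-source pollution
pressure.  Correlations are computed per scale (sub-basin, five buffer
widths, lakeshore), per source landscape (PFSL, CLSL) and per index, with
bilateral significance at the 0.05 / 0.01 levels and no multiple-testing
correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cost_distance import MCRSurface
from .grid_io import WQ_INDEXES, WaterQualityTable
from .spatial_scales import ZoneSet

__all__ = [
    "ZonalStat",
    "CorrelationResult",
    "monthly_mean",
    "zonal_mean",
    "pearson",
    "pearson_pvalue",
    "correlation_matrix",
    "correlation_frame",
]

log = logging.getLogger(__name__)


@dataclass
class ZonalStat:
    scale_name: str
    zone_id: int
    river: str
    source_type: str
    mean_mcr: float
    n_cells: int


@dataclass
class CorrelationResult:
    scale_name: str
    source_type: str
    index: str
    r: float
    p: float
    n: int
    significance: str  # "" | "0.05" | "0.01"
    insufficient: bool = False


def monthly_mean(samples: dict[str, dict[str, list[float]]]) -> WaterQualityTable:
    """Arithmetic mean over available monthly samples per river and index.

    Rivers with interrupted flow may carry fewer than 12 months; an empty
    sample list is an error.
    """
    rows: dict[str, dict[str, float]] = {}
    for river, per_index in samples.items():
        rows[river] = {}
        for index in WQ_INDEXES:
            vals = per_index.get(index, [])
            if len(vals) == 0:
                raise ValueError(f"no monthly samples for {river}/{index}")
            rows[river][index] = float(np.mean(vals))
    return WaterQualityTable(rows=rows)


def zonal_mean(mcr: MCRSurface, zones: ZoneSet) -> list[ZonalStat]:
    """Mean finite MCR per zone; zones without finite cells are dropped."""
    vals = mcr.finite()
    for zone in zones.zones.values():
        if zone.mask.shape != vals.shape:
            raise ValueError("zone masks do not match the MCR grid")
    out: list[ZonalStat] = []
    for zid, zone in sorted(zones.zones.items()):
        member = vals[zone.mask]
        member = member[np.isfinite(member)]
        if member.size == 0:
            log.warning("zone %s/%s has no finite MCR cells; dropped",
                        zones.scale_name, zone.name)
            continue
        out.append(ZonalStat(
            scale_name=zones.scale_name, zone_id=zid, river=zone.name,
            source_type=mcr.source_type, mean_mcr=float(member.mean()),
            n_cells=int(member.size)))
    return out


def pearson(x, y) -> float:
    """Pearson correlation coefficient, clamped to [−1, 1].

    Exactly (anti)linear inputs return exactly ±1: a |r| within double-
    precision rounding of 1 is indistinguishable from perfect correlation
    and is snapped to the bound.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance")
    r = float(np.clip(sps.pearsonr(x, y).statistic, -1.0, 1.0))
    if 1.0 - abs(r) < 1e-12:
        return float(np.sign(r))
    return r


def pearson_pvalue(r: float, n: int) -> float:
    """Two-sided p-value of r via the t-transform on n−2 df."""
    if n < 3:
        raise ValueError("need n ≥ 3")
    if not -1 <= r <= 1:
        raise ValueError("|r| must be ≤ 1")
    if abs(r) == 1:
        return 0.0
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return float(2 * sps.t.sf(abs(t), df=n - 2))


def _stars(p: float) -> str:
    if p < 0.01:
        return "0.01"
    if p < 0.05:
        return "0.05"
    return ""


def correlation_matrix(
    zonal_stats: list[ZonalStat],
    wq: WaterQualityTable,
) -> list[CorrelationResult]:
    """One correlation per (scale, source type, index).

    River names in the zonal statistics are matched against the
    water-quality rows; unmatched rivers are excluded pairwise with a
    logged count.  Cells with fewer than 3 matched rivers, or zero
    variance in the zonal means, are emitted flagged rather than dropped.
    """
    if not zonal_stats:
        raise ValueError("no zonal statistics")
    groups: dict[tuple[str, str], list[ZonalStat]] = {}
    for zs in zonal_stats:
        groups.setdefault((zs.scale_name, zs.source_type), []).append(zs)

    results: list[CorrelationResult] = []
    matched_any = False
    for (scale, stype), rows in groups.items():
        matched = [zs for zs in rows if zs.river in wq.rows]
        dropped = len(rows) - len(matched)
        if dropped:
            log.info("%s/%s: %d zones without water-quality rows excluded",
                     scale, stype, dropped)
        means = np.array([zs.mean_mcr for zs in matched])
        if len(matched) >= 3:
            matched_any = True
        for index in WQ_INDEXES:
            conc = np.array([wq.rows[zs.river][index] for zs in matched])
            if len(matched) < 3 or np.ptp(means) == 0 or np.ptp(conc) == 0:
                results.append(CorrelationResult(
                    scale_name=scale, source_type=stype, index=index,
                    r=float("nan"), p=float("nan"), n=len(matched),
                    significance="", insufficient=True))
                continue
            r = pearson(means, conc)
            p = pearson_pvalue(r, len(matched))
            results.append(CorrelationResult(
                scale_name=scale, source_type=stype, index=index,
                r=r, p=p, n=len(matched), significance=_stars(p)))
    if not matched_any:
        raise ValueError("no (scale, source) group had ≥ 3 matched rivers")
    return results


def correlation_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    """Correlation results as a tidy DataFrame (CSV-ready)."""
    return pd.DataFrame([{
        "scale": c.scale_name, "source_type": c.source_type, "index": c.index,
        "r": c.r, "p": c.p, "n": c.n, "significance": c.significance,
        "insufficient": c.insufficient,
    } for c in results])
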