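"""Minimum cumulative resistance (MCR) accumulation.

For every grid cell the MCR is the least, over all 8-connected paths from
any source cell, of the accumulated link costs

    cost(a → b) = d · (R_a + R_b) / 2

with d = cell_size for rook moves and cell_size·√2 for diagonal moves —
the standard cost-distance formulation (distance × mean resistance of the
two cells a link joins).  Source cells have MCR = 0; cells unreachable from
every source (e.g. separated by nodata, which is impassable) are nodata.

The accumulation is a Dijkstra scan with a binary heap.  Because all link
costs are positive and the settled value of a cell is unique, the result is
independent of heap tie order.  ``verify_relaxed`` is an independent
optimality certificate: a finite labelling is the true shortest-path
distance iff it is zero on sources and no 8-neighbour link can relax it.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from math import sqrt

import numpy as np

from .grid_io import Raster
from .resistance_surface import ResistanceSurface, SourceMask

__all__ = ["MCRSurface", "accumulate_mcr", "verify_relaxed"]

# 8-neighbour offsets and their distance multipliers
_NEIGHBORS_8 = [
    (0, 1, 1.0), (1, 1, sqrt(2.0)), (1, 0, 1.0), (1, -1, sqrt(2.0)),
    (0, -1, 1.0), (-1, -1, sqrt(2.0)), (-1, 0, 1.0), (-1, 1, sqrt(2.0)),
]
_NEIGHBORS_4 = [(0, 1, 1.0), (1, 0, 1.0), (0, -1, 1.0), (-1, 0, 1.0)]


@dataclass
class MCRSurface:
    """Accumulated minimum cost from a source landscape."""

    raster: Raster  # semantic "mcr"; unreachable cells nodata
    source_type: str

    def finite(self) -> np.ndarray:
        """MCR values with unreachable/nodata as +inf."""
        return self.raster.data(fill=np.inf)


def _neighbors(connectivity: int):
    if connectivity == 8:
        return _NEIGHBORS_8
    if connectivity == 4:
        return _NEIGHBORS_4
    raise ValueError("connectivity must be 4 or 8")


def accumulate_mcr(
    resistance: ResistanceSurface,
    sources: SourceMask,
    connectivity: int = 8,
) -> MCRSurface:
    """Dijkstra accumulation of minimum cumulative resistance.

    Raises if resistance is negative anywhere or if every source cell sits
    on nodata.
    """
    r = resistance.raster
    if not r.same_geometry(sources.raster):
        raise ValueError("resistance and source mask grids differ")
    res = r.data(fill=np.nan)
    finite_res = res[np.isfinite(res)]
    if finite_res.size and finite_res.min() < 0:
        raise ValueError("negative resistance")
    passable = np.isfinite(res)
    src = sources.mask & passable
    if not src.any():
        raise ValueError("all source cells lie on nodata")

    nr, nc = r.shape
    s = r.cell_size
    dist = np.full((nr, nc), np.inf)
    dist[src] = 0.0
    heap = [(0.0, int(i), int(j)) for i, j in zip(*np.nonzero(src))]
    heapq.heapify(heap)
    offsets = _neighbors(connectivity)
    while heap:
        d0, i, j = heapq.heappop(heap)
        if d0 > dist[i, j]:
            continue  # stale entry
        ri = res[i, j]
        for di, dj, mult in offsets:
            ni, nj = i + di, j + dj
            if 0 <= ni < nr and 0 <= nj < nc and passable[ni, nj]:
                nd = d0 + s * mult * (ri + res[ni, nj]) * 0.5
                if nd < dist[ni, nj]:
                    dist[ni, nj] = nd
                    heapq.heappush(heap, (nd, ni, nj))

    out = dist.copy()
    out[~np.isfinite(dist)] = r.nodata
    out[~passable] = r.nodata
    return MCRSurface(
        raster=r.like(out, semantic="mcr"), source_type=sources.source_type)


def verify_relaxed(
    mcr: MCRSurface,
    resistance: ResistanceSurface,
    sources: SourceMask | None = None,
    connectivity: int = 8,
    tol: float = 1e-9,
) -> bool:
    """Certificate that an MCR labelling is shortest-path optimal.

    True iff every 8-neighbour link satisfies the triangle relaxation
    ``MCR(b) ≤ MCR(a) + d·(R_a+R_b)/2 + tol`` and (when ``sources`` is
    given) MCR is exactly 0 on every passable source cell.
    """
    r = resistance.raster
    if not r.same_geometry(mcr.raster):
        raise ValueError("MCR and resistance grids differ")
    res = r.data(fill=np.nan)
    d = mcr.finite()
    if not np.isfinite(d).any():
        raise ValueError("no finite MCR cells to verify")
    if sources is not None:
        src = sources.mask & np.isfinite(res)
        if not np.all(d[src] == 0):
            return False
    s = r.cell_size
    for di, dj, mult in _neighbors(connectivity):
        # slide the grid against itself along this offset
        a_i = slice(max(0, -di), min(d.shape[0], d.shape[0] - di))
        a_j = slice(max(0, -dj), min(d.shape[1], d.shape[1] - dj))
        b_i = slice(max(0, di), min(d.shape[0], d.shape[0] + di))
        b_j = slice(max(0, dj), min(d.shape[1], d.shape[1] + dj))
        da, db = d[a_i, a_j], d[b_i, b_j]
        ra, rb = res[a_i, a_j], res[b_i, b_j]
        link = s * mult * (ra + rb) * 0.5
        ok = np.isfinite(da) & np.isfinite(rb) & np.isfinite(ra)
        if np.any(db[ok] > da[ok] + link[ok] + tol):
            return False
    return True
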