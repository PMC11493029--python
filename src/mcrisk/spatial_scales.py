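"""Analysis scales: D8 sub-basins, riparian buffers, lakeshore zone.

Seven scales drive the multi-scale correlation: one sub-basin partition
(from D8 single-flow-direction routing and per-river pour points), five
riparian buffers (100/300/500/700/1000 m around each inflow river) and a
110 m lakeshore band.  All zones are raster cell sets so zonal statistics
are exact set operations on the grid; lake cells carry no landscape
resistance and are excluded from every zone.

Depression filling uses the priority-flood algorithm, which produces the
minimal surface on which every cell drains to an outlet by non-ascending
8-neighbour steps.  Flow direction is steepest descent with a fixed
tie-break order (E, SE, S, SW, W, NW, N, NE); flats are resolved by
breadth-first growth from cells that already drain, so every flat cell
points toward the nearest lower terrain.
"""

from __future__ import annotations

import heapq
from collections import deque
from dataclasses import dataclass, field
from math import sqrt

import numpy as np
import shapely

from .grid_io import Raster, VectorLayer

__all__ = [
    "Zone",
    "ZoneSet",
    "fill_sinks",
    "d8_flow_direction",
    "flow_accumulation",
    "delineate_subbasins",
    "buffer_zones",
    "lakeshore_zone",
]

#: neighbour order used for every tie-break: E, SE, S, SW, W, NW, N, NE
D8_OFFSETS = [
    (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1),
]
_D8_DIST = [1.0, sqrt(2.0), 1.0, sqrt(2.0), 1.0, sqrt(2.0), 1.0, sqrt(2.0)]
OUTLET = -1  # direction code of cells that drain off-grid / into an outlet


@dataclass
class Zone:
    name: str
    mask: np.ndarray  # boolean cell membership

    @property
    def n_cells(self) -> int:
        return int(self.mask.sum())


@dataclass
class ZoneSet:
    """Labelled analysis zones at one scale."""

    scale_name: str
    zones: dict[int, Zone]
    provenance: dict = field(default_factory=dict)

    def zone_raster(self, template: Raster) -> Raster:
        """Zone-id layer (overlapping zones: the higher id wins)."""
        out = np.zeros(template.shape, dtype=np.int64)
        for zid, zone in sorted(self.zones.items()):
            out[zone.mask] = zid
        out[out == 0] = int(template.nodata)
        return template.like(out, semantic="zoneid")


# ---------------------------------------------------------------------------
# depression filling

def fill_sinks(dem: Raster, outlets: np.ndarray | None = None) -> Raster:
    """Priority-flood depression filling.

    Water can leave through ``outlets`` (default: the grid border).  The
    result is the minimal surface ≥ the input on which every cell reaches
    an outlet by a non-ascending 8-neighbour path.
    """
    z = dem.data(fill=np.nan)
    nr, nc = z.shape
    filled = np.full_like(z, np.inf)
    visited = np.zeros_like(z, dtype=bool)
    heap: list[tuple[float, int, int]] = []

    if outlets is None:
        outlets = np.zeros_like(visited)
        outlets[0, :] = outlets[-1, :] = True
        outlets[:, 0] = outlets[:, -1] = True
    else:
        outlets = np.asarray(outlets, dtype=bool).copy()
        outlets[0, :] = outlets[-1, :] = True
        outlets[:, 0] = outlets[:, -1] = True

    for i, j in zip(*np.nonzero(outlets & np.isfinite(z))):
        heapq.heappush(heap, (z[i, j], int(i), int(j)))
        visited[i, j] = True
    while heap:
        level, i, j = heapq.heappop(heap)
        filled[i, j] = level
        for di, dj in D8_OFFSETS:
            ni, nj = i + di, j + dj
            if 0 <= ni < nr and 0 <= nj < nc and not visited[ni, nj] \
                    and np.isfinite(z[ni, nj]):
                visited[ni, nj] = True
                heapq.heappush(heap, (max(z[ni, nj], level), ni, nj))
    out = filled.copy()
    out[~np.isfinite(out)] = dem.nodata
    return dem.like(out, semantic="dem")


# ---------------------------------------------------------------------------
# flow routing

def d8_flow_direction(filled: Raster, outlets: np.ndarray | None = None) -> Raster:
    """Steepest-descent direction code per cell (index into D8_OFFSETS).

    Outlet cells and border cells with no downhill neighbour get code −1
    (they drain off-grid).  Flat cells are resolved by breadth-first growth
    from already-draining cells across equal elevation.
    """
    z = filled.data(fill=np.nan)
    nr, nc = z.shape
    direction = np.full((nr, nc), -2, dtype=np.int64)  # -2 = unresolved
    valid = np.isfinite(z)
    direction[~valid] = OUTLET

    outlet_mask = np.zeros((nr, nc), dtype=bool)
    if outlets is not None:
        outlet_mask |= np.asarray(outlets, dtype=bool)

    queue: deque[tuple[int, int]] = deque()
    for i in range(nr):
        for j in range(nc):
            if not valid[i, j]:
                continue
            if outlet_mask[i, j]:
                direction[i, j] = OUTLET
                queue.append((i, j))
                continue
            best_k, best_drop = -1, 0.0
            off_grid = False
            for k, (di, dj) in enumerate(D8_OFFSETS):
                ni, nj = i + di, j + dj
                if not (0 <= ni < nr and 0 <= nj < nc):
                    off_grid = True
                    continue
                if not valid[ni, nj]:
                    continue
                drop = (z[i, j] - z[ni, nj]) / _D8_DIST[k]
                if drop > best_drop:
                    best_drop, best_k = drop, k
            if best_k >= 0:
                direction[i, j] = best_k
                queue.append((i, j))
            elif off_grid:
                direction[i, j] = OUTLET  # border cell draining off-grid
                queue.append((i, j))
    # resolve flats toward the nearest already-draining equal-elevation cell
    while queue:
        i, j = queue.popleft()
        for k, (di, dj) in enumerate(D8_OFFSETS):
            ni, nj = i + di, j + dj
            if 0 <= ni < nr and 0 <= nj < nc and direction[ni, nj] == -2 \
                    and z[ni, nj] == z[i, j]:
                # neighbour (ni,nj) drains through (i,j): opposite offset
                direction[ni, nj] = (k + 4) % 8
                queue.append((ni, nj))
    if np.any(direction == -2):
        raise ValueError("unresolved flat cells: DEM was not filled")
    return filled.like(direction, semantic="zoneid")


def _downstream(direction: np.ndarray):
    """(row, col) of the downstream cell per cell; -1 where none."""
    nr, nc = direction.shape
    down_r = np.full((nr, nc), -1, dtype=np.int64)
    down_c = np.full((nr, nc), -1, dtype=np.int64)
    for k, (di, dj) in enumerate(D8_OFFSETS):
        sel = direction == k
        ii, jj = np.nonzero(sel)
        ni, nj = ii + di, jj + dj
        inside = (ni >= 0) & (ni < nr) & (nj >= 0) & (nj < nc)
        down_r[ii[inside], jj[inside]] = ni[inside]
        down_c[ii[inside], jj[inside]] = nj[inside]
    return down_r, down_c


def flow_accumulation(directions: Raster) -> Raster:
    """Count of upstream cells per cell (self excluded), topological order."""
    direction = np.asarray(directions.values, dtype=np.int64)
    nr, nc = direction.shape
    down_r, down_c = _downstream(direction)
    indeg = np.zeros((nr, nc), dtype=np.int64)
    has_down = down_r >= 0
    np.add.at(indeg, (down_r[has_down], down_c[has_down]), 1)
    acc = np.zeros((nr, nc), dtype=np.int64)
    queue = deque(zip(*np.nonzero(indeg == 0)))
    processed = 0
    n_routed = int(np.sum(direction >= -1))
    while queue:
        i, j = queue.popleft()
        processed += 1
        if has_down[i, j]:
            ni, nj = down_r[i, j], down_c[i, j]
            acc[ni, nj] += acc[i, j] + 1
            indeg[ni, nj] -= 1
            if indeg[ni, nj] == 0:
                queue.append((ni, nj))
    if processed < n_routed:
        raise ValueError("cycle in the flow-direction field")
    return directions.like(acc, semantic="zoneid")


def delineate_subbasins(
    directions: Raster,
    pour_points: VectorLayer,
    snap_radius: int = 3,
) -> ZoneSet:
    """Catchment of each pour point: all cells draining to it first.

    Each pour point is snapped to the maximum-accumulation cell within
    ``snap_radius`` cells; a cell belongs to the first pour point its flow
    path reaches downstream, so zones are pairwise disjoint.
    """
    direction = np.asarray(directions.values, dtype=np.int64)
    nr, nc = direction.shape
    acc = np.asarray(flow_accumulation(directions).values)
    down_r, down_c = _downstream(direction)

    pour_cells: dict[tuple[int, int], int] = {}
    names: dict[int, str] = {}
    x0, y0 = directions.origin
    s = directions.cell_size
    for zid, (geom, attrs) in enumerate(pour_points.features, start=1):
        px, py = geom.x, geom.y
        c = int((px - x0) / s)
        r = int((y0 - py) / s)
        if not (0 <= r < nr and 0 <= c < nc):
            raise ValueError(f"pour point {zid} outside the grid")
        r0, r1 = max(0, r - snap_radius), min(nr, r + snap_radius + 1)
        c0, c1 = max(0, c - snap_radius), min(nc, c + snap_radius + 1)
        # snap to the highest-accumulation routed cell in the window;
        # outlet cells (direction −1, e.g. lake or off-grid) are skipped so
        # nearby river mouths cannot collapse onto one sink cell
        window = [
            (acc[i, j], i, j)
            for i in range(r0, r1) for j in range(c0, c1)
            if direction[i, j] >= 0 and (i, j) not in pour_cells
        ]
        if not window and direction[r, c] == OUTLET and (r, c) not in pour_cells:
            window = [(acc[r, c], r, c)]  # pour point sits on a basin outlet
        if not window:
            raise ValueError(f"pour point {zid} snapped onto nodata or a "
                             f"claimed cell")
        _, ci, cj = max(window)
        cell = (ci, cj)
        pour_cells[cell] = zid
        names[zid] = str(attrs.get("name", f"zone_{zid}"))

    # downstream-first order: strictly increasing accumulation along flow
    zone = np.zeros((nr, nc), dtype=np.int64)
    order = np.argsort(acc, axis=None)[::-1]
    for flat in order:
        i, j = divmod(int(flat), nc)
        if (i, j) in pour_cells:
            zone[i, j] = pour_cells[(i, j)]
        elif down_r[i, j] >= 0:
            zone[i, j] = zone[down_r[i, j], down_c[i, j]]
    zones = {
        zid: Zone(name=names[zid], mask=zone == zid) for zid in names
    }
    return ZoneSet(
        scale_name="subbasin",
        zones=zones,
        provenance={"snap_radius": snap_radius},
    )


# ---------------------------------------------------------------------------
# buffers

def _center_points(template: Raster):
    xs, ys = template.cell_centers()
    return shapely.points(xs.ravel(), ys.ravel())


def buffer_zones(
    rivers: VectorLayer,
    template: Raster,
    distances: tuple[float, ...] = (100.0, 300.0, 500.0, 700.0, 1000.0),
    exclude: np.ndarray | None = None,
) -> dict[float, ZoneSet]:
    """Riparian buffer ZoneSets, one per distance.

    A cell belongs to a river's buffer when its centre lies within the
    Euclidean distance of the river polyline.  Buffers of different rivers
    are separate zones and may overlap.  ``exclude`` (e.g. the lake mask)
    removes cells from every zone.
    """
    if len(rivers) == 0:
        raise ValueError("empty river layer")
    pts = _center_points(template)
    excl = np.zeros(template.shape, dtype=bool) if exclude is None \
        else np.asarray(exclude, dtype=bool)
    out: dict[float, ZoneSet] = {}
    dists_per_river = [
        shapely.distance(geom, pts).reshape(template.shape)
        for geom, _ in rivers
    ]
    for w in distances:
        zones = {}
        for zid, ((geom, attrs), d) in enumerate(
                zip(rivers, dists_per_river), start=1):
            mask = (d <= w) & ~excl
            zones[zid] = Zone(name=str(attrs.get("name", f"river_{zid}")),
                              mask=mask)
        out[w] = ZoneSet(
            scale_name=f"buffer_{int(w)}", zones=zones,
            provenance={"distance_m": float(w)},
        )
    return out


def lakeshore_zone(
    lake: VectorLayer,
    template: Raster,
    width: float = 110.0,
    lake_mask: np.ndarray | None = None,
) -> ZoneSet:
    """The land band within ``width`` metres of the lake boundary."""
    if lake.geometry_kind != "polygon" or len(lake) == 0:
        raise ValueError("lakeshore_zone needs a non-empty polygon layer")
    poly = shapely.unary_union(lake.geometries())
    xs, ys = template.cell_centers()
    pts = _center_points(template)
    d = shapely.distance(poly.boundary, pts).reshape(template.shape)
    inside = shapely.contains_xy(poly, xs.ravel(), ys.ravel()).reshape(template.shape)
    mask = (d <= width) & ~inside
    if lake_mask is not None:
        mask &= ~np.asarray(lake_mask, dtype=bool)
    return ZoneSet(
        scale_name="lakeshore",
        zones={1: Zone(name="lakeshore", mask=mask)},
        provenance={"width_m": float(width)},
    )
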