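"""Raster / vector / table I/O for the risk pipeline.

Rasters are single-band grids in a projected, metre-based frame, stored on
disk as ESRI ASCII grid (``.asc``) — a plain-text format every desktop GIS
reads.  Vectors are GeoJSON.  The water-quality table is a CSV of rivers ×
seven indexes (monthly means, mg/L).

Grid convention: row 0 is the north edge, x increases east, y increases
north; the centre of cell (r, c) is at
``(x0 + (c + 0.5)·s, y0 − (r + 0.5)·s)`` where ``(x0, y0)`` is the top-left
corner and ``s`` the cell size.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import shapely
from shapely.geometry import mapping as geom_mapping
from shapely.geometry import shape as geom_shape
from shapely.geometry.base import BaseGeometry

__all__ = [
    "Raster",
    "VectorLayer",
    "WaterQualityTable",
    "WQ_INDEXES",
    "read_raster",
    "write_raster",
    "read_vector",
    "write_vector",
    "read_wq_table",
    "rasterize",
]

#: the seven water-quality indexes, in canonical column order
WQ_INDEXES = ("NH3-N", "TP", "TN", "COD_Mn", "BOD5", "COD_Cr", "Fluoride")

_SEMANTICS = {
    "dem", "landuse", "fvc", "factor", "resistance", "mcr", "riskclass", "zoneid",
}
_INTEGER_SEMANTICS = {"landuse", "riskclass", "zoneid"}


@dataclass
class Raster:
    """A single-band georeferenced grid.

    Parameters
    ----------
    values : ndarray
        2-D grid; nodata cells hold ``nodata``.
    cell_size : float
        Metres per cell edge (> 0).
    origin : tuple of float
        (x, y) of the top-left corner in projected metres.
    nodata : float
        Sentinel for missing cells.
    semantic : str
        Layer role: dem | landuse | fvc | factor | resistance | mcr |
        riskclass | zoneid.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = -9999.0
    semantic: str = "factor"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("raster values must be a non-empty 2-D grid")
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")
        if self.semantic not in _SEMANTICS:
            raise ValueError(f"unknown semantic {self.semantic!r}")
        if self.semantic in _INTEGER_SEMANTICS:
            v = self.values[self.mask]
            if v.size and not np.allclose(v, np.round(v)):
                raise ValueError(f"{self.semantic} layer must hold integer codes")
        finite = self.values[self.mask]
        if finite.size and not np.all(np.isfinite(finite)):
            raise ValueError("non-nodata values must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell carries data."""
        with np.errstate(invalid="ignore"):
            return (self.values != self.nodata) & ~np.isnan(self.values)

    def data(self, fill: float = np.nan) -> np.ndarray:
        """Float copy with nodata replaced by ``fill``."""
        out = self.values.astype(float, copy=True)
        out[~self.mask] = fill
        return out

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of every cell centre, each of grid shape."""
        nr, nc = self.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(nc) + 0.5) * self.cell_size
        ys = y0 - (np.arange(nr) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def like(self, values: np.ndarray, semantic: str | None = None,
             nodata: float | None = None) -> "Raster":
        """New raster on this grid geometry."""
        return Raster(
            values=values,
            cell_size=self.cell_size,
            origin=self.origin,
            nodata=self.nodata if nodata is None else nodata,
            semantic=self.semantic if semantic is None else semantic,
        )

    def same_geometry(self, other: "Raster", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and math.isclose(self.cell_size, other.cell_size, rel_tol=0, abs_tol=tol)
            and math.isclose(self.origin[0], other.origin[0], rel_tol=0, abs_tol=tol)
            and math.isclose(self.origin[1], other.origin[1], rel_tol=0, abs_tol=tol)
        )


@dataclass
class VectorLayer:
    """Features of one geometry kind with per-feature attributes."""

    features: list[tuple[BaseGeometry, dict]]
    geometry_kind: str  # polygon | polyline | point

    _KINDS = {"Polygon": "polygon", "LineString": "polyline", "Point": "point"}

    def __post_init__(self) -> None:
        if self.geometry_kind not in {"polygon", "polyline", "point"}:
            raise ValueError(f"unknown geometry kind {self.geometry_kind!r}")
        fixed = []
        for geom, attrs in self.features:
            kind = self._KINDS.get(geom.geom_type)
            if kind != self.geometry_kind:
                raise ValueError(
                    f"feature of type {geom.geom_type} in a {self.geometry_kind} layer"
                )
            if not geom.is_valid:
                geom = shapely.make_valid(geom)
            fixed.append((geom, dict(attrs)))
        self.features = fixed

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self) -> Iterator[tuple[BaseGeometry, dict]]:
        return iter(self.features)

    def geometries(self) -> list[BaseGeometry]:
        return [g for g, _ in self.features]


@dataclass
class WaterQualityTable:
    """Rivers × seven indexes of monthly-mean concentrations (mg/L)."""

    rows: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for river, vals in self.rows.items():
            missing = set(WQ_INDEXES) - set(vals)
            if missing:
                raise ValueError(f"river {river!r} missing indexes {sorted(missing)}")
            for idx in WQ_INDEXES:
                if not (float(vals[idx]) >= 0):
                    raise ValueError(
                        f"negative concentration {vals[idx]} for {river}/{idx}"
                    )

    @property
    def rivers(self) -> list[str]:
        return list(self.rows)

    def column(self, index: str) -> np.ndarray:
        """Concentrations of one index, in river order."""
        if index not in WQ_INDEXES:
            raise KeyError(index)
        return np.array([self.rows[r][index] for r in self.rows], dtype=float)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame.from_dict(self.rows, orient="index")[list(WQ_INDEXES)]


# ---------------------------------------------------------------------------
# raster I/O (ESRI ASCII grid)

def write_raster(r: Raster, path: str | Path) -> None:
    """Write a raster as an ESRI ASCII grid.

    Integer-semantic layers are written as integers and round-trip
    bit-exactly; float layers are written with ``repr`` precision.
    """
    path = Path(path)
    if not path.parent.is_dir():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    nr, nc = r.shape
    x0, y0 = r.origin
    integer = r.semantic in _INTEGER_SEMANTICS
    header = (
        f"ncols {nc}\n"
        f"nrows {nr}\n"
        f"xllcorner {x0!r}\n"
        f"yllcorner {(y0 - nr * r.cell_size)!r}\n"
        f"cellsize {r.cell_size!r}\n"
        f"NODATA_value {int(r.nodata) if integer else repr(float(r.nodata))}\n"
    )
    with open(path, "w") as fh:
        fh.write(f"# semantic: {r.semantic}\n")
        fh.write(header)
        for row in r.values:
            if integer:
                fh.write(" ".join(str(int(v)) for v in row) + "\n")
            else:
                fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_raster(path: str | Path) -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_raster`.

    Raises if the header looks like geographic (degree) coordinates: a metre
    frame is required for distances and buffers.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    semantic = "factor"
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "semantic:" in line:
                    semantic = line.split("semantic:")[1].strip()
                continue
            parts = line.split()
            if parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"malformed ASCII grid, missing {key}: {path}")
    cell = header["cellsize"]
    # heuristic degree detection: sub-centimetre "cells" at lat/lon-range
    # coordinates mean the grid is in geographic degrees
    if cell < 0.01 and abs(header["xllcorner"]) <= 360 and abs(header["yllcorner"]) <= 90:
        raise ValueError(
            "raster appears to be in geographic (degree) coordinates; "
            "reproject to a metre-based projected frame first"
        )
    values = np.array(rows, dtype=float)
    nr, nc = int(header["nrows"]), int(header["ncols"])
    if values.shape != (nr, nc):
        raise ValueError(f"grid body {values.shape} does not match header ({nr}, {nc})")
    nodata = header.get("nodata_value", -9999.0)
    if semantic in _INTEGER_SEMANTICS:
        values = values.astype(np.int64)
    origin = (header["xllcorner"], header["yllcorner"] + nr * cell)
    return Raster(values=values, cell_size=cell, origin=origin,
                  nodata=nodata, semantic=semantic)


# ---------------------------------------------------------------------------
# vector I/O (GeoJSON)

def write_vector(v: VectorLayer, path: str | Path) -> None:
    features = [
        {"type": "Feature", "geometry": geom_mapping(geom), "properties": attrs}
        for geom, attrs in v.features
    ]
    payload = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_vector(path: str | Path) -> VectorLayer:
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    payload = json.loads(path.read_text())
    feats = payload.get("features", [])
    if not feats:
        raise ValueError(f"empty GeoJSON layer: {path}")
    geoms_attrs = [(geom_shape(f["geometry"]), f.get("properties") or {}) for f in feats]
    kinds = {VectorLayer._KINDS.get(g.geom_type, g.geom_type) for g, _ in geoms_attrs}
    if len(kinds) != 1:
        raise ValueError(f"mixed geometry kinds {sorted(kinds)} in {path}")
    return VectorLayer(features=geoms_attrs, geometry_kind=kinds.pop())


# ---------------------------------------------------------------------------
# water-quality table

def read_wq_table(path: str | Path) -> WaterQualityTable:
    """Read a rivers × indexes CSV (header ``River,NH3-N,...,Fluoride``)."""
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    rows: dict[str, dict[str, float]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        cols = reader.fieldnames or []
        missing = [c for c in ("River", *WQ_INDEXES) if c not in cols]
        if missing:
            raise ValueError(f"water-quality CSV missing columns {missing}")
        for rec in reader:
            river = rec["River"].strip()
            if river in rows:
                raise ValueError(f"duplicate river name {river!r}")
            try:
                rows[river] = {idx: float(rec[idx]) for idx in WQ_INDEXES}
            except (TypeError, ValueError) as exc:
                raise ValueError(f"non-numeric cell in row {river!r}") from exc
    return WaterQualityTable(rows=rows)


def packaged_wq_table() -> WaterQualityTable:
    """The packaged 19-river monthly-mean water-quality fixture."""
    return read_wq_table(Path(__file__).parent / "data" / "water_quality_three_lakes.csv")


# ---------------------------------------------------------------------------
# rasterization

def rasterize(v: VectorLayer, template: Raster, burn: str | float = 1.0) -> Raster:
    """Burn a vector layer onto the template grid.

    A cell is burned when its centre lies inside a polygon, or within half a
    cell size of a polyline, or within half a cell of a point.  ``burn`` is a
    constant or an attribute name looked up per feature.  Unburned cells are 0.
    """
    if len(v) == 0:
        raise ValueError("cannot rasterize an empty layer")
    xs, ys = template.cell_centers()
    out = np.zeros(template.shape, dtype=float)
    pts = shapely.points(xs.ravel(), ys.ravel())
    for geom, attrs in v:
        value = float(attrs[burn]) if isinstance(burn, str) else float(burn)
        if v.geometry_kind == "polygon":
            hit = shapely.contains_xy(geom, xs.ravel(), ys.ravel())
        else:
            hit = shapely.dwithin(geom, pts, template.cell_size / 2.0)
        out.ravel()[hit] = value
    return template.like(out, semantic="factor", nodata=-9999.0)
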