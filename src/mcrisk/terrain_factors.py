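"""Physical factor layers for the resistance base surface.

Four of the five evaluation factors are derived here from the DEM and the
lake: relative elevation (height of a cell above the lake level), relative
slope (the angle subtended by that height over the straight-line distance to
the lake), local slope (Horn's 3×3 estimator, degrees) and surface roughness
M = 1/cos(slope).  Vegetation coverage and land use arrive as data layers.

Orientation semantics: relative elevation and relative slope *raise* the
pollution risk as they grow (gravity and runoff energy), so they are tagged
``risk_increasing``; roughness and vegetation coverage *resist* pollutant
transfer, so ``resistance_increasing``; land use is categorical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt

from .grid_io import Raster

__all__ = [
    "FactorLayer",
    "ORIENTATIONS",
    "slope_degrees",
    "surface_roughness",
    "relative_elevation",
    "relative_slope",
]

#: fixed orientation per factor name
ORIENTATIONS = {
    "relative_elevation": "risk_increasing",
    "relative_slope": "risk_increasing",
    "surface_roughness": "resistance_increasing",
    "vegetation_coverage": "resistance_increasing",
    "land_use": "categorical",
}


@dataclass
class FactorLayer:
    """One evaluation factor with its fixed orientation."""

    raster: Raster
    name: str

    def __post_init__(self) -> None:
        if self.name not in ORIENTATIONS:
            raise ValueError(f"unknown factor name {self.name!r}")

    @property
    def orientation(self) -> str:
        return ORIENTATIONS[self.name]


def _propagate_nodata(src: Raster, values: np.ndarray, semantic: str = "factor") -> Raster:
    values = values.astype(float, copy=True)
    values[~src.mask] = src.nodata
    return src.like(values, semantic=semantic)


def slope_degrees(dem: Raster) -> Raster:
    """Per-cell slope in degrees from Horn's 3×3 finite differences.

    Edge cells use edge-replicated neighbours.  With the 3×3 neighbourhood

    ::

        a b c
        d e f
        g h i

    the gradients are dz/dx = ((c+2f+i) − (a+2d+g)) / (8s) and
    dz/dy = ((g+2h+i) − (a+2b+c)) / (8s), and slope = atan(‖∇z‖).
    """
    if min(dem.shape) < 3:
        raise ValueError("slope needs at least a 3×3 grid")
    z = np.pad(dem.data(fill=np.nan), 1, mode="edge")
    # neighbour views, letters as in the docstring stencil
    a, b, c = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    d, f = z[1:-1, :-2], z[1:-1, 2:]
    g, h, i = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    s = dem.cell_size
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * s)
    dzdy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8 * s)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    slope = np.nan_to_num(slope, nan=0.0)
    return _propagate_nodata(dem, slope)


def surface_roughness(slope: Raster) -> Raster:
    """Roughness M = 1/cos(∂·π/180) from slope ∂ in degrees; M ≥ 1."""
    vals = slope.data()
    finite = vals[np.isfinite(vals)]
    if finite.size and (finite.max() >= 90 or finite.min() < 0):
        raise ValueError("slope must lie in [0, 90) degrees")
    m = 1.0 / np.cos(np.radians(np.nan_to_num(vals, nan=0.0)))
    return _propagate_nodata(slope, m)


def relative_elevation(dem: Raster, lake_level: float) -> Raster:
    """Height of each cell above the lake surface, floored at 0 m."""
    if not np.isfinite(lake_level):
        raise ValueError("lake_level must be finite")
    rel = np.maximum(dem.data(fill=0.0) - lake_level, 0.0)
    return _propagate_nodata(dem, rel)


def relative_slope(dem: Raster, lake_mask: np.ndarray, lake_level: float) -> Raster:
    """Angle of descent toward the lake, degrees.

    For each cell: ``atan(max(0, z − lake_level) / d)`` where ``d`` is the
    Euclidean distance from the cell centre to the nearest lake cell centre
    (floored at one cell size so shoreline-adjacent cells stay finite).
    Lake cells are 0.
    """
    lake_mask = np.asarray(lake_mask, dtype=bool)
    if lake_mask.shape != dem.shape:
        raise ValueError("lake mask shape does not match DEM")
    if not lake_mask.any():
        raise ValueError("empty lake mask")
    d = distance_transform_edt(~lake_mask) * dem.cell_size
    d = np.maximum(d, dem.cell_size)
    rise = np.maximum(dem.data(fill=0.0) - lake_level, 0.0)
    ang = np.degrees(np.arctan2(rise, d))
    ang[lake_mask] = 0.0
    return _propagate_nodata(dem, ang)
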