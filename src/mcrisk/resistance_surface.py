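"""Build the vertical resistance base surface R from the five factors.

Continuous factors are min–max normalised, oriented so that larger always
means *more resistance to pollutant transfer*, then graded into the odd
scores 1/3/5/7/9.  Land use is scored directly from a code table (source
classes — paddy, construction — get the lowest resistance).  The weighted
overlay R = Σ wₖ·gradeₖ with the expert weights

    relative_elevation 0.20, relative_slope 0.17, surface_roughness 0.13,
    vegetation_coverage 0.24, land_use 0.26

yields per-cell resistance in [1, 9].  Low R near source patches means high
pollutant accessibility, hence high nonpoint-source pollution risk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid_io import Raster
from .terrain_factors import ORIENTATIONS, FactorLayer

__all__ = [
    "DEFAULT_WEIGHTS",
    "DEFAULT_LANDUSE_SCORES",
    "LANDUSE_CODES",
    "FactorStack",
    "ResistanceSurface",
    "SourceMask",
    "normalize_minmax",
    "orient",
    "grade",
    "score_landuse",
    "weighted_overlay",
    "extract_sources",
    "build_resistance",
]

DEFAULT_WEIGHTS = {
    "relative_elevation": 0.20,
    "relative_slope": 0.17,
    "surface_roughness": 0.13,
    "vegetation_coverage": 0.24,
    "land_use": 0.26,
}

#: land-use integer codes used throughout the pipeline
LANDUSE_CODES = {
    "paddy": 1,
    "dryland": 2,
    "forest": 3,
    "grass": 4,
    "construction": 5,
    "water": 6,
}

#: resistance scores per land-use code; pollutant-exporting classes score
#: low (little interception), wood/grass intercept strongly, water neutral
DEFAULT_LANDUSE_SCORES = {
    LANDUSE_CODES["paddy"]: 1,
    LANDUSE_CODES["construction"]: 1,
    LANDUSE_CODES["dryland"]: 3,
    LANDUSE_CODES["water"]: 5,
    LANDUSE_CODES["grass"]: 7,
    LANDUSE_CODES["forest"]: 9,
}

_GRADE_SCORES = np.array([1, 3, 5, 7, 9])
_GRADE_EDGES = np.array([0.2, 0.4, 0.6, 0.8])


@dataclass
class FactorStack:
    """The five graded factor layers plus their weights and score table."""

    layers: dict[str, Raster]  # name -> graded raster (scores 1..9)
    weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    landuse_scores: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_LANDUSE_SCORES))

    def __post_init__(self) -> None:
        if set(self.layers) != set(ORIENTATIONS):
            raise ValueError(
                f"need exactly the five factors {sorted(ORIENTATIONS)}, "
                f"got {sorted(self.layers)}")
        if set(self.weights) != set(ORIENTATIONS):
            raise ValueError("weights must cover exactly the five factors")
        if abs(sum(self.weights.values()) - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")


@dataclass
class ResistanceSurface:
    """Per-cell resistance R of the landscape to pollutant transfer.

    A weighted overlay of 1–9 grades lands in [1, 9]; the container itself
    only requires non-negative values so rescaled surfaces remain legal.
    """

    raster: Raster

    def __post_init__(self) -> None:
        vals = self.raster.values[self.raster.mask]
        if vals.size and vals.min() < 0:
            raise ValueError("resistance must be non-negative")


@dataclass
class SourceMask:
    """Binary mask of one source landscape class (PFSL or CLSL)."""

    raster: Raster
    source_type: str  # "PFSL" | "CLSL"

    def __post_init__(self) -> None:
        if self.source_type not in {"PFSL", "CLSL"}:
            raise ValueError(f"unknown source type {self.source_type!r}")
        if not np.any(self.raster.values == 1):
            raise ValueError("source mask has no source cells")

    @property
    def mask(self) -> np.ndarray:
        return np.asarray(self.raster.values == 1)


def normalize_minmax(layer: FactorLayer) -> Raster:
    """Min–max normalise a continuous factor to [0, 1].

    A zero-range (constant) layer maps to the neutral 0.5 everywhere so a
    flat basin does not spuriously dominate through one factor's weight.
    """
    if layer.orientation == "categorical":
        raise ValueError("cannot min-max normalise a categorical factor")
    r = layer.raster
    vals = r.data()
    finite = vals[np.isfinite(vals)]
    lo, hi = finite.min(), finite.max()
    if hi - lo == 0:
        out = np.full(r.shape, 0.5)
    else:
        out = (vals - lo) / (hi - lo)
    out[~r.mask] = r.nodata
    return r.like(out, semantic="factor")


def orient(normalized: Raster, orientation: str) -> Raster:
    """Flip risk-increasing factors so larger output = more resistance."""
    if orientation == "categorical":
        raise ValueError("categorical factors are scored, not oriented")
    if orientation not in {"risk_increasing", "resistance_increasing"}:
        raise ValueError(f"unknown orientation {orientation!r}")
    vals = normalized.data()
    finite = vals[np.isfinite(vals)]
    if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
        raise ValueError("oriented input must lie in [0, 1]")
    if orientation == "risk_increasing":
        vals = 1.0 - vals
    vals[~normalized.mask] = normalized.nodata
    return normalized.like(vals)


def grade(oriented: Raster) -> Raster:
    """Equal-interval grading of [0, 1] values into scores 1/3/5/7/9.

    Bins are left-closed: [0,0.2) → 1, [0.2,0.4) → 3, …, [0.8,1] → 9.
    """
    vals = oriented.data()
    finite = vals[np.isfinite(vals)]
    if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
        raise ValueError("grade input must lie in [0, 1]")
    idx = np.digitize(np.nan_to_num(vals, nan=0.0), _GRADE_EDGES, right=False)
    out = _GRADE_SCORES[idx].astype(float)
    out[~oriented.mask] = oriented.nodata
    return oriented.like(out)


def grade_quantile(oriented: Raster) -> Raster:
    """Quantile (equal-count) alternative to :func:`grade`."""
    vals = oriented.data()
    finite = vals[np.isfinite(vals)]
    edges = np.quantile(finite, [0.2, 0.4, 0.6, 0.8])
    idx = np.digitize(np.nan_to_num(vals, nan=0.0), edges, right=False)
    out = _GRADE_SCORES[idx].astype(float)
    out[~oriented.mask] = oriented.nodata
    return oriented.like(out)


def score_landuse(landuse: Raster, scores: dict[int, int] | None = None) -> Raster:
    """Per-cell resistance score lookup for the land-use layer."""
    scores = dict(DEFAULT_LANDUSE_SCORES) if scores is None else scores
    codes = np.asarray(landuse.values)
    present = np.unique(codes[landuse.mask]).astype(int)
    unmapped = [c for c in present if c not in scores]
    if unmapped:
        raise ValueError(f"land-use codes without a score: {unmapped}")
    out = np.full(landuse.shape, float(landuse.nodata))
    m = landuse.mask
    lut = {c: float(s) for c, s in scores.items()}
    out[m] = np.vectorize(lut.get)(codes[m].astype(int))
    return landuse.like(out, semantic="factor")


def weighted_overlay(stack: FactorStack) -> ResistanceSurface:
    """R = Σ wₖ·gradeₖ per cell; nodata where any factor is nodata."""
    layers = list(stack.layers.values())
    ref = layers[0]
    for lyr in layers[1:]:
        if not ref.same_geometry(lyr):
            raise ValueError("factor layers do not share grid geometry")
    acc = np.zeros(ref.shape)
    valid = np.ones(ref.shape, dtype=bool)
    for name, lyr in stack.layers.items():
        acc += stack.weights[name] * lyr.data(fill=0.0)
        valid &= lyr.mask
    acc[~valid] = ref.nodata
    return ResistanceSurface(ref.like(acc, semantic="resistance"))


def extract_sources(landuse: Raster, source_type: str) -> SourceMask:
    """Mask of the paddy (PFSL) or construction (CLSL) source class."""
    code = {"PFSL": LANDUSE_CODES["paddy"], "CLSL": LANDUSE_CODES["construction"]}
    if source_type not in code:
        raise ValueError(f"unknown source type {source_type!r}")
    mask = (np.asarray(landuse.values) == code[source_type]) & landuse.mask
    if not mask.any():
        raise ValueError(f"no {source_type} cells in the land-use layer")
    return SourceMask(
        raster=landuse.like(mask.astype(np.int64), semantic="factor"),
        source_type=source_type,
    )


def build_resistance(
    dem: Raster,
    landuse: Raster,
    fvc: Raster,
    lake_mask: np.ndarray,
    lake_level: float | None = None,
    weights: dict[str, float] | None = None,
    landuse_scores: dict[int, int] | None = None,
    grading: str = "interval",
    relative_slope_mode: str = "lake",
) -> ResistanceSurface:
    """Convenience: factors → normalise → orient → grade → overlay.

    ``lake_level`` defaults to the minimum DEM elevation over the lake mask.
    ``relative_slope_mode`` selects the lake-relative angle (default) or the
    local Horn slope as the relative-slope factor.
    """
    from .terrain_factors import (
        relative_elevation, relative_slope, slope_degrees, surface_roughness)

    if lake_level is None:
        lake_level = float(dem.data()[np.asarray(lake_mask, bool)].min())
    local_slope = slope_degrees(dem)
    continuous = {
        "relative_elevation": relative_elevation(dem, lake_level),
        "relative_slope": (
            relative_slope(dem, lake_mask, lake_level)
            if relative_slope_mode == "lake" else local_slope),
        "surface_roughness": surface_roughness(local_slope),
        "vegetation_coverage": fvc,
    }
    grader = {"interval": grade, "quantile": grade_quantile}[grading]
    graded: dict[str, Raster] = {}
    for name, raster in continuous.items():
        layer = FactorLayer(raster=raster, name=name)
        graded[name] = grader(orient(normalize_minmax(layer), layer.orientation))
    graded["land_use"] = score_landuse(landuse, landuse_scores)
    stack = FactorStack(
        layers=graded,
        weights=dict(DEFAULT_WEIGHTS) if weights is None else dict(weights),
        landuse_scores=dict(DEFAULT_LANDUSE_SCORES)
        if landuse_scores is None else dict(landuse_scores),
    )
    return weighted_overlay(stack)
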