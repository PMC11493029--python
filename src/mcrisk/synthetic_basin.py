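"""Seeded synthetic plateau-lake basin scenarios.

Real inputs to the risk analysis (a 30 m DEM, a land-use map, vegetation
cover, inflow rivers, monthly water-quality means) are not redistributable,
so this module generates basins with the same statistical structure: a
bowl-shaped DEM with a single deep lake at its floor, dendritic drainage
into the lake, paddy patches clustered on flat land near the rivers,
construction near the shoreline, forest and grass on the slopes, and
per-river pollutant concentrations with a configurable *negative*
dependence on zonal mean MCR — the association the downstream correlation
stage is meant to detect.

Everything is a pure function of the scenario (including its seed); each
generator stage draws from its own seeded stream, so stages are
individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import LineString

from .grid_io import WQ_INDEXES, Raster, VectorLayer, WaterQualityTable
from .resistance_surface import LANDUSE_CODES
from .spatial_scales import (D8_OFFSETS, d8_flow_direction, fill_sinks,
                             flow_accumulation)
from .terrain_factors import slope_degrees

__all__ = [
    "BasinScenario",
    "SyntheticBasin",
    "DEFAULT_BASELINE",
    "generate_dem",
    "lake_mask_from_dem",
    "lake_polygon",
    "generate_rivers",
    "generate_landuse",
    "generate_fvc",
    "default_truth",
    "generate_water_quality",
    "generate_basin",
]

#: per-index baseline concentrations β0 (mg/L), of the order of the
#: column means of typical inflow-river monitoring tables
DEFAULT_BASELINE = {
    "NH3-N": 1.4, "TP": 0.4, "TN": 5.6, "COD_Mn": 4.5,
    "BOD5": 5.3, "COD_Cr": 21.0, "Fluoride": 0.45,
}

# terrain constants (metres)
_Z_FLOOR = 1700.0
_RELIEF = 400.0
_NOISE_AMP = 22.0

# per-stage rng streams
_STAGE_DEM, _STAGE_LANDUSE, _STAGE_FVC, _STAGE_WQ = 0, 1, 2, 3


@dataclass
class BasinScenario:
    """Study conditions for one synthetic basin."""

    seed: int = 1
    nrows: int = 128
    ncols: int = 128
    cell_size: float = 30.0
    lake_level: float = 1775.0
    n_rivers: int = 19
    paddy_fraction: float = 0.18
    construction_fraction: float = 0.08
    dryland_fraction: float = 0.12
    effect_slope: float = 1.0  # β1: mg/L (in index units) per SD of zonal MCR
    noise_sd: float = 0.25     # σ of the standardized concentration noise
    baseline: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BASELINE))
    fvc_noise_sd: float = 0.07

    def __post_init__(self) -> None:
        fr = (self.paddy_fraction, self.construction_fraction, self.dryland_fraction)
        if any(f < 0 or f > 1 for f in fr) or sum(fr) >= 1:
            raise ValueError("land-use fractions must lie in [0,1] and sum < 1")
        if self.n_rivers < 1:
            raise ValueError("need at least one river")
        if self.noise_sd < 0 or self.effect_slope < 0:
            raise ValueError("noise_sd and effect_slope must be ≥ 0")


@dataclass
class SyntheticBasin:
    scenario: BasinScenario
    dem: Raster
    landuse: Raster
    fvc: Raster
    lake_mask: np.ndarray
    lake: VectorLayer          # single polygon
    rivers: VectorLayer        # named polylines, headwater → lake boundary
    filled_dem: Raster
    flow_dir: Raster
    truth: dict


def _rng(scenario: BasinScenario, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(scenario.seed), stage])


def generate_dem(scenario: BasinScenario) -> Raster:
    """Bowl-shaped DEM: radial power-law rise plus smoothed random relief.

    The floor of the bowl sits below ``lake_level``; the noise amplitude is
    damped near the lake so the depression stays a single clean basin.
    """
    rng = _rng(scenario, _STAGE_DEM)
    nr, nc = scenario.nrows, scenario.ncols
    cy = nr / 2 + rng.uniform(-nr * 0.04, nr * 0.04)
    cx = nc / 2 + rng.uniform(-nc * 0.04, nc * 0.04)
    ii, jj = np.mgrid[0:nr, 0:nc]
    d = np.hypot(ii - cy, jj - cx)
    dn = d / (0.95 * min(nr, nc) / 2)
    base = _Z_FLOOR + _RELIEF * dn ** 1.7
    noise = ndimage.gaussian_filter(rng.standard_normal((nr, nc)), sigma=6.0)
    noise = noise / noise.std()
    damp = np.clip(dn, 0.15, 1.0)
    dem = base + _NOISE_AMP * damp * noise
    return Raster(values=dem, cell_size=scenario.cell_size,
                  origin=(0.0, nr * scenario.cell_size), semantic="dem")


def lake_mask_from_dem(dem: Raster, lake_level: float) -> np.ndarray:
    """Largest connected patch below the lake level (the lake itself)."""
    below = dem.data() < lake_level
    labels, n = ndimage.label(below, structure=np.ones((3, 3)))
    if n == 0:
        raise ValueError("no cells below the lake level")
    sizes = ndimage.sum_labels(below, labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def lake_polygon(lake_mask: np.ndarray, template: Raster) -> VectorLayer:
    """Lake outline as the union of its cell squares."""
    x0, y0 = template.origin
    s = template.cell_size
    rr, cc = np.nonzero(lake_mask)
    boxes = shapely.box(x0 + cc * s, y0 - (rr + 1) * s,
                        x0 + (cc + 1) * s, y0 - rr * s)
    poly = shapely.union_all(boxes)
    if poly.geom_type == "MultiPolygon":
        poly = max(poly.geoms, key=lambda g: g.area)
    return VectorLayer(features=[(poly, {"name": "lake"})], geometry_kind="polygon")


def _route(dem: Raster, lake_mask: np.ndarray):
    filled = fill_sinks(dem, outlets=lake_mask)
    fdir = d8_flow_direction(filled, outlets=lake_mask)
    acc = flow_accumulation(fdir)
    return filled, fdir, acc


def generate_rivers(
    dem: Raster,
    lake_mask: np.ndarray,
    n_rivers: int,
    min_acc: int = 5,
) -> VectorLayer:
    """Trace ``n_rivers`` inflow rivers from headwaters to the lake edge.

    Pour candidates are land cells draining directly into a lake cell,
    ranked by flow accumulation within angular sectors around the lake so
    the rivers spread along the shoreline.  Each river is traced upstream
    along the maximum-accumulation branch, then emitted headwater-first;
    the final vertex lies on the shared edge between the pour cell and the
    lake cell it drains into, i.e. exactly on the lake boundary.
    """
    filled, fdir, acc = _route(dem, lake_mask)
    direction = np.asarray(fdir.values)
    accv = np.asarray(acc.values)
    nr, nc = direction.shape

    # land cells whose downstream neighbour is a lake cell
    cand = []
    for i, j in zip(*np.nonzero(~lake_mask)):
        k = direction[i, j]
        if k < 0:
            continue
        di, dj = D8_OFFSETS[k]
        ni, nj = i + di, j + dj
        if 0 <= ni < nr and 0 <= nj < nc and lake_mask[ni, nj]:
            cand.append((i, j))
    if len(cand) < n_rivers:
        raise ValueError(
            f"only {len(cand)} drainage paths reach the lake, need {n_rivers}")

    cy, cx = np.mean(np.nonzero(lake_mask), axis=1)
    angles = np.array([np.arctan2(i - cy, j - cx) for i, j in cand])
    accs = np.array([accv[i, j] for i, j in cand])
    sector = ((angles + np.pi) / (2 * np.pi) * n_rivers).astype(int) % n_rivers

    chosen: list[tuple[int, int]] = []
    taken = np.zeros(len(cand), dtype=bool)
    for sec in range(n_rivers):
        in_sec = np.nonzero((sector == sec) & ~taken)[0]
        if in_sec.size:
            best = in_sec[np.argmax(accs[in_sec])]
            chosen.append(cand[best])
            taken[best] = True
    # fill any empty sectors with the best remaining candidates
    order = np.argsort(-accs)
    for idx in order:
        if len(chosen) >= n_rivers:
            break
        if not taken[idx]:
            i, j = cand[idx]
            if all(max(abs(i - ci), abs(j - cj)) > 1 for ci, cj in chosen):
                chosen.append((i, j))
                taken[idx] = True
    if len(chosen) < n_rivers:
        raise ValueError(
            f"could not place {n_rivers} separated pour points "
            f"({len(chosen)} available)")

    x0, y0 = dem.origin
    s = dem.cell_size

    def center(i: int, j: int) -> tuple[float, float]:
        return (x0 + (j + 0.5) * s, y0 - (i + 0.5) * s)

    features = []
    for rid, (pi, pj) in enumerate(chosen, start=1):
        path = [(pi, pj)]
        i, j = pi, pj
        while True:
            ups = []
            for k, (di, dj) in enumerate(D8_OFFSETS):
                ni, nj = i + di, j + dj
                if 0 <= ni < nr and 0 <= nj < nc and direction[ni, nj] >= 0:
                    ddi, ddj = D8_OFFSETS[direction[ni, nj]]
                    if (ni + ddi, nj + ddj) == (i, j):
                        ups.append((accv[ni, nj], ni, nj))
            if not ups:
                break
            a, ni, nj = max(ups)
            if a < min_acc:
                break
            path.append((ni, nj))
            i, j = ni, nj
        path.reverse()  # headwater first
        coords = [center(i, j) for i, j in path]
        di, dj = D8_OFFSETS[direction[pi, pj]]
        lx, ly = center(pi + di, pj + dj)
        px, py = center(pi, pj)
        coords.append(((px + lx) / 2, (py + ly) / 2))  # point on the lake edge
        features.append((LineString(coords), {"name": f"River {rid:02d}"}))
    return VectorLayer(features=features, geometry_kind="polyline")


def _smooth_noise(rng: np.random.Generator, shape, sigma=4.0) -> np.ndarray:
    n = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    return n / n.std()


def generate_landuse(
    scenario: BasinScenario,
    dem: Raster,
    rivers: VectorLayer,
    lake_mask: np.ndarray,
) -> Raster:
    """Place the six land-use classes with the expected spatial structure.

    Construction clusters on flat land near the shoreline, paddy on
    low-slope land near rivers, dryland on the flattest remainder; the
    remaining slopes split into grass (gentler) and forest (steeper).
    Class shares are hit by count selection, so realized fractions match
    the targets up to rounding.
    """
    rng = _rng(scenario, _STAGE_LANDUSE)
    slope = slope_degrees(dem).data()
    nr, nc = dem.shape
    n_land = int((~lake_mask).sum())
    n_con = round(scenario.construction_fraction * n_land)
    n_paddy = round(scenario.paddy_fraction * n_land)
    n_dry = round(scenario.dryland_fraction * n_land)
    if n_con + n_paddy + n_dry > n_land:
        raise ValueError("land-use targets infeasible on this terrain")

    xs, ys = dem.cell_centers()
    pts = shapely.points(xs.ravel(), ys.ravel())
    river_union = shapely.union_all([g for g, _ in rivers])
    d_river = shapely.distance(river_union, pts).reshape(nr, nc)
    d_lake = ndimage.distance_transform_edt(~lake_mask) * dem.cell_size

    out = np.zeros((nr, nc), dtype=np.int64)
    out[lake_mask] = LANDUSE_CODES["water"]
    free = ~lake_mask

    def take(suit: np.ndarray, n: int, code: int) -> None:
        nonlocal free
        if n <= 0:
            return
        s = np.where(free, suit, -np.inf)
        idx = np.argpartition(s, -n, axis=None)[-n:]
        sel = np.zeros(out.size, dtype=bool)
        sel[idx] = True
        sel = sel.reshape(out.shape)
        out[sel] = code
        free &= ~sel

    scale = dem.cell_size
    suit_con = (-d_lake / (12 * scale) - slope / 6.0
                + 0.8 * _smooth_noise(rng, (nr, nc)))
    take(suit_con, n_con, LANDUSE_CODES["construction"])
    suit_paddy = (-d_river / (8 * scale) - slope / 4.0
                  + 0.8 * _smooth_noise(rng, (nr, nc)))
    take(suit_paddy, n_paddy, LANDUSE_CODES["paddy"])
    suit_dry = -slope / 4.0 - d_river / (20 * scale) \
        + 0.6 * _smooth_noise(rng, (nr, nc))
    take(suit_dry, n_dry, LANDUSE_CODES["dryland"])

    # remaining slopes: gentler 40% grass, steeper forest
    rem_slope = slope[free]
    if rem_slope.size:
        cut = np.quantile(rem_slope, 0.4)
        grass = free & (slope <= cut)
        out[grass] = LANDUSE_CODES["grass"]
        out[free & ~grass] = LANDUSE_CODES["forest"]
    return dem.like(out, semantic="landuse", nodata=-9999)


#: class-conditional mean fractional vegetation cover
_FVC_MEANS = {
    LANDUSE_CODES["forest"]: 0.85,
    LANDUSE_CODES["grass"]: 0.65,
    LANDUSE_CODES["dryland"]: 0.45,
    LANDUSE_CODES["paddy"]: 0.35,
    LANDUSE_CODES["construction"]: 0.12,
    LANDUSE_CODES["water"]: 0.02,
}


def generate_fvc(scenario: BasinScenario, landuse: Raster) -> Raster:
    """Fractional vegetation cover: class mean plus seeded noise, in [0, 1]."""
    rng = _rng(scenario, _STAGE_FVC)
    codes = np.asarray(landuse.values)
    out = np.zeros(landuse.shape, dtype=float)
    for code, mean in _FVC_MEANS.items():
        out[codes == code] = mean
    if scenario.fvc_noise_sd > 0:
        out = out + rng.normal(0.0, scenario.fvc_noise_sd, size=out.shape)
    out = np.clip(out, 0.0, 1.0)
    return landuse.like(out, semantic="fvc", nodata=-9999.0)


def default_truth(scenario: BasinScenario) -> dict[str, dict[str, float]]:
    """Per-index (β0, β1, σ) of the planted MCR → concentration link."""
    return {
        idx: {"beta0": float(scenario.baseline[idx]),
              "beta1": float(scenario.effect_slope),
              "sigma": float(scenario.noise_sd)}
        for idx in WQ_INDEXES
    }


def generate_water_quality(
    zone_means: dict[str, float],
    truth: dict[str, dict[str, float]],
    seed: int,
) -> tuple[WaterQualityTable, dict]:
    """Concentrations with a planted negative dependence on zonal mean MCR.

    For each index with parameters (β0, β1, σ) the model is

        conc = β0 − s·(β1·z + ε),   ε ~ N(0, σ²),   s = β0 / 3,

    where z is the across-river standardized zonal mean MCR.  The per-index
    amplitude ``s`` keeps every index on its own concentration scale while
    β1 and σ stay comparable across indexes (Pearson correlation is
    invariant to the scaling).  Values are clipped at 0 mg/L; the clipping
    rate is reported alongside the truth parameters.
    """
    rivers = list(zone_means)
    if len(rivers) < 3:
        raise ValueError("need at least 3 rivers for a downstream correlation")
    m = np.array([zone_means[r] for r in rivers], dtype=float)
    sd = m.std()
    z = (m - m.mean()) / sd if sd > 0 else np.zeros_like(m)
    rng = np.random.default_rng(seed)
    rows: dict[str, dict[str, float]] = {r: {} for r in rivers}
    clipped = 0
    for idx in WQ_INDEXES:
        p = truth[idx]
        s = p["beta0"] / 3.0
        eps = rng.normal(0.0, p["sigma"], size=len(rivers))
        conc = p["beta0"] - s * (p["beta1"] * z + eps)
        clipped += int(np.sum(conc < 0))
        conc = np.maximum(conc, 0.0)
        for r, c in zip(rivers, conc):
            rows[r][idx] = float(c)
    report = {
        "truth": truth,
        "clip_rate": clipped / (len(rivers) * len(WQ_INDEXES)),
    }
    return WaterQualityTable(rows=rows), report


def generate_basin(scenario: BasinScenario) -> SyntheticBasin:
    """Generate all spatial layers of a scenario (no water quality yet —
    concentrations depend on zonal MCR means computed downstream)."""
    dem = generate_dem(scenario)
    lmask = lake_mask_from_dem(dem, scenario.lake_level)
    lake = lake_polygon(lmask, dem)
    rivers = generate_rivers(dem, lmask, scenario.n_rivers)
    landuse = generate_landuse(scenario, dem, rivers, lmask)
    fvc = generate_fvc(scenario, landuse)
    filled = fill_sinks(dem, outlets=lmask)
    fdir = d8_flow_direction(filled, outlets=lmask)
    return SyntheticBasin(
        scenario=scenario, dem=dem, landuse=landuse, fvc=fvc,
        lake_mask=lmask, lake=lake, rivers=rivers,
        filled_dem=filled, flow_dir=fdir, truth=default_truth(scenario))
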