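"""End-to-end orchestration: scenario/inputs → risk maps → correlations.

A run executes, in order: input generation or loading, factor layers,
resistance base surface, source masks (PFSL and CLSL), MCR accumulation per
source type, five-level risk zoning with class shares, the seven analysis
scales, zonal mean MCR, and the multi-scale Pearson correlation against the
water-quality table.  Outputs land under a fixed run-directory layout
(``layers/``, ``zones/``, ``tables/``, ``report.json``) and are
deterministic for a fixed config + seed, so a rerun is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import grid_io
from .cost_distance import accumulate_mcr
from .grid_io import Raster, VectorLayer, WaterQualityTable, read_raster, \
    read_vector, read_wq_table, write_raster, write_vector
from .resistance_surface import (DEFAULT_LANDUSE_SCORES, DEFAULT_WEIGHTS,
                                 LANDUSE_CODES, build_resistance,
                                 extract_sources)
from .risk_zoning import classify_risk, risk_shares
from .spatial_scales import buffer_zones, lakeshore_zone, ZoneSet
from .stats_link import correlation_frame, correlation_matrix, zonal_mean
from .synthetic_basin import (BasinScenario, SyntheticBasin, generate_basin,
                              generate_water_quality)

__all__ = ["RunConfig", "RunResult", "run", "validate_grids", "simulate"]

log = logging.getLogger(__name__)

SOURCE_TYPES = ("PFSL", "CLSL")


@dataclass
class RunConfig:
    """Everything a run needs; exactly one of scenario / input paths."""

    scenario: BasinScenario | None = None
    dem_path: str | None = None
    landuse_path: str | None = None
    fvc_path: str | None = None
    lake_path: str | None = None
    rivers_path: str | None = None
    wq_path: str | None = None
    weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    landuse_scores: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_LANDUSE_SCORES))
    grading: str = "interval"
    connectivity: int = 8
    buffer_distances: tuple[float, ...] = (100.0, 300.0, 500.0, 700.0, 1000.0)
    lakeshore_width: float = 110.0
    jenks_sample_cap: int = 5000
    seed: int = 1
    out_dir: str | None = None

    def __post_init__(self) -> None:
        paths = [self.dem_path, self.landuse_path, self.fvc_path,
                 self.lake_path, self.rivers_path]
        has_paths = any(p is not None for p in paths)
        if (self.scenario is None) == (not has_paths):
            raise ValueError("exactly one of {scenario, input paths} must be set")
        d = list(self.buffer_distances)
        if any(x <= 0 for x in d) or d != sorted(set(d)):
            raise ValueError("buffer distances must be positive, strictly increasing")


@dataclass
class RunResult:
    mcr: dict            # source_type -> MCRSurface
    risk: dict           # source_type -> RiskMap
    shares: dict         # source_type -> DataFrame
    zonesets: dict       # scale_name -> ZoneSet
    correlations: object  # DataFrame
    wq: WaterQualityTable
    report: dict


def validate_grids(layers: list[Raster]) -> None:
    """All layers of one run must share shape, cell size and origin."""
    if len(layers) < 2:
        raise ValueError("need at least two layers to validate")
    ref = layers[0]
    for k, lyr in enumerate(layers[1:], start=1):
        if not ref.same_geometry(lyr):
            raise ValueError(
                f"layer {k} geometry mismatch: shape {lyr.shape} vs {ref.shape}, "
                f"cell {lyr.cell_size} vs {ref.cell_size}, "
                f"origin {lyr.origin} vs {ref.origin}")


def simulate(scenario: BasinScenario, out_dir: str | Path) -> SyntheticBasin:
    """Generate a scenario's input layers and write them to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    basin = generate_basin(scenario)
    write_raster(basin.dem, out / "dem.asc")
    write_raster(basin.landuse, out / "landuse.asc")
    write_raster(basin.fvc, out / "fvc.asc")
    write_vector(basin.lake, out / "lake.geojson")
    write_vector(basin.rivers, out / "rivers.geojson")
    (out / "truth.json").write_text(json.dumps(basin.truth, indent=1))
    return basin


def _load_inputs(cfg: RunConfig):
    dem = read_raster(cfg.dem_path)
    landuse = read_raster(cfg.landuse_path)
    fvc = read_raster(cfg.fvc_path)
    lake = read_vector(cfg.lake_path)
    rivers = read_vector(cfg.rivers_path)
    lake_mask = grid_io.rasterize(lake, dem, burn=1.0).values == 1.0
    wq = read_wq_table(cfg.wq_path) if cfg.wq_path else None
    return dem, landuse, fvc, lake, rivers, lake_mask, wq


def _config_digest(cfg: RunConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run(cfg: RunConfig) -> RunResult:
    """Execute the full analysis; see the module docstring for the stages."""
    timings: dict[str, float] = {}
    warnings: list[str] = []
    t0 = time.perf_counter()

    def tick(stage: str) -> None:
        nonlocal t0
        timings[stage] = round(time.perf_counter() - t0, 3)
        t0 = time.perf_counter()
        log.info("stage %-12s %.3fs", stage, timings[stage])

    wq: WaterQualityTable | None = None
    if cfg.scenario is not None:
        basin = generate_basin(cfg.scenario)
        dem, landuse, fvc = basin.dem, basin.landuse, basin.fvc
        lake, rivers, lake_mask = basin.lake, basin.rivers, basin.lake_mask
    else:
        dem, landuse, fvc, lake, rivers, lake_mask, wq = _load_inputs(cfg)
    validate_grids([dem, landuse, fvc])
    tick("inputs")

    resistance = build_resistance(
        dem, landuse, fvc, lake_mask,
        weights=cfg.weights, landuse_scores=cfg.landuse_scores,
        grading=cfg.grading)
    tick("resistance")

    mcr, risk, shares = {}, {}, {}
    for stype in SOURCE_TYPES:
        sources = extract_sources(landuse, stype)
        mcr[stype] = accumulate_mcr(resistance, sources,
                                    connectivity=cfg.connectivity)
        risk[stype] = classify_risk(mcr[stype], k=5,
                                    sample_cap=cfg.jenks_sample_cap,
                                    seed=cfg.seed)
        shares[stype] = risk_shares(risk[stype])
    tick("mcr_risk")

    zonesets: dict[str, ZoneSet] = {}
    buffers = buffer_zones(rivers, dem, distances=cfg.buffer_distances,
                           exclude=lake_mask)
    for w, zs in buffers.items():
        zonesets[zs.scale_name] = zs
    from .spatial_scales import delineate_subbasins, d8_flow_direction, fill_sinks
    filled = fill_sinks(dem, outlets=lake_mask)
    fdir = d8_flow_direction(filled, outlets=lake_mask)
    pour_feats = []
    from shapely.geometry import Point
    for geom, attrs in rivers:
        pour_feats.append((Point(geom.coords[-1]), dict(attrs)))
    pours = VectorLayer(features=pour_feats, geometry_kind="point")
    zonesets["subbasin"] = delineate_subbasins(fdir, pours)
    zonesets["lakeshore"] = lakeshore_zone(lake, dem, width=cfg.lakeshore_width,
                                           lake_mask=lake_mask)
    tick("scales")

    zonal_stats = []
    for zs in zonesets.values():
        for stype in SOURCE_TYPES:
            zonal_stats.extend(zonal_mean(mcr[stype], zs))
    tick("zonal")

    wq_report = {}
    if wq is None:
        if cfg.scenario is None:
            raise ValueError(
                "file-based runs need a water-quality table (wq_path); "
                "synthetic concentrations exist only in scenario mode")
        # synthetic concentrations planted on the 1000 m-buffer PFSL means
        key = f"buffer_{int(max(cfg.buffer_distances))}"
        means = {zs.river: zs.mean_mcr for zs in zonal_stats
                 if zs.scale_name == key and zs.source_type == "PFSL"}
        scen = cfg.scenario
        from .synthetic_basin import default_truth
        wq, wq_report = generate_water_quality(
            means, default_truth(scen), seed=int(np.random.SeedSequence(
                [scen.seed, 3]).generate_state(1)[0] % (2**31)))
        if wq_report["clip_rate"] > 0:
            warnings.append(f"clipped concentration rate "
                            f"{wq_report['clip_rate']:.4f}")
    corr = correlation_frame(correlation_matrix(zonal_stats, wq))
    tick("correlation")

    report = {
        "config_digest": _config_digest(cfg),
        "seed": cfg.seed,
        "n_mcr_layers": len(mcr),
        "n_risk_maps": len(risk),
        "n_zonesets": len(zonesets),
        "n_correlation_rows": int(len(corr)),
        "water_quality": wq_report,
        "warnings": warnings,
        "timings_s": timings,
    }
    result = RunResult(mcr=mcr, risk=risk, shares=shares, zonesets=zonesets,
                       correlations=corr, wq=wq, report=report)
    if cfg.out_dir:
        _write_outputs(cfg, result, dem)
    return result


def _write_outputs(cfg: RunConfig, res: RunResult, template: Raster) -> None:
    out = Path(cfg.out_dir)
    for sub in ("layers", "zones", "tables"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    for stype in SOURCE_TYPES:
        write_raster(res.mcr[stype].raster, out / "layers" / f"mcr_{stype}.asc")
        write_raster(res.risk[stype].raster, out / "layers" / f"risk_{stype}.asc")
        res.shares[stype].to_csv(out / "tables" / f"risk_shares_{stype}.csv",
                                 index=False, float_format="%.10g")
    sidecar = {}
    for name, zs in res.zonesets.items():
        write_raster(zs.zone_raster(template), out / "zones" / f"{name}.asc")
        sidecar[name] = {
            "provenance": zs.provenance,
            "zones": {zid: z.name for zid, z in zs.zones.items()},
        }
    (out / "zones" / "zonesets.json").write_text(json.dumps(sidecar, indent=1))
    res.correlations.to_csv(out / "tables" / "correlations.csv",
                            index=False, float_format="%.10g")
    res.wq.to_frame().rename_axis("River").to_csv(
        out / "tables" / "water_quality.csv", float_format="%.10g")
    (out / "report.json").write_text(json.dumps(res.report, indent=1))
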