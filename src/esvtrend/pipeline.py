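"""End-to-end orchestration: simulate/load -> value -> trend -> joinpoint -> compare.

`run_pipeline` executes every stage on a config, writes all outputs
(CSV/ASC/GeoJSON/JSON, all plain text) under the output directory and
returns the in-memory results. Each stage is also callable on its own;
the CLI in :mod:`esvtrend.cli` is a thin wrapper over this module.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely

from . import compare as cmp
from . import gridio, joinpoint as jp, trend as tr
from .coefficients import default_weight_table
from .core import LandUseSeries, Raster, SocioEconomicSeries, tabulate_areas, LandUseClass, ServiceType
from .synthetic import LandscapeConfig, generate_landscape_series, generate_socioeconomic_series
from .valuation import (
    build_value_table,
    calibrate_unit_value,
    comparable_esv,
    deflate_series,
    dynamic_adjust,
    esv_raster,
    esv_totals,
)

log = logging.getLogger("esvtrend")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    outdir: str = "esvtrend_out"
    seed: int = 0
    # inputs: either simulate=True or paths to prepared files
    simulate: bool = True
    landscape: LandscapeConfig | None = None
    landuse_dir: str | None = None  # landuse_<year>.asc files
    socio_csv: str | None = None
    concessions_geojson: str | None = None
    study_geojson: str | None = None
    # valuation
    base_year: int = 1990
    # trend
    beta_threshold: float = tr.DEFAULT_BETA_THRESHOLD
    z_threshold: float = tr.DEFAULT_Z_THRESHOLD
    # joinpoint
    max_joinpoints: int = 3
    # compare
    n_points: int = 300
    buffer_radius: float = 1000.0
    grid_cell: float = 10_000.0
    alpha: float = 0.05
    write_rasters: bool = True


@dataclass
class PipelineResult:
    accounts: pd.DataFrame
    trend_summary: pd.DataFrame
    joinpoint_report: dict
    comparison: pd.DataFrame
    class_raster: Raster
    manifest: dict


def _load_inputs(cfg: PipelineConfig):
    if cfg.simulate:
        lc = cfg.landscape or LandscapeConfig(seed=cfg.seed)
        series, concessions, study, _ = generate_landscape_series(lc)
        socio = generate_socioeconomic_series(years=lc.years, seed=cfg.seed)
        return series, concessions, study, socio
    for name in ("landuse_dir", "socio_csv", "concessions_geojson", "study_geojson"):
        p = getattr(cfg, name)
        if p is None or not Path(p).exists():
            raise FileNotFoundError(f"pipeline input {name} missing: {p}")
    files = sorted(Path(cfg.landuse_dir).glob("landuse_*.asc"))
    years = [int(f.stem.split("_")[1]) for f in files]
    if not years:
        raise FileNotFoundError(f"no landuse_<year>.asc files in {cfg.landuse_dir}")
    rasters = [gridio.read_ascii_grid(f, categorical=True) for f in files]
    series = LandUseSeries(years, rasters)
    socio = gridio.read_socioeconomic_csv(cfg.socio_csv)
    concessions = gridio.read_polygons(cfg.concessions_geojson)
    study = gridio.read_polygons(cfg.study_geojson)[0]
    return series, concessions, study, socio


def _dynamic_factors(socio: SocioEconomicSeries, base_year: int):
    """Per-year multiplier (E_an/E_avg) * Ac applied to static value."""
    e_an, e_avg = deflate_series(socio, base_year)
    b = socio.index_of(base_year)
    rows = []
    for off, year in enumerate(socio.years[b:]):
        t, ac, _ = dynamic_adjust(1.0, socio.engel[b + off])
        rows.append(
            {
                "year": int(year),
                "e_an": float(e_an[off]),
                "e_avg": float(e_avg),
                "t": t,
                "ac": ac,
                "factor": float(e_an[off] / e_avg * ac),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    t_start = time.time()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    timings = {}

    def tick(stage, t0):
        timings[stage] = round(time.time() - t0, 3)
        log.info("stage %s done in %.2fs", stage, timings[stage])

    t0 = time.time()
    series, concessions, study, socio = _load_inputs(cfg)
    if cfg.simulate:
        gridio.write_polygons(out / "concessions.geojson", concessions)
        gridio.write_polygons(out / "study_area.geojson", [study])
        gridio.write_socioeconomic_csv(out / "socioeconomic.csv", socio)
    tick("inputs", t0)

    # --- valuation ---------------------------------------------------
    t0 = time.time()
    b = socio.index_of(cfg.base_year)
    D = calibrate_unit_value(float(socio.grain_yield[b]), float(socio.grain_price[b]))
    vc = build_value_table(default_weight_table(), D)
    factors = _dynamic_factors(socio, cfg.base_year)
    fac_by_year = factors.set_index("year")
    acc_rows = []
    dyn_stack: list[Raster] = []
    for year in series.years:
        areas = tabulate_areas(series, year)
        acct = esv_totals(areas, vc, year=year)
        f = fac_by_year.loc[year]
        acct.esv_comparable = comparable_esv(acct.esv_static, f["e_avg"], f["e_an"])
        acct.esv_dynamic = acct.esv_comparable * f["ac"]
        row = {
            "year": year,
            "esv_static": acct.esv_static,
            "esv_comparable": acct.esv_comparable,
            "esv_dynamic": acct.esv_dynamic,
            "ac": f["ac"],
        }
        row.update({f"esv_{s.name}": v for s, v in acct.esv_by_service.items()})
        row.update({f"area_{k.name}": areas[k] for k in LandUseClass})
        acc_rows.append(row)
        static_r = esv_raster(series.raster_for(year), vc, per="hectare")
        dyn = Raster(static_r.data * f["factor"], static_r.transform, nodata=float("nan"))
        dyn_stack.append(dyn)
    accounts = pd.DataFrame(acc_rows)
    accounts.to_csv(out / "esv_accounts.csv", index=False)
    tick("valuation", t0)

    # --- trend -------------------------------------------------------
    t0 = time.time()
    beta_r, z_r, class_r = tr.trend_raster(
        dyn_stack, np.asarray(series.years, dtype=float),
        cfg.beta_threshold, cfg.z_threshold,
    )
    summary = tr.summarize_classes(class_r)
    summary.to_csv(out / "trend_class_areas.csv", index=False)
    if cfg.write_rasters:
        gridio.write_ascii_grid(out / "trend_beta.asc", beta_r)
        gridio.write_ascii_grid(out / "trend_z.asc", z_r)
        gridio.write_ascii_grid(out / "trend_class.asc", class_r)
        gridio.write_ascii_grid(out / f"esv_dynamic_{series.years[-1]}.asc", dyn_stack[-1])
    tick("trend", t0)

    # --- joinpoint on regional mean ESVd (mining vs control) ---------
    t0 = time.time()
    conc_mask = dyn_stack[0].mask_for(concessions)
    jp_report = {}
    for name, mask in (("mining", conc_mask), ("control", ~conc_mask)):
        mean_series = np.array(
            [float(np.nanmean(r.data[mask])) for r in dyn_stack]
        )
        fit = jp.select_model(
            np.asarray(series.years, dtype=float), mean_series, cfg.max_joinpoints
        )
        segs = jp.apc(fit, cfg.alpha)
        aapc_res = jp.aapc(fit, cfg.alpha)
        jp_report[name] = {
            "breakpoints": [float(x) for x in fit.breakpoints],
            "segments": [
                {
                    "start": s.start, "end": s.end, "apc": s.apc,
                    "ci": [s.ci_low, s.ci_high], "p": s.p_value,
                }
                for s in segs
            ],
            "aapc": aapc_res.aapc,
            "aapc_ci": [aapc_res.ci_low, aapc_res.ci_high],
            "aapc_p": aapc_res.p_value,
            "mean_esv_per_ha": mean_series.tolist(),
        }
    (out / "joinpoint.json").write_text(json.dumps(jp_report, indent=1))
    tick("joinpoint", t0)

    # --- compare -----------------------------------------------------
    t0 = time.time()
    pts = cmp.sample_points(
        study, concessions, n=cfg.n_points, seed=cfg.seed, buffer_radius=cfg.buffer_radius
    )
    comp_rows = []
    for year, dyn in ((series.years[0], dyn_stack[0]), (series.years[-1], dyn_stack[-1])):
        ext = cmp.buffer_extract(dyn, pts)
        a = ext.loc[ext.group == cmp.MINING, "mean"]
        bvals = ext.loc[ext.group == cmp.CONTROL, "mean"]
        res = cmp.mann_whitney(a, bvals, cfg.alpha)
        tt = cmp.t_test(a, bvals, cfg.alpha)
        comp_rows.append({"year": year, "test": "mann_whitney", **res})
        comp_rows.append({"year": year, "test": "t_test", **tt})
    comparison = pd.DataFrame(comp_rows)
    comparison.to_csv(out / "comparison.csv", index=False)
    grid_table, _ = cmp.grid_aggregate(dyn_stack[-1], cfg.grid_cell)
    grid_table.to_csv(out / "grid_aggregate.csv", index=False)
    pts.to_frame().to_csv(out / "sample_points.csv", index=False)
    tick("compare", t0)

    manifest = {
        "config": {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
            for k, v in dataclasses.asdict(cfg).items()
        },
        "seed": cfg.seed,
        "years": list(map(int, series.years)),
        "base_unit_value": D,
        "n_points": len(pts),
        "timings_s": timings,
        "total_s": round(time.time() - t_start, 3),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return PipelineResult(accounts, summary, jp_report, comparison, class_r, manifest)
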