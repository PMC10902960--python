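"""Text-format I/O: ESRI ASCII grids, GeoJSON polygons, CSV tables.

Rasters are exchanged as ESRI ASCII grid (.asc), a plain-text raster
format readable by GDAL/QGIS; categorical grids are written as integers,
continuous grids as floats with NaN mapped to the declared NODATA value.
Polygons travel as GeoJSON; the socioeconomic series and valuation
accounts as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import shapely.geometry

from .core import GridTransform, LandUseClass, Raster, SocioEconomicSeries

__all__ = [
    "write_ascii_grid",
    "read_ascii_grid",
    "write_polygons",
    "read_polygons",
    "write_socioeconomic_csv",
    "read_socioeconomic_csv",
    "write_legend",
]


def write_ascii_grid(path, raster: Raster, fmt: str | None = None) -> None:
    """Write a Raster as an ESRI ASCII grid (requires square pixels)."""
    path = Path(path)
    tr = raster.transform
    if abs(tr.dx - tr.dy) > 1e-9:
        raise ValueError("ASCII grid requires square pixels")
    rows, cols = raster.shape
    data = raster.data
    is_float = np.issubdtype(data.dtype, np.floating)
    nodata = raster.nodata
    if nodata is None:
        nodata = -9999
    if is_float and isinstance(nodata, float) and np.isnan(nodata):
        nodata_out = -9999.0
        data = np.where(np.isnan(data), nodata_out, data)
    else:
        nodata_out = nodata
    if fmt is None:
        fmt = "%.6f" if is_float else "%d"
    header = (
        f"ncols {cols}\nnrows {rows}\n"
        f"xllcorner {tr.x0:.6f}\nyllcorner {tr.y0 - rows * tr.dy:.6f}\n"
        f"cellsize {tr.dx:.6f}\nNODATA_value {nodata_out}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt=fmt)


def read_ascii_grid(path, categorical: bool = False) -> Raster:
    """Read an ESRI ASCII grid into a Raster."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            ):
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        data = np.loadtxt(fh)
    rows, cols = int(header["nrows"]), int(header["ncols"])
    data = data.reshape(rows, cols)
    cell = header["cellsize"]
    tr = GridTransform(header["xllcorner"], header["yllcorner"] + rows * cell, cell, cell)
    nodata_in = header.get("nodata_value", -9999)
    if categorical:
        return Raster(data.astype(np.uint8), tr, nodata=int(nodata_in))
    data = np.where(data == nodata_in, np.nan, data)
    return Raster(data, tr, nodata=float("nan"))


def write_polygons(path, polygons, properties=None) -> None:
    """Write shapely polygons as a GeoJSON FeatureCollection."""
    feats = []
    for i, poly in enumerate(polygons):
        props = dict(properties[i]) if properties else {}
        feats.append(
            {"type": "Feature", "geometry": shapely.geometry.mapping(poly), "properties": props}
        )
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}, indent=1))


def read_polygons(path) -> list[shapely.Geometry]:
    doc = json.loads(Path(path).read_text())
    if doc.get("type") == "FeatureCollection":
        return [shapely.geometry.shape(f["geometry"]) for f in doc["features"]]
    if doc.get("type") == "Feature":
        return [shapely.geometry.shape(doc["geometry"])]
    return [shapely.geometry.shape(doc)]


_SOCIO_COLS = ["year", "gdp", "gdp_index", "engel", "grain_yield", "grain_price"]


def write_socioeconomic_csv(path, socio: SocioEconomicSeries) -> None:
    pd.DataFrame(
        {c: getattr(socio, "years" if c == "year" else c) for c in _SOCIO_COLS}
    ).to_csv(path, index=False)


def read_socioeconomic_csv(path) -> SocioEconomicSeries:
    df = pd.read_csv(path)
    missing = set(_SOCIO_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"socioeconomic CSV missing columns: {sorted(missing)}")
    return SocioEconomicSeries(
        years=df["year"].to_numpy(),
        gdp=df["gdp"].to_numpy(),
        gdp_index=df["gdp_index"].to_numpy(),
        engel=df["engel"].to_numpy(),
        grain_yield=df["grain_yield"].to_numpy(),
        grain_price=df["grain_price"].to_numpy(),
    )


def write_legend(path) -> None:
    Path(path).write_text(json.dumps(LandUseClass.legend(), indent=1))
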