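"""File dialects: GeoJSON, ESRI ASCII grid, cohort CSV.

GeoJSON files are RFC 7946 FeatureCollections whose coordinates are
*planar metres*, not WGS84; every file written here carries a
``crs_note`` foreign member saying so.  Geometry types are limited to
Point / Polygon / MultiPolygon.  Rasters use the plain-text ESRI ASCII
grid (six-line header, ``NODATA_value -9999``); the in-memory raster
convention (row 0 = southernmost) is flipped to the format's
north-first row order on write and back on read.  CSVs are UTF-8,
comma-separated, ``.`` decimal, with a header row.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .proximity import FacilityLayer, Raster, RasterGrid
from .synthetic_city import SectorMap

NODATA = -9999.0
CRS_NOTE = "planar metric coordinates (local projection), not WGS84"
_ALLOWED_GEOMS = {"Point", "Polygon", "MultiPolygon"}

COHORT_COLUMNS = [
    "id", "x_m", "y_m", "sex", "age", "bmi",
    "gait_speed_m_s", "grip_kg", "weight_loss_kg_6mo",
    "exhaustion_q1", "exhaustion_q2",
    "diff_walk_block", "diff_climb_stairs", "planted_category",
]


class ParseError(ValueError):
    """Raised for malformed input files."""


# ---------------------------------------------------------------------------
# GeoJSON


def _check_geometry(gj: dict, where: str) -> None:
    t = gj.get("type")
    if t not in _ALLOWED_GEOMS:
        raise ParseError(
            f"{where}: geometry type {t!r} not supported "
            f"(allowed: {sorted(_ALLOWED_GEOMS)})"
        )


def write_geojson(path, features: list[dict]) -> None:
    """Write a FeatureCollection of (geometry, properties) dicts."""
    fc = {
        "type": "FeatureCollection",
        "crs_note": CRS_NOTE,
        "features": features,
    }
    Path(path).write_text(json.dumps(fc, indent=1), encoding="utf-8")


def read_geojson(path) -> list[dict]:
    """Read a FeatureCollection, validating geometry types."""
    try:
        fc = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as e:
        raise ParseError(f"{path}: invalid JSON at line {e.lineno}: {e.msg}") from e
    if fc.get("type") != "FeatureCollection":
        raise ParseError(f"{path}: not a FeatureCollection")
    feats = fc.get("features", [])
    for i, f in enumerate(feats):
        if "geometry" not in f:
            raise ParseError(f"{path}: feature {i} has no geometry")
        _check_geometry(f["geometry"], f"{path}: feature {i}")
    return feats


def write_sectors_geojson(path, sector_map: SectorMap) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": mapping(poly),
            "properties": {"sector_id": sid, "ses_label": label},
        }
        for sid, poly, label in sector_map.sectors
    ]
    write_geojson(path, feats)


def read_sectors_geojson(path) -> SectorMap:
    from shapely.geometry import box

    feats = read_geojson(path)
    sectors = [
        (
            int(f["properties"]["sector_id"]),
            shape(f["geometry"]),
            f["properties"]["ses_label"],
        )
        for f in feats
    ]
    if len({sid for sid, _, _ in sectors}) != len(sectors):
        raise ParseError(f"{path}: duplicate sector ids")
    minx, miny, maxx, maxy = np.array(
        [p.bounds for _, p, _ in sectors]
    ).T.reshape(4, -1)
    boundary = box(minx.min(), miny.min(), maxx.max(), maxy.max())
    return SectorMap(sectors=sectors, city_boundary=boundary)


def write_facilities_geojson(path, layer: FacilityLayer) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": mapping(g),
            "properties": {"category": layer.category},
        }
        for g in layer.geometries
    ]
    write_geojson(path, feats)


def read_facilities_geojson(path, category: str | None = None) -> FacilityLayer:
    feats = read_geojson(path)
    if not feats:
        raise ParseError(f"{path}: facility file contains no features")
    cat = category or feats[0]["properties"].get("category")
    return FacilityLayer(
        category=cat, geometries=[shape(f["geometry"]) for f in feats]
    )


# ---------------------------------------------------------------------------
# ESRI ASCII grid


def write_asc(path, raster: Raster) -> None:
    """Write a raster as an ESRI ASCII grid (north row first)."""
    g = raster.grid
    vals = np.where(np.isnan(raster.values), NODATA, raster.values)
    header = (
        f"ncols {g.n_cols}\n"
        f"nrows {g.n_rows}\n"
        f"xllcorner {g.origin_x_m:.10g}\n"
        f"yllcorner {g.origin_y_m:.10g}\n"
        f"cellsize {g.cell_size_m:.10g}\n"
        f"NODATA_value {NODATA:.10g}\n"
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        np.savetxt(fh, vals[::-1], fmt="%.10g")


def read_asc(path) -> Raster:
    """Read an ESRI ASCII grid; NODATA cells become NaN."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    header: dict[str, float] = {}
    expected = ["ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"]
    for i, key in enumerate(expected):
        if i >= len(lines):
            raise ParseError(f"{path}: truncated header at line {i + 1}")
        parts = lines[i].split()
        if len(parts) != 2 or parts[0].lower() != key:
            raise ParseError(
                f"{path}: line {i + 1}: expected '{key} <value>', got {lines[i]!r}"
            )
        try:
            header[key] = float(parts[1])
        except ValueError as e:
            raise ParseError(f"{path}: line {i + 1}: non-numeric value") from e
    try:
        values = np.loadtxt(lines[6:], ndmin=2)
    except ValueError as e:
        raise ParseError(f"{path}: bad data row after header: {e}") from e
    grid = RasterGrid(
        origin_x_m=header["xllcorner"],
        origin_y_m=header["yllcorner"],
        cell_size_m=header["cellsize"],
        n_cols=int(header["ncols"]),
        n_rows=int(header["nrows"]),
    )
    if values.shape != (grid.n_rows, grid.n_cols):
        raise ParseError(
            f"{path}: data shape {values.shape} does not match header "
            f"({grid.n_rows} rows x {grid.n_cols} cols)"
        )
    values = values[::-1]
    values = np.where(values == header["nodata_value"], np.nan, values)
    return Raster(grid, values)


# ---------------------------------------------------------------------------
# CSV


def write_cohort_csv(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False, columns=[c for c in COHORT_COLUMNS if c in table])


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns and c != "planted_category"]
    if missing:
        raise ParseError(f"{path}: cohort CSV missing columns {missing}")
    return df
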