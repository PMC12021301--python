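"""Euclidean proximity scoring of urban facility layers.

The accessibility model is deliberately simple and mirrors common
desk-GIS practice: for each facility category a planar Euclidean
distance field is computed over a regular grid, the field is classified
into three concentric proximity bands (close / medium / distant, scored
3 / 2 / 1), and the seven per-category score rasters are summed into an
urban quality index ranging from 7 (poor access to everything) to 21
(close to everything).

All coordinates are planar metres; geographic (lat/lon) input is not
supported and must be projected upstream.  Row 0 of every raster is the
*southernmost* row and cell (row, col) has its centre at
``origin + (col + 0.5, row + 0.5) * cell_size`` — a fixed convention
shared by every raster in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry
from shapely.strtree import STRtree

#: The seven facility categories, in canonical order.
CATEGORIES: tuple[str, ...] = (
    "vegetables_fruit_shops",
    "senior_centers",
    "pharmacies",
    "emergency_health_centers",
    "squares_parks",
    "health_centers",
    "stadiums_sports_fields",
)

#: Human-readable names for reports.
CATEGORY_LABELS: dict[str, str] = {
    "vegetables_fruit_shops": "Vegetables and fruit shops",
    "senior_centers": "Senior centers or communities",
    "pharmacies": "Pharmacies",
    "emergency_health_centers": "Emergency health centers",
    "squares_parks": "Main squares and parks",
    "health_centers": "Family or community health centers",
    "stadiums_sports_fields": "Stadiums and sports fields",
}


class ProximityError(ValueError):
    """Raised for invalid proximity-engine inputs."""


@dataclass(frozen=True)
class RasterGrid:
    """Regular grid in planar metres; row 0 is the southernmost row."""

    origin_x_m: float
    origin_y_m: float
    cell_size_m: float
    n_cols: int
    n_rows: int

    def __post_init__(self) -> None:
        if self.cell_size_m <= 0:
            raise ProximityError("cell_size_m must be positive")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ProximityError("grid must have at least one cell")

    @property
    def width_m(self) -> float:
        return self.n_cols * self.cell_size_m

    @property
    def height_m(self) -> float:
        return self.n_rows * self.cell_size_m

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """(xs, ys) arrays of shape (n_rows, n_cols) with cell centres."""
        xs = self.origin_x_m + (np.arange(self.n_cols) + 0.5) * self.cell_size_m
        ys = self.origin_y_m + (np.arange(self.n_rows) + 0.5) * self.cell_size_m
        return np.meshgrid(xs, ys)

    def locate(self, x, y):
        """Vectorised (row, col) of the cells containing planar points.

        Points exactly on the east/north extent edge are assigned to the
        last cell; points outside the extent raise with the offending
        indices named.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        max_x = self.origin_x_m + self.width_m
        max_y = self.origin_y_m + self.height_m
        bad = (x < self.origin_x_m) | (x > max_x) | (y < self.origin_y_m) | (y > max_y)
        if np.any(bad):
            ids = np.flatnonzero(np.atleast_1d(bad))
            raise ProximityError(
                f"point(s) at positions {ids.tolist()} fall outside the grid extent"
            )
        col = np.clip(
            np.floor((x - self.origin_x_m) / self.cell_size_m).astype(int),
            0,
            self.n_cols - 1,
        )
        row = np.clip(
            np.floor((y - self.origin_y_m) / self.cell_size_m).astype(int),
            0,
            self.n_rows - 1,
        )
        return row, col


@dataclass
class Raster:
    """A grid plus one float value per cell (shape ``(n_rows, n_cols)``)."""

    grid: RasterGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_rows, self.grid.n_cols):
            raise ProximityError(
                f"values shape {self.values.shape} does not match grid "
                f"({self.grid.n_rows}, {self.grid.n_cols})"
            )


# Aliases naming the role a raster plays in the pipeline.
DistanceRaster = Raster
ScoreRaster = Raster
IndexRaster = Raster
DensityRaster = Raster


@dataclass
class FacilityLayer:
    """One facility category as a set of point/polygon geometries (metres).

    The spatial index is built lazily and cached; treat the geometry
    list as immutable after construction.
    """

    category: str
    geometries: list[BaseGeometry] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ProximityError(
                f"unknown facility category {self.category!r}; "
                f"expected one of {list(CATEGORIES)}"
            )
        if not self.geometries:
            raise ProximityError(f"facility layer {self.category!r} is empty")
        self._tree: STRtree | None = None

    def tree(self) -> STRtree:
        if self._tree is None:
            self._tree = STRtree(self.geometries)
        return self._tree


@dataclass(frozen=True)
class BandSpec:
    """Distance break-points and 3/2/1 scores for one facility category.

    ``d < near_break`` scores 3, ``near_break <= d <= far_break`` scores 2
    and ``d > far_break`` scores 1: both break values belong to the middle
    band, matching strict "<" / ">" bounds on the outer bands.
    """

    category: str
    near_break_m: float
    far_break_m: float

    def __post_init__(self) -> None:
        if not 0 < self.near_break_m < self.far_break_m:
            raise ProximityError("band breaks must satisfy 0 < near < far")


#: Per-category default band specifications (metres).
DEFAULT_BANDS: dict[str, BandSpec] = {
    "vegetables_fruit_shops": BandSpec("vegetables_fruit_shops", 300, 600),
    "senior_centers": BandSpec("senior_centers", 500, 1000),
    "pharmacies": BandSpec("pharmacies", 500, 1000),
    "emergency_health_centers": BandSpec("emergency_health_centers", 1000, 2000),
    "squares_parks": BandSpec("squares_parks", 200, 400),
    "health_centers": BandSpec("health_centers", 700, 1400),
    "stadiums_sports_fields": BandSpec("stadiums_sports_fields", 400, 600),
}


# ---------------------------------------------------------------------------
# Distances


def nearest_distance(point, layer: FacilityLayer) -> float:
    """Exact planar distance from ``point`` to the nearest layer geometry.

    ``point`` is an ``(x, y)`` pair or shapely Point.  The distance to a
    polygon is 0 for interior points, else the distance to its boundary.
    """
    p = point if isinstance(point, BaseGeometry) else shapely.Point(point)
    return float(min(p.distance(g) for g in layer.geometries))


def layer_distances(xs: np.ndarray, ys: np.ndarray, layer: FacilityLayer) -> np.ndarray:
    """Vectorised nearest distances from many points to a layer."""
    pts = shapely.points(np.asarray(xs, float), np.asarray(ys, float))
    flat = pts.ravel()
    tree = layer.tree()
    idx = tree.nearest(flat)
    geoms = np.asarray(layer.geometries, dtype=object)
    d = shapely.distance(flat, geoms[idx])
    return d.reshape(np.shape(pts))


def distance_field(grid: RasterGrid, layer: FacilityLayer) -> DistanceRaster:
    """Distance raster: nearest distance evaluated at every cell centre."""
    xs, ys = grid.cell_centres()
    return Raster(grid, layer_distances(xs, ys, layer))


# ---------------------------------------------------------------------------
# Band classification and the summary index


def band_score(d, spec: BandSpec):
    """Score a distance (or array of distances) into the 3/2/1 bands."""
    arr = np.asarray(d, dtype=float)
    if np.any(arr < 0):
        raise ProximityError("distances must be nonnegative")
    out = np.where(arr < spec.near_break_m, 3, np.where(arr <= spec.far_break_m, 2, 1))
    if np.isscalar(d) or np.ndim(d) == 0:
        return int(out)
    return out


def classify_raster(d: DistanceRaster, spec: BandSpec) -> ScoreRaster:
    """Cellwise band classification of a distance raster."""
    return Raster(d.grid, band_score(d.values, spec))


def summary_index(scores: list[ScoreRaster]) -> IndexRaster:
    """Cellwise sum of the seven per-category score rasters (range 7–21)."""
    if len(scores) != len(CATEGORIES):
        raise ProximityError(
            f"summary index needs exactly {len(CATEGORIES)} score rasters, "
            f"got {len(scores)}"
        )
    grid = scores[0].grid
    for s in scores[1:]:
        if s.grid != grid:
            raise ProximityError("score rasters are not on a common grid")
    return Raster(grid, np.sum([s.values for s in scores], axis=0))


def sample_raster(r: Raster, points) -> np.ndarray:
    """Raster values at the cells containing each point (no interpolation)."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    row, col = r.grid.locate(pts[:, 0], pts[:, 1])
    return r.values[row, col]
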