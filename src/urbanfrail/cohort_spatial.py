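"""Per-participant environmental exposures.

Joins each participant's residence to (a) the sector/cluster polygon
containing it, (b) the exact nearest distance to each of the seven
facility categories, (c) the urban quality summary index of the raster
cell at the residence, and (d) the population density there.  The
resulting exposure table is the single input of the statistical layer.

Cluster boundary points are resolved to the lowest-id covering sector;
points in no sector get the sentinel ``UNASSIGNED`` (-1), are kept in
the table (and in distance/density comparisons) but are excluded from
cluster-stratified outputs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import shapely

from .proximity import (
    CATEGORIES,
    DensityRaster,
    FacilityLayer,
    IndexRaster,
    layer_distances,
    sample_raster,
)

logger = logging.getLogger(__name__)

#: Sentinel cluster id for residences outside every sector polygon.
UNASSIGNED = -1

EXPOSURE_COLUMNS = (
    ["participant_id", "cluster_id"]
    + [f"dist_{c}_m" for c in CATEGORIES]
    + ["index_value", "density", "category"]
)


class ExposureError(ValueError):
    """Raised for inconsistent exposure-table inputs."""


def assign_clusters(points, sector_map) -> np.ndarray:
    """Vectorised sector/cluster assignment for an array of (x, y) points.

    Boundary points (covered by more than one polygon) get the lowest
    sector id; points covered by none get ``UNASSIGNED``.
    """
    pts = shapely.points(np.asarray(points, dtype=float).reshape(-1, 2))
    out = np.full(len(pts), UNASSIGNED, dtype=int)
    for sid, poly, _label in sorted(sector_map.sectors, key=lambda s: s[0]):
        mask = (out == UNASSIGNED) & shapely.covers(poly, pts)
        out[mask] = sid
    return out


def assign_cluster(point, sector_map) -> int:
    """Cluster id of the sector containing a single point."""
    return int(assign_clusters([point], sector_map)[0])


def density_at(point, surface: DensityRaster) -> float:
    """Population density (persons/m^2) at a point: nearest-cell lookup."""
    return float(sample_raster(surface, [point])[0])


def build_exposure_table(
    cohort_table: pd.DataFrame,
    frailty_table: pd.DataFrame,
    sector_map,
    layers: list[FacilityLayer],
    index: IndexRaster,
    density: DensityRaster,
) -> pd.DataFrame:
    """Assemble one exposure record per participant.

    ``cohort_table`` must carry ``id``, ``x_m``, ``y_m`` columns (the
    cohort CSV schema); ``frailty_table`` is indexed by the same ids and
    carries ``category``.  Distances are vector-exact (not raster
    sampled).  The result is sorted by participant id so the table is
    invariant to input ordering.
    """
    if len(layers) != len(CATEGORIES):
        raise ExposureError(f"expected {len(CATEGORIES)} facility layers, got {len(layers)}")
    by_cat = {l.category: l for l in layers}
    missing = set(CATEGORIES) - set(by_cat)
    if missing:
        raise ExposureError(f"missing facility layers: {sorted(missing)}")

    cohort_ids = pd.Index(cohort_table["id"])
    if not cohort_ids.is_unique:
        dupes = cohort_ids[cohort_ids.duplicated()].unique().tolist()
        raise ExposureError(f"duplicate participant ids: {dupes}")
    unmatched = cohort_ids.difference(frailty_table.index)
    if len(unmatched):
        raise ExposureError(
            f"participants missing from the frailty table: {unmatched.tolist()}"
        )

    ct = cohort_table.sort_values("id").reset_index(drop=True)
    xs = ct["x_m"].to_numpy(float)
    ys = ct["y_m"].to_numpy(float)

    rec = {"participant_id": ct["id"].to_numpy(), "cluster_id": assign_clusters(np.column_stack([xs, ys]), sector_map)}
    n_un = int((rec["cluster_id"] == UNASSIGNED).sum())
    if n_un:
        logger.warning(
            "%d participant(s) fall outside every sector; kept with cluster_id=%d "
            "and excluded from cluster-stratified tables",
            n_un,
            UNASSIGNED,
        )
    for cat in CATEGORIES:
        rec[f"dist_{cat}_m"] = layer_distances(xs, ys, by_cat[cat])
    rec["index_value"] = sample_raster(index, np.column_stack([xs, ys]))
    rec["density"] = sample_raster(density, np.column_stack([xs, ys]))
    rec["category"] = frailty_table.loc[ct["id"], "category"].to_numpy()
    return pd.DataFrame(rec, columns=EXPOSURE_COLUMNS)
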