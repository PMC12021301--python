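"""Shared fixtures: one synthetic city per session plus derived products."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from urbanfrail import (
    CityConfig,
    CohortConfig,
    cohort_frailty_table,
    generate_city,
    generate_cohort,
)
from urbanfrail.cohort_spatial import build_exposure_table
from urbanfrail.proximity import (
    CATEGORIES,
    DEFAULT_BANDS,
    classify_raster,
    distance_field,
    summary_index,
)


@pytest.fixture(scope="session")
def city():
    """(sectors, facilities, density) for the default 10 km city, seed 1."""
    return generate_city(CityConfig(seed=1))


@pytest.fixture(scope="session")
def small_grid_city():
    """A coarse 2.5 km city (100x100 cells at 25 m) for raster-heavy tests."""
    cfg = CityConfig(
        extent_m=(2500.0, 2500.0),
        cell_size_m=25.0,
        facility_counts={
            "vegetables_fruit_shops": 20,
            "senior_centers": 10,
            "pharmacies": 8,
            "emergency_health_centers": 3,
            "squares_parks": 30,
            "health_centers": 4,
            "stadiums_sports_fields": 8,
        },
        seed=3,
    )
    return cfg, generate_city(cfg)


@pytest.fixture(scope="session")
def cohort(city):
    sectors, facilities, density = city
    return generate_cohort(CohortConfig(seed=2), sectors, facilities, density)


@pytest.fixture(scope="session")
def frailty_table(cohort):
    return cohort_frailty_table(cohort.assessments, ids=cohort.table["id"].tolist())


@pytest.fixture(scope="session")
def index_raster(small_grid_city):
    cfg, (sectors, facilities, density) = small_grid_city
    scores = [
        classify_raster(distance_field(cfg.grid(), layer), DEFAULT_BANDS[layer.category])
        for layer in facilities
    ]
    return summary_index(scores)


@pytest.fixture(scope="session")
def default_index(city):
    """Urban quality index raster of the default 10 km city."""
    _, facilities, _ = city
    grid = CityConfig().grid()
    scores = [
        classify_raster(distance_field(grid, layer), DEFAULT_BANDS[layer.category])
        for layer in facilities
    ]
    return summary_index(scores)


@pytest.fixture(scope="session")
def exposure(city, cohort, frailty_table, default_index):
    sectors, facilities, density = city
    return build_exposure_table(
        cohort.table, frailty_table, sectors, facilities, default_index, density
    )


def brute_force_point_distances(xs, ys, pts: np.ndarray) -> np.ndarray:
    """Independent nearest-distance oracle for point layers (pure numpy)."""
    q = np.column_stack([np.ravel(xs), np.ravel(ys)])
    d = np.sqrt(((q[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)).min(axis=1)
    return d.reshape(np.shape(xs))
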