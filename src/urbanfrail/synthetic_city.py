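"""Synthetic city and cohort generator.

Emulates a mid-sized Chilean city and a geocoded cohort of older adults
so the whole classify → score → compare pipeline can be exercised and
tested without any external data:

* six space-filling sectors (seeded Voronoi cells of well-separated
  generator points) carrying socioeconomic labels, with the
  "historic-center" sector anchored near the city centre;
* seven facility layers whose default counts were chosen once so that
  nearest-distance magnitudes match a compact city (shops a few hundred
  metres away, emergency health centres one to two kilometres);
* a smooth population-density surface (one Gaussian bump per sector,
  persons/m^2, sector means spanning roughly 0.008–0.015);
* a cohort with *planted* frailty–environment associations: frailty
  probability shifted by sector socioeconomic stratum, and frail
  residences tilted toward (or away from) chosen facility categories
  and toward denser areas by a calibrated exponential tilt, so the
  requested mean shifts hold in expectation.

Measurements are generated *conditionally on the planted category*
(category first, measurements second): flagged components are drawn
beyond their cut-offs and the flag count matches the category band, so
the phenotype classifier recovers the planted category by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
from scipy.optimize import brentq, minimize
from scipy.special import logsumexp
from scipy.stats import truncnorm
from shapely.geometry import MultiPoint, Point, Polygon, box
from shapely.ops import voronoi_diagram

from .cohort_spatial import assign_clusters
from .frailty import ParticipantAssessment
from .proximity import (
    CATEGORIES,
    DensityRaster,
    FacilityLayer,
    Raster,
    RasterGrid,
    layer_distances,
    sample_raster,
)

SES_LABELS = (
    "high",
    "low",
    "lower-middle",
    "historic-center",
    "medium-high",
    "industrial",
)

CATEGORY_ORDER = ("robust", "prefrail", "frail")

#: Default facility counts for a 10 km x 10 km city.  Chosen once from the
#: Poisson nearest-neighbour relation E[d] ~ 0.5 / sqrt(count / area) so
#: that typical nearest distances sit at the magnitudes a compact city
#: shows: shops and parks a few hundred metres, emergency centres
#: 1-2 km (with between-resident spread of several hundred metres).
DEFAULT_FACILITY_COUNTS: dict[str, int] = {
    "vegetables_fruit_shops": 300,
    "senior_centers": 130,
    "pharmacies": 100,
    "emergency_health_centers": 20,
    "squares_parks": 500,
    "health_centers": 25,
    "stadiums_sports_fields": 120,
}

#: Fraction of each category drawn from the central (historic-center)
#: Gaussian rather than uniformly: commerce clusters downtown.
_CENTRALITY: dict[str, float] = {
    "vegetables_fruit_shops": 0.6,
    "senior_centers": 0.4,
    "pharmacies": 0.6,
    "emergency_health_centers": 0.5,
    "squares_parks": 0.3,
    "health_centers": 0.4,
    "stadiums_sports_fields": 0.2,
}

#: Default Gaussian-bump amplitudes (persons/m^2) per sector label.  The
#: surface is a pure sum of bumps (no constant term), so scaling every
#: amplitude scales every cell.
DEFAULT_DENSITY_AMPLITUDES: dict[str, float] = {
    "high": 0.005,
    "low": 0.013,
    "lower-middle": 0.010,
    "historic-center": 0.009,
    "medium-high": 0.006,
    "industrial": 0.004,
}


class ConfigError(ValueError):
    """Raised for invalid generator configuration."""


class GenerationError(RuntimeError):
    """Raised when a planted effect cannot be realised."""


@dataclass(frozen=True)
class CityConfig:
    """Geometry and facility-layout parameters of the synthetic city."""

    extent_m: tuple[float, float] = (10_000.0, 10_000.0)
    cell_size_m: float = 25.0
    n_sectors: int = 6
    sector_ses_labels: tuple[str, ...] = SES_LABELS
    facility_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_FACILITY_COUNTS)
    )
    density_amplitudes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DENSITY_AMPLITUDES)
    )
    seed: int = 0

    def validate(self) -> None:
        w, h = self.extent_m
        if w <= 0 or h <= 0:
            raise ConfigError("extent must be positive")
        if self.cell_size_m <= 0:
            raise ConfigError("cell_size_m must be positive")
        # the grid must tile the extent to within one cell of rounding
        for dim in (w, h):
            n = round(dim / self.cell_size_m)
            if n < 1 or abs(n * self.cell_size_m - dim) > self.cell_size_m:
                raise ConfigError("cell_size_m does not divide the extent")
        if self.n_sectors != len(self.sector_ses_labels):
            raise ConfigError(
                f"{self.n_sectors} sectors but {len(self.sector_ses_labels)} SES labels"
            )
        if len(set(self.sector_ses_labels)) != len(self.sector_ses_labels):
            raise ConfigError("sector SES labels must be unique")
        for cat in CATEGORIES:
            if self.facility_counts.get(cat, 0) < 1:
                raise ConfigError(
                    f"facility category {cat!r} needs a positive count "
                    "(the summary index requires all 7 layers)"
                )

    def grid(self) -> RasterGrid:
        w, h = self.extent_m
        return RasterGrid(
            0.0, 0.0, self.cell_size_m,
            int(round(w / self.cell_size_m)), int(round(h / self.cell_size_m)),
        )


@dataclass(frozen=True)
class CohortConfig:
    """Cohort size, composition and planted frailty–environment effects.

    ``proximity_effect_m`` maps facility category to the planted mean
    shift (metres) in residence-to-facility distance for frail versus
    nonfrail participants; negative means frail live closer.
    ``density_effect`` is the planted elevation (persons/m^2) of density
    at frail residences.  ``ses_frailty_log_odds`` adds to the frail
    log-odds per sector label (re-centred so the citywide category
    marginals stay at ``category_fractions``).
    """

    n_participants: int = 251
    frac_women: float = 0.745
    category_fractions: tuple[float, float, float] = (0.36, 0.48, 0.16)
    ses_frailty_log_odds: dict[str, float] = field(
        default_factory=lambda: {
            "high": -0.6,
            "low": 0.1,
            "lower-middle": 1.0,
            "historic-center": 0.0,
            "medium-high": 0.3,
            "industrial": -0.3,
        }
    )
    proximity_effect_m: dict[str, float] = field(
        default_factory=lambda: {
            "vegetables_fruit_shops": 60.0,
            "senior_centers": -68.0,
            "emergency_health_centers": -400.0,
            "squares_parks": -50.0,
            "stadiums_sports_fields": -140.0,
        }
    )
    density_effect: float = 0.003
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 3:
            raise ConfigError("need at least 3 participants")
        if not 0 <= self.frac_women <= 1:
            raise ConfigError("frac_women must be in [0, 1]")
        f = np.asarray(self.category_fractions, dtype=float)
        if np.any(f < 0) or np.any(f > 1) or abs(f.sum() - 1) > 1e-9:
            raise ConfigError("category_fractions must be in [0,1] and sum to 1")
        for cat in self.proximity_effect_m:
            if cat not in CATEGORIES:
                raise ConfigError(f"unknown facility category {cat!r}")


@dataclass
class SectorMap:
    """Six labelled polygons partitioning the city extent."""

    sectors: list[tuple[int, Polygon, str]]  # (id 1..n, polygon, ses_label)
    city_boundary: Polygon
    generators: list[Point] = field(default_factory=list)

    def polygon(self, sector_id: int) -> Polygon:
        for sid, poly, _ in self.sectors:
            if sid == sector_id:
                return poly
        raise KeyError(sector_id)

    def label(self, sector_id: int) -> str:
        for sid, _, lab in self.sectors:
            if sid == sector_id:
                return lab
        raise KeyError(sector_id)


# ---------------------------------------------------------------------------
# Sectors


def generate_sectors(config: CityConfig) -> SectorMap:
    """Partition the extent into labelled Voronoi sectors.

    Generator points are drawn with a minimum mutual separation of a
    quarter of the smaller extent dimension (so no sliver sectors); the
    point for the "historic-center" label is drawn from the central
    third of the extent.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    w, h = config.extent_m
    boundary = box(0, 0, w, h)
    min_sep = 0.25 * min(w, h)

    labels = list(config.sector_ses_labels)
    try:
        centre_idx = labels.index("historic-center")
    except ValueError:
        centre_idx = None

    pts: list[np.ndarray] = []
    for i in range(config.n_sectors):
        for _attempt in range(10_000):
            if i == centre_idx:
                cand = np.array([w, h]) * (1 / 3) + rng.random(2) * np.array([w, h]) / 3
            else:
                cand = rng.random(2) * np.array([w, h])
            if all(np.hypot(*(cand - p)) >= min_sep for p in pts):
                pts.append(cand)
                break
        else:  # pragma: no cover - separation always feasible for 6 points
            raise GenerationError("could not place separated sector generators")

    generators = [Point(p) for p in pts]
    cells = voronoi_diagram(MultiPoint(generators), envelope=boundary)
    sectors: list[tuple[int, Polygon, str]] = []
    for i, g in enumerate(generators):
        cell = next(c for c in cells.geoms if c.contains(g))
        sectors.append((i + 1, cell.intersection(boundary), labels[i]))
    return SectorMap(sectors=sectors, city_boundary=boundary, generators=generators)


# ---------------------------------------------------------------------------
# Facilities


def _sample_points_in(
    rng: np.random.Generator,
    n: int,
    boundary: Polygon,
    centre: np.ndarray,
    sigma: float,
    frac_central: float,
) -> np.ndarray:
    """n points: mixture of a central Gaussian and a uniform over the box."""
    minx, miny, maxx, maxy = boundary.bounds
    out = np.empty((n, 2))
    got = 0
    while got < n:
        m = 4 * (n - got)
        central = rng.random(m) < frac_central
        cand = np.where(
            central[:, None],
            centre + rng.standard_normal((m, 2)) * sigma,
            np.column_stack(
                [rng.uniform(minx, maxx, m), rng.uniform(miny, maxy, m)]
            ),
        )
        inside = shapely.contains_xy(boundary, cand[:, 0], cand[:, 1])
        cand = cand[inside]
        take = min(len(cand), n - got)
        out[got : got + take] = cand[:take]
        got += take
    return out


def generate_facilities(config: CityConfig, sectors: SectorMap) -> list[FacilityLayer]:
    """Seven facility layers with sector-weighted inhomogeneous placement.

    Commercial categories concentrate around the historic-center
    sector's generator point.  Squares and parks are small square
    polygons (clipped to the boundary); the other six categories are
    point layers.  The returned list follows the canonical category
    order.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    boundary = sectors.city_boundary
    w, h = config.extent_m
    try:
        centre_pt = next(
            g for (sid, _p, lab), g in zip(sectors.sectors, sectors.generators)
            if lab == "historic-center"
        )
        centre = np.array([centre_pt.x, centre_pt.y])
    except StopIteration:
        centre = np.array([w / 2, h / 2])
    sigma = min(w, h) / 6

    layers: list[FacilityLayer] = []
    for cat in CATEGORIES:
        n = config.facility_counts[cat]
        pts = _sample_points_in(rng, n, boundary, centre, sigma, _CENTRALITY[cat])
        if cat == "squares_parks":
            sides = rng.uniform(40.0, 120.0, n)
            geoms = []
            for (x, y), s in zip(pts, sides):
                poly = box(x - s / 2, y - s / 2, x + s / 2, y + s / 2).intersection(
                    boundary
                )
                geoms.append(poly if not poly.is_empty else Point(x, y))
        else:
            geoms = [Point(x, y) for x, y in pts]
        layers.append(FacilityLayer(category=cat, geometries=geoms))
    return layers


# ---------------------------------------------------------------------------
# Population surface


def generate_population_surface(
    config: CityConfig, sectors: SectorMap
) -> DensityRaster:
    """Smooth density surface: one Gaussian bump per sector centroid.

    Cell value = sum over sectors of amplitude * exp(-r^2 / (2 sigma^2))
    with sigma set to the sector's equivalent radius, in persons/m^2.
    The surface is linear in the amplitudes and strictly positive.
    """
    config.validate()
    grid = config.grid()
    xs, ys = grid.cell_centres()
    values = np.zeros_like(xs)
    for _sid, poly, label in sectors.sectors:
        amp = config.density_amplitudes.get(label, 0.0)
        cx, cy = poly.centroid.x, poly.centroid.y
        sigma = np.sqrt(poly.area / np.pi)
        r2 = (xs - cx) ** 2 + (ys - cy) ** 2
        values += amp * np.exp(-r2 / (2 * sigma**2))
    return Raster(grid, values)


# ---------------------------------------------------------------------------
# Cohort


@dataclass
class SyntheticCohort:
    """Generated cohort: tabular form plus typed assessments."""

    table: pd.DataFrame  # cohort CSV schema, one row per participant
    assessments: list[ParticipantAssessment]

    @property
    def residences(self) -> np.ndarray:
        return self.table[["x_m", "y_m"]].to_numpy(float)


def _sector_category_probs(
    cfg: CohortConfig, labels_by_sid: dict[int, str], sector_weights: dict[int, float]
) -> dict[int, np.ndarray]:
    """Per-sector (robust, prefrail, frail) probabilities.

    The per-sector frail log-odds offsets are re-centred by a global
    constant so that the sector-weight-averaged frail probability equals
    the configured frail fraction.
    """
    base = np.log(np.clip(np.asarray(cfg.category_fractions, float), 1e-12, None))
    etas = {sid: cfg.ses_frailty_log_odds.get(lab, 0.0) for sid, lab in labels_by_sid.items()}

    def mean_frail(c: float) -> float:
        tot = 0.0
        for sid, wgt in sector_weights.items():
            logit = base.copy()
            logit[2] += etas[sid] + c
            p = np.exp(logit - logsumexp(logit))
            tot += wgt * p[2]
        return tot - cfg.category_fractions[2]

    if all(abs(e) < 1e-12 for e in etas.values()):
        c0 = 0.0
    else:
        c0 = brentq(mean_frail, -10.0, 10.0)

    probs = {}
    for sid in labels_by_sid:
        logit = base.copy()
        logit[2] += etas[sid] + c0
        probs[sid] = np.exp(logit - logsumexp(logit))
    return probs


def _calibrate_tilt(
    feats: np.ndarray,
    p_frail: np.ndarray,
    p_nonfrail: np.ndarray,
    targets: np.ndarray,
) -> np.ndarray:
    """Solve for tilt coefficients lambda on standardized features.

    Finds lambda such that the exp(lambda . f)-tilted mean of the
    features under the frail proposal equals the nonfrail mean plus the
    requested shifts — the maximum-entropy distribution with those mean
    constraints.  The objective log sum w_i exp(lambda.(f_i - t)) is
    convex; an unattainable target shows up as an unbounded solution.
    """
    mu_nf = np.average(feats, axis=0, weights=p_nonfrail)
    t = mu_nf + targets
    lo, hi = feats.min(axis=0), feats.max(axis=0)
    if np.any(t <= lo) or np.any(t >= hi):
        raise GenerationError(
            "planted effect is unreachable: target mean outside the support "
            "of the candidate feature distribution"
        )
    w = p_frail / p_frail.sum()
    centred = feats - t

    def obj(lam):
        return logsumexp(centred @ lam, b=w)

    def grad(lam):
        lw = centred @ lam + np.log(w)
        lw -= logsumexp(lw)
        return np.exp(lw) @ centred

    res = minimize(obj, np.zeros(feats.shape[1]), jac=grad, method="BFGS")
    if not res.success or np.any(np.abs(res.x) > 50):
        raise GenerationError(
            f"planted effect calibration failed to converge: {res.message}"
        )
    return res.x


def _draw_measurements(
    rng: np.random.Generator, category: str, sex: str
) -> ParticipantAssessment:
    """Measurements conditional on the planted category.

    The number of flagged components is drawn within the category's band
    (robust: 0, prefrail: 1–2, frail: 3–5) and each measurement is drawn
    clear of its cut-off on the flagged or unflagged side.
    """
    n_flags = {"robust": 0, "prefrail": int(rng.integers(1, 3)), "frail": int(rng.integers(3, 6))}[category]
    flagged = np.zeros(5, dtype=bool)
    flagged[rng.choice(5, size=n_flags, replace=False)] = True
    slow, weak, wloss, exh, lowact = flagged

    gait = rng.uniform(0.30, 0.79) if slow else rng.uniform(0.81, 1.40)
    if sex == "female":
        grip = rng.uniform(6.0, 14.5) if weak else rng.uniform(15.5, 34.0)
    else:
        grip = rng.uniform(10.0, 26.5) if weak else rng.uniform(27.5, 48.0)
    loss = rng.uniform(5.0, 10.0) if wloss else rng.uniform(0.0, 4.5)
    if exh:
        q1 = int(rng.integers(3, 8))
        q2 = int(rng.integers(0, 8))
    else:
        q1, q2 = int(rng.integers(0, 3)), int(rng.integers(0, 3))
    if lowact:
        which = rng.integers(0, 3)  # block / stairs / both
        walk, stairs = which in (0, 2), which in (1, 2)
    else:
        walk = stairs = False
    return ParticipantAssessment(
        sex=sex,
        gait_speed_m_s=round(gait, 3),
        grip_kg=round(grip, 1),
        weight_loss_kg_6mo=round(loss, 1),
        exhaustion_q1=q1,
        exhaustion_q2=q2,
        diff_walk_block=walk,
        diff_climb_stairs=stairs,
    )


_MAX_REJECTION_ATTEMPTS = 10_000  # per participant
_POOL_SIZE = 4000  # candidate pool for calibration


def generate_cohort(
    cfg: CohortConfig,
    sectors: SectorMap,
    facilities: list[FacilityLayer],
    density: DensityRaster,
) -> SyntheticCohort:
    """Generate the cohort with planted frailty–environment associations.

    Residence placement: a participant's frailty category is drawn from
    the citywide category marginals; the residence is then drawn by
    rejection sampling from a density proportional to
    ``P(category | sector(x))`` — times, for frail participants, the
    calibrated exponential tilt on the planted-effect features — so
    sector confounding and the planted mean shifts both hold in
    expectation.  Bounded at 10,000 attempts per participant.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    boundary = sectors.city_boundary
    minx, miny, maxx, maxy = boundary.bounds
    labels_by_sid = {sid: lab for sid, _p, lab in sectors.sectors}
    by_cat = {l.category: l for l in facilities}

    effect_cats = [c for c in CATEGORIES if abs(cfg.proximity_effect_m.get(c, 0.0)) > 0]
    use_density = abs(cfg.density_effect) > 0
    n_feats = len(effect_cats) + int(use_density)

    def features(xy: np.ndarray) -> np.ndarray:
        cols = [layer_distances(xy[:, 0], xy[:, 1], by_cat[c]) for c in effect_cats]
        if use_density:
            cols.append(sample_raster(density, xy))
        return np.column_stack(cols) if cols else np.empty((len(xy), 0))

    # --- candidate pool: uniform over the city, used for calibration
    pool = np.column_stack(
        [rng.uniform(minx, maxx, _POOL_SIZE), rng.uniform(miny, maxy, _POOL_SIZE)]
    )
    pool_sid = assign_clusters(pool, sectors)
    area_w = {
        sid: float((pool_sid == sid).mean()) for sid in labels_by_sid
    }  # empirical sector weights of the uniform proposal
    probs_by_sid = _sector_category_probs(cfg, labels_by_sid, area_w)
    p_cat_pool = np.stack([probs_by_sid[s] for s in pool_sid])  # (M, 3)
    marginal = p_cat_pool.mean(axis=0)

    lam = np.zeros(n_feats)
    scale = np.ones(n_feats)
    if n_feats:
        feats_pool = features(pool)
        scale = feats_pool.std(axis=0)
        scale[scale == 0] = 1.0
        targets = np.array(
            [cfg.proximity_effect_m[c] for c in effect_cats]
            + ([cfg.density_effect] if use_density else [])
        )
        lam = _calibrate_tilt(
            feats_pool / scale,
            p_frail=p_cat_pool[:, 2],
            p_nonfrail=1.0 - p_cat_pool[:, 2],
            targets=targets / scale,
        )
        # rejection envelope for the frail acceptance probability
        log_env = (
            np.log(p_cat_pool[:, 2]) + (feats_pool / scale) @ lam
        ).max() + 0.1

    # --- draw categories for everyone, then residences by rejection
    n = cfg.n_participants
    cat_idx = rng.choice(3, size=n, p=marginal / marginal.sum())
    categories = np.array(CATEGORY_ORDER)[cat_idx]
    max_p = p_cat_pool.max(axis=0)

    def sample_residences(k: int, n_needed: int) -> np.ndarray:
        """Batched rejection sampling from the category-k residence density."""
        got: list[np.ndarray] = []
        n_got = 0
        attempts = 0
        budget = _MAX_REJECTION_ATTEMPTS * n_needed
        while n_got < n_needed:
            m = max(4 * (n_needed - n_got), 256)
            attempts += m
            if attempts > budget:
                raise GenerationError(
                    f"residence rejection sampling exhausted "
                    f"{_MAX_REJECTION_ATTEMPTS} attempts per participant for "
                    f"category {CATEGORY_ORDER[k]!r}; the planted effect may "
                    "be unreachable"
                )
            cand = np.column_stack(
                [rng.uniform(minx, maxx, m), rng.uniform(miny, maxy, m)]
            )
            sid = assign_clusters(cand, sectors)
            u = rng.random(m)  # drawn for every candidate to keep the
            # stream length independent of the acceptance pattern
            ok = sid >= 0
            p = np.where(
                ok, np.stack([probs_by_sid.get(s, np.zeros(3))[k] for s in sid]), 0.0
            )
            if k == 2 and n_feats:
                logp = np.log(np.clip(p, 1e-300, None))
                logp += (features(cand) / scale) @ lam - log_env
                accept_p = np.exp(np.minimum(logp, 0.0))
            else:
                accept_p = p / max_p[k]
            acc = cand[ok & (u < accept_p)]
            got.append(acc)
            n_got += len(acc)
        return np.concatenate(got)[:n_needed]

    xy = np.empty((n, 2))
    for k in range(3):
        slots = np.flatnonzero(cat_idx == k)
        if len(slots):
            xy[slots] = sample_residences(k, len(slots))

    # --- demographics and category-conditional measurements
    sexes = np.where(rng.random(n) < cfg.frac_women, "female", "male")
    a, b = (65.0 - 74.0) / 6.0, (95.0 - 74.0) / 6.0
    ages = truncnorm.rvs(a, b, loc=74.0, scale=6.0, size=n, random_state=rng)
    bmis = rng.lognormal(mean=np.log(29.0), sigma=0.18, size=n)

    assessments = [
        _draw_measurements(rng, categories[i], sexes[i]) for i in range(n)
    ]
    table = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "x_m": np.round(xy[:, 0], 3),
            "y_m": np.round(xy[:, 1], 3),
            "sex": sexes,
            "age": np.round(ages, 1),
            "bmi": np.round(bmis, 1),
            "gait_speed_m_s": [a_.gait_speed_m_s for a_ in assessments],
            "grip_kg": [a_.grip_kg for a_ in assessments],
            "weight_loss_kg_6mo": [a_.weight_loss_kg_6mo for a_ in assessments],
            "exhaustion_q1": [a_.exhaustion_q1 for a_ in assessments],
            "exhaustion_q2": [a_.exhaustion_q2 for a_ in assessments],
            "diff_walk_block": [a_.diff_walk_block for a_ in assessments],
            "diff_climb_stairs": [a_.diff_climb_stairs for a_ in assessments],
            "planted_category": categories,
        }
    )
    return SyntheticCohort(table=table, assessments=assessments)


def generate_city(city_cfg: CityConfig):
    """Convenience: sectors, facilities and density surface in one call."""
    sectors = generate_sectors(city_cfg)
    facilities = generate_facilities(city_cfg, sectors)
    density = generate_population_surface(city_cfg, sectors)
    return sectors, facilities, density


def null_cohort_config(cfg: CohortConfig | None = None, seed: int = 0) -> CohortConfig:
    """A copy of ``cfg`` with every planted effect removed (null model)."""
    base = cfg or CohortConfig()
    return replace(
        base,
        ses_frailty_log_odds={},
        proximity_effect_m={},
        density_effect=0.0,
        seed=seed,
    )
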