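"""Pipeline orchestration: generate → classify → score → analyze.

A single configured, seeded run produces the cohort / frailty /
exposure CSVs, all distance, score, index and density rasters, the
four statistics tables and a JSON manifest (seed, config hash, package
version, warnings).  Identical config + seed gives byte-identical CSV
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort_spatial import build_exposure_table
from .frailty import assessments_from_frame, cohort_frailty_table
from .io import (
    read_asc,
    read_cohort_csv,
    read_facilities_geojson,
    read_sectors_geojson,
    write_asc,
    write_cohort_csv,
    write_facilities_geojson,
    write_sectors_geojson,
)
from .proximity import (
    CATEGORIES,
    BandSpec,
    DEFAULT_BANDS,
    classify_raster,
    distance_field,
    summary_index,
)
from .stats import (
    cluster_distribution_table,
    compare_all_by_frailty,
    sociodemographic_table,
)
from .synthetic_city import CityConfig, CohortConfig, generate_city, generate_cohort

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""


@dataclass
class RunConfig:
    """Everything one reproducible run needs.

    ``inputs`` is either the literal string ``"synthetic"`` (generate
    the whole study from the seeded configs) or a mapping with paths for
    ``sectors`` (GeoJSON), ``facilities`` (directory of
    ``facilities_<category>.geojson``), ``population`` (ASC) and
    ``cohort`` (CSV) — all files or all synthetic, never a mix.
    """

    inputs: str | dict = "synthetic"
    city: CityConfig = field(default_factory=CityConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    bands: dict[str, BandSpec] = field(default_factory=lambda: dict(DEFAULT_BANDS))
    test_policy: str = "auto"  # auto | anova | kw
    seed: int = 0
    outdir: str = "urbanfrail_run"

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(
            self,
            seed=seed,
            city=replace(self.city, seed=seed),
            cohort=replace(self.cohort, seed=seed + 1),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        kwargs: dict = {}
        if "city" in raw:
            kwargs["city"] = CityConfig(**{
                k: tuple(v) if k in ("extent_m", "sector_ses_labels") else v
                for k, v in raw["city"].items()
            })
        if "cohort" in raw:
            c = dict(raw["cohort"])
            if "category_fractions" in c:
                c["category_fractions"] = tuple(c["category_fractions"])
            kwargs["cohort"] = CohortConfig(**c)
        if "bands" in raw:
            kwargs["bands"] = {
                cat: BandSpec(cat, *breaks) for cat, breaks in raw["bands"].items()
            }
        for k in ("inputs", "test_policy", "seed", "outdir"):
            if k in raw:
                kwargs[k] = raw[k]
        cfg = cls(**kwargs)
        return cfg.with_seed(cfg.seed) if "seed" in raw else cfg

    def config_hash(self) -> str:
        d = asdict(self)
        d["bands"] = {k: (v.near_break_m, v.far_break_m) for k, v in self.bands.items()}
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _stage(name):
    """Decorator: re-raise stage failures with the stage name attached."""

    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as e:
                raise PipelineError(f"stage {name!r} failed: {e}") from e

        wrapper.__name__ = fn.__name__
        return wrapper

    return deco


@_stage("generate")
def _load_or_generate(cfg: RunConfig):
    if cfg.inputs == "synthetic":
        sectors, facilities, density = generate_city(cfg.city)
        cohort = generate_cohort(cfg.cohort, sectors, facilities, density)
        return sectors, facilities, density, cohort.table, cohort.assessments
    paths = cfg.inputs
    sectors = read_sectors_geojson(paths["sectors"])
    fac_dir = Path(paths["facilities"])
    facilities = [
        read_facilities_geojson(fac_dir / f"facilities_{cat}.geojson", category=cat)
        for cat in CATEGORIES
    ]
    density = read_asc(paths["population"])
    table = read_cohort_csv(paths["cohort"])
    return sectors, facilities, density, table, assessments_from_frame(table)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest dictionary.

    Artifacts are written under ``cfg.outdir``; the returned manifest
    (also written as ``manifest.json``) records the seed, config hash,
    package version, produced files and any warnings.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []
    produced: list[str] = []

    def save(name: str, writer, *args) -> None:
        writer(out / name, *args)
        produced.append(name)

    sectors, facilities, density, cohort_table, assessments = _load_or_generate(cfg)
    if cfg.inputs == "synthetic":
        save("sectors.geojson", write_sectors_geojson, sectors)
        for layer in facilities:
            save(f"facilities_{layer.category}.geojson", write_facilities_geojson, layer)
        save("population.asc", write_asc, density)
        save("cohort.csv", write_cohort_csv, cohort_table)

    # classify
    try:
        frailty = cohort_frailty_table(assessments, ids=cohort_table["id"].tolist())
    except Exception as e:
        raise PipelineError(f"stage 'classify' failed: {e}") from e
    frailty.to_csv(out / "frailty.csv")
    produced.append("frailty.csv")

    # score
    try:
        grid = cfg.city.grid() if cfg.inputs == "synthetic" else density.grid
        scores = []
        for layer in facilities:
            d = distance_field(grid, layer)
            s = classify_raster(d, cfg.bands[layer.category])
            save(f"distance_{layer.category}.asc", write_asc, d)
            save(f"score_{layer.category}.asc", write_asc, s)
            scores.append(s)
        index = summary_index(scores)
        save("urban_quality_index.asc", write_asc, index)
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(f"stage 'score' failed: {e}") from e

    # exposure
    try:
        exposure = build_exposure_table(
            cohort_table, frailty, sectors, facilities, index, density
        )
    except Exception as e:
        raise PipelineError(f"stage 'exposure' failed: {e}") from e
    exposure.to_csv(out / "exposure.csv", index=False, float_format="%.6f")
    produced.append("exposure.csv")

    # analyze
    try:
        sociodemographic_table(exposure, cohort_table).to_csv(
            out / "table2.csv", index=False
        )
        cluster_distribution_table(exposure).to_csv(out / "table3.csv", index=False)
        comparisons = compare_all_by_frailty(exposure, policy=cfg.test_policy)
        dist_vars = [f"dist_{c}_m" for c in CATEGORIES]
        comparisons[comparisons["variable"].isin(dist_vars)].to_csv(
            out / "figure4_stats.csv", index=False
        )
        comparisons[~comparisons["variable"].isin(dist_vars)].to_csv(
            out / "figure5_stats.csv", index=False
        )
        produced += ["table2.csv", "table3.csv", "figure4_stats.csv", "figure5_stats.csv"]
    except Exception as e:
        raise PipelineError(f"stage 'analyze' failed: {e}") from e

    manifest = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "version": __version__,
        "n_participants": int(len(cohort_table)),
        "score_rasters": [f"score_{c}.asc" for c in CATEGORIES],
        "index_raster": "urban_quality_index.asc",
        "outputs": produced,
        "warnings": warnings,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1), encoding="utf-8")
    return manifest
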