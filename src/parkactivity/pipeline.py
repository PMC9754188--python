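"""End-to-end orchestration: generate -> clip -> filter -> metrics -> stats.

Every stage is deterministic given the config (one master seed is split
into per-stage seeds), so a rerun with the same config reproduces
byte-identical outputs.  The run manifest records the config hash,
library versions and per-stage record counts — the exclusion filter is
the least visible, most consequential step, so retained/excluded cell
counts are logged per property.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__, geo, metrics, stats
from .synth import (
    AnonymizationParams,
    LandscapeConfig,
    SpeciesResponse,
    VisitationParams,
    generate_landscape,
    generate_reservations,
    generate_tree_surveys,
    render_activity_tiles,
    simulate_visitation,
)


class PipelineError(RuntimeError):
    """A user-facing pipeline failure (bad config or missing input)."""


@dataclass
class RunConfig:
    seed: int
    output_dir: str = "out"
    landscape: dict[str, Any] = field(default_factory=dict)
    visitation: dict[str, Any] = field(default_factory=dict)
    anonymization: dict[str, Any] = field(default_factory=dict)
    reservations: dict[str, Any] = field(default_factory=dict)
    tree_surveys: dict[str, Any] | None = None
    night_windows: tuple[int, ...] = (0, 2, 4)
    stratum: str = "all"
    trail_buffer_m: float = 0.0
    n_perm: int = 999

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise PipelineError(f"{path}: config must be a YAML mapping")
        if "seed" not in raw:
            raise PipelineError(f"{path}: config must set an explicit seed")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"{path}: unknown config keys {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.stratum not in ("weekday", "weekend", "all"):
            raise PipelineError("stratum must be weekday, weekend or all")
        cfg.night_windows = tuple(int(w) for w in cfg.night_windows)
        return cfg

    def digest(self) -> str:
        payload = asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()


def _stage_seed(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big")


# ---------------------------------------------------------------------------
# Stage: generate
# ---------------------------------------------------------------------------


def generate_stage(config: RunConfig, out_dir: Path) -> dict[str, int]:
    out_dir.mkdir(parents=True, exist_ok=True)
    landscape = generate_landscape(
        LandscapeConfig(**_tupled(config.landscape)), _stage_seed(config.seed, "landscape")
    )
    vis_params = VisitationParams(**_tupled(config.visitation))
    truth = simulate_visitation(landscape, vis_params, _stage_seed(config.seed, "visitation"))
    anon_cfg = dict(config.anonymization)
    anon_cfg.setdefault("seed", _stage_seed(config.seed, "anonymization"))
    tiles = render_activity_tiles(truth, AnonymizationParams(**anon_cfg))

    geo.write_green_spaces(out_dir / "properties.geojson", landscape.green_spaces)
    geo.write_trails(out_dir / "trails.geojson", landscape.trails)
    geo.write_geojson(
        out_dir / "roads.geojson", ((road, {"kind": "road"}) for road in landscape.roads)
    )
    geo.write_land_cover(out_dir / "land_cover.geojson", landscape.land_cover)
    geo.write_tiles(out_dir / "tiles.csv", tiles)

    reservations = generate_reservations(
        truth,
        _stage_seed(config.seed, "reservations"),
        max_party=int(config.reservations.get("max_party", 6)),
    )
    reservations.to_csv(out_dir / "reservations.csv", index=False)
    truth.daily_visitors.to_csv(out_dir / "truth_daily_visitors.csv", index=False)
    pd.Series(truth.property_activity, name="base_intensity").rename_axis(
        "property_id"
    ).to_csv(out_dir / "truth_property_activity.csv")

    counts = {
        "n_properties": len(landscape.green_spaces),
        "n_grid_cells": len(landscape.grid),
        "n_tile_records": len(tiles),
        "n_reservations": len(reservations),
    }

    if config.tree_surveys is not None:
        ts_cfg = dict(config.tree_surveys)
        effect = SpeciesResponse(
            loadings={str(k): float(v) for k, v in ts_cfg["loadings"].items()},
            years=tuple(int(y) for y in ts_cfg.get("years", (2018, 2019))),
            intercepts={str(k): float(v) for k, v in ts_cfg.get("intercepts", {}).items()},
            year_loading=float(ts_cfg.get("year_loading", 0.0)),
            noise_sd=float(ts_cfg.get("noise_sd", 0.0)),
        )
        trees = generate_tree_surveys(
            landscape, truth, effect, _stage_seed(config.seed, "tree_surveys")
        )
        trees.to_csv(out_dir / "tree_surveys.csv")
        counts["n_tree_rows"] = len(trees)
    return counts


def _tupled(cfg: dict[str, Any]) -> dict[str, Any]:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in cfg.items()}


# ---------------------------------------------------------------------------
# Stage: metrics
# ---------------------------------------------------------------------------


def compute_summaries(
    cells: Sequence[geo.ActivityCell],
    spaces: Sequence[geo.GreenSpace],
    trails: dict[str, list] | None,
    *,
    night_windows: Sequence[int] = (0, 2, 4),
    strata: Sequence[str] = ("all",),
    trail_buffer_m: float = 0.0,
) -> pd.DataFrame:
    """Clip, filter and summarize every property for each requested stratum."""
    rows = []
    night = frozenset(int(w) for w in night_windows)
    for space in spaces:
        clipped = geo.clip_cells(cells, space)
        space_trails = trails.get(space.id, []) if trails is not None else None
        for stratum in strata:
            s = metrics.summarize_property(
                clipped,
                space,
                space_trails,
                night_windows=night,
                stratum=stratum,
                trail_buffer_m=trail_buffer_m,
            )
            rows.append(asdict(s))
    return pd.DataFrame(rows)


def metrics_stage(
    config: RunConfig, out_dir: Path, *, with_trails: bool = True
) -> dict[str, int]:
    tiles_path = out_dir / "tiles.csv"
    props_path = out_dir / "properties.geojson"
    for path, layer in ((tiles_path, "tiles"), (props_path, "properties")):
        if not path.exists():
            raise PipelineError(f"missing input layer '{layer}': {path}")
    cells = geo.read_tiles(tiles_path)
    spaces = geo.read_green_spaces(props_path)
    trails = None
    if with_trails:
        trails_path = out_dir / "trails.geojson"
        if not trails_path.exists():
            raise PipelineError(
                f"missing input layer 'trails': {trails_path} "
                f"(required for on-trail metrics)"
            )
        trails = geo.read_trails(trails_path)
    summaries = compute_summaries(
        cells,
        spaces,
        trails,
        night_windows=config.night_windows,
        strata=("all", "weekday", "weekend"),
        trail_buffer_m=config.trail_buffer_m,
    )
    summaries.to_csv(out_dir / "activity_summary.csv", index=False)
    return {
        "n_summary_rows": len(summaries),
        "n_cells_retained": int(
            summaries.loc[summaries.day_stratum == "all", "n_cells_retained"].sum()
        ),
        "n_cells_excluded": int(
            summaries.loc[summaries.day_stratum == "all", "n_cells_excluded"].sum()
        ),
    }


def landcover_stage(config: RunConfig, out_dir: Path) -> dict[str, int]:
    cover_path = out_dir / "land_cover.geojson"
    if not cover_path.exists():
        raise PipelineError(f"missing input layer 'land_cover': {cover_path}")
    cells = geo.read_tiles(out_dir / "tiles.csv")
    spaces = geo.read_green_spaces(out_dir / "properties.geojson")
    cover = geo.read_land_cover(cover_path)
    rows = []
    night = frozenset(config.night_windows)
    for space in spaces:
        clipped = geo.clip_cells(cells, space)
        flagged = metrics.flag_overnight_cells(clipped, night)
        retained = metrics.drop_flagged(clipped, flagged)
        for usage in metrics.landcover_usage(retained, cover, space):
            rows.append(asdict(usage))
    pd.DataFrame(rows).to_csv(out_dir / "land_cover_usage.csv", index=False)
    return {"n_landcover_rows": len(rows)}


# ---------------------------------------------------------------------------
# Stage: stats
# ---------------------------------------------------------------------------


def stats_stage(config: RunConfig, out_dir: Path) -> dict[str, Any]:
    summary_path = out_dir / "activity_summary.csv"
    if not summary_path.exists():
        raise PipelineError(f"missing input 'activity_summary': {summary_path}")
    summary = pd.read_csv(summary_path, dtype={"property_id": str})
    counts: dict[str, Any] = {}

    res_path = out_dir / "reservations.csv"
    if res_path.exists():
        lm = reservation_validation(summary, pd.read_csv(res_path, dtype={"property_id": str}))
        coef = pd.DataFrame(
            {"estimate": lm.params, "std_error": lm.bse}
        ).rename_axis("term")
        coef.to_csv(out_dir / "lm_reservations_coefficients.csv")
        lm.anova.to_csv(out_dir / "lm_reservations_anova.csv", index=False)
        counts["lm_r_squared"] = lm.r_squared

    trees_path = out_dir / "tree_surveys.csv"
    if trees_path.exists():
        trees = read_tree_surveys(trees_path)
        result, perm = tree_composition_pcca(
            summary, trees, n_perm=config.n_perm, seed=_stage_seed(config.seed, "pcca")
        )
        _write_cca_outputs(out_dir, result, perm)
        counts["pcca_pseudo_f"] = result.pseudo_f
        counts["pcca_p_value"] = perm.p_value
    return counts


def read_tree_surveys(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"site_id": str})
    return df.set_index(["site_id", "year"])


def reservation_validation(
    summary: pd.DataFrame, reservations: pd.DataFrame
) -> stats.LinearModelResult:
    """Regress per-(property, stratum) activity density on reservation
    totals with a weekday/weekend interaction."""
    visitors = (
        reservations.groupby(["property_id", "day_stratum"])["party_size"]
        .sum()
        .rename("visitors")
    )
    strat = summary[summary.day_stratum.isin(["weekday", "weekend"])]
    merged = strat.merge(
        visitors.reset_index(), on=["property_id", "day_stratum"], how="inner"
    ).sort_values(["property_id", "day_stratum"], kind="mergesort")
    if merged.empty:
        raise PipelineError("no overlap between summary properties and reservations")
    return stats.fit_lm_interaction(
        merged["activity_density"].to_numpy(),
        merged["visitors"].to_numpy(),
        (merged["day_stratum"] == "weekend").to_numpy(),
    )


def activity_predictors(summary: pd.DataFrame) -> pd.DataFrame:
    """Per-property constraint matrix: stratum-averaged density, coverage
    and the weekend/weekday density ratio, z-scored per column."""
    wide = summary.pivot_table(
        index="property_id", columns="day_stratum", values="activity_density"
    )
    cov = summary[summary.day_stratum == "all"].set_index("property_id")[
        "activity_coverage_pct"
    ]
    X = pd.DataFrame(
        {
            "activity_density": (wide["weekday"] + wide["weekend"]) / 2.0,
            "activity_coverage": cov,
            "weekend_ratio": wide["weekend"] / wide["weekday"],
        }
    )
    X = X.replace([np.inf, -np.inf], np.nan).dropna()
    sd = X.std(ddof=0)
    sd = sd.replace(0.0, 1.0)
    return (X - X.mean()) / sd


def tree_composition_pcca(
    summary: pd.DataFrame, trees: pd.DataFrame, *, n_perm: int, seed: int
) -> tuple[stats.CcaResult, stats.PermutationTestResult]:
    predictors = activity_predictors(summary)
    sites = trees.index.get_level_values("site_id")
    keep = sites.isin(predictors.index)
    if not keep.any():
        raise PipelineError("no tree-survey sites match summarized properties")
    trees = trees.loc[keep]
    sites = trees.index.get_level_values("site_id")
    X = predictors.loc[sites].to_numpy()
    Z = trees.index.get_level_values("year").to_numpy(dtype=float).reshape(-1, 1)
    result = stats.cca(trees, X, Z)
    perm = stats.permutation_test_cca(trees, X, Z, n_perm=n_perm, seed=seed)
    return result, perm


def _write_cca_outputs(
    out_dir: Path, result: stats.CcaResult, perm: stats.PermutationTestResult
) -> None:
    result.site_scores.rename_axis("site").to_csv(out_dir / "pcca_site_scores.csv")
    result.species_scores.rename_axis("species").to_csv(
        out_dir / "pcca_species_scores.csv"
    )
    result.biplot_scores.rename_axis("constraint").to_csv(
        out_dir / "pcca_biplot_scores.csv"
    )
    payload = {
        "total_inertia": result.total_inertia,
        "conditioned_inertia": result.conditioned_inertia,
        "constrained_inertia": result.constrained_inertia,
        "residual_inertia": result.residual_inertia,
        "eigenvalues": list(map(float, result.eigenvalues)),
        "pseudo_f": _nan_none(result.pseudo_f),
        "df_num": result.df_num,
        "df_den": result.df_den,
        "prop_explained_total": _nan_none(result.prop_explained_total),
        "prop_explained_unconditioned": _nan_none(result.prop_explained_unconditioned),
        "adj_r_squared": _nan_none(result.adj_r_squared),
        "permutation_p": perm.p_value,
        "n_perm": perm.n_perm,
    }
    (out_dir / "pcca_summary.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n"
    )


def _nan_none(x: float) -> float | None:
    return None if x is None or (isinstance(x, float) and math.isnan(x)) else float(x)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict[str, Any]:
    """Run every stage in order and write a run manifest.

    Returns the manifest dict.  Reruns with an identical config produce
    byte-identical outputs; inputs are never mutated.
    """
    out = Path(out_dir) if out_dir is not None else Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, Any] = {}
    for name, fn in (
        ("generate", generate_stage),
        ("metrics", metrics_stage),
        ("landcover", landcover_stage),
        ("stats", stats_stage),
    ):
        try:
            stages[name] = fn(config, out)
        except PipelineError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc

    manifest = {
        "config_sha256": config.digest(),
        "versions": _versions(),
        "stages": stages,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest


def _versions() -> dict[str, str]:
    import shapely

    return {
        "parkactivity": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "shapely": shapely.__version__,
    }
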