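"""Multi-stage orchestration: transitions → metrics → quality → gravity →
model, with CSV outputs, a JSON manifest and a plain-text summary report.

The pipeline accepts either a synthetic-scenario request or paths to
existing co-registered land-use rasters (plus DEM and growth zones for the
model stage).  Every stage failure aborts with the stage name and the
underlying cause; outputs are deterministic under fixed seeds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .grids import (
    LandTypeScheme,
    default_scheme,
    read_categorical,
    read_continuous,
    write_categorical,
    write_continuous,
)
from .gravity import center_of_gravity, displacement
from .logistic import (
    LogisticFit,
    build_covariates,
    draw_samples,
    fit_logistic,
    predict_probability_map,
    validate,
)
from .metrics import class_level, landscape_level, metrics_frame
from .quality import default_service_values, quality_series
from .synth import SyntheticConfig, generate_scenario
from .transitions import (
    compute_transition_matrix,
    contribution_and_probability,
    gains_losses_map,
    net_change,
)

__all__ = ["PipelineConfig", "PipelineError", "PipelineResult",
           "run_pipeline", "report_summary"]

log = logging.getLogger("ecoland.pipeline")

ALL_STAGES = ("transitions", "metrics", "quality", "gravity", "model")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    outdir: Path
    scenario: SyntheticConfig | None = None
    landuse_paths: dict[int, str] | None = None
    dem_path: str | None = None
    levels_path: str | None = None
    stages: tuple[str, ...] = ALL_STAGES
    n_samples: int = 2000
    holdout_samples: int = 1000
    sample_seed: int = 0
    stepwise: bool = True
    connectivity: int = 8

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.scenario is None and not self.landuse_paths:
            raise ValueError("need a synthetic scenario or land-use paths")
        if self.landuse_paths:
            missing = [p for p in self._all_paths() if not Path(p).exists()]
            if missing:
                raise FileNotFoundError(f"missing inputs: {missing}")

    def _all_paths(self):
        paths = list((self.landuse_paths or {}).values())
        for p in (self.dem_path, self.levels_path):
            if p:
                paths.append(p)
        return paths


@dataclass
class PipelineResult:
    outdir: Path
    years: list[int]
    transition_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    net_changes: pd.DataFrame | None = None
    gainloss_summary: pd.DataFrame | None = None
    metrics: pd.DataFrame | None = None
    quality: pd.DataFrame | None = None
    gravity_track: pd.DataFrame | None = None
    fit: LogisticFit | None = None
    validation: object | None = None
    class_probabilities: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)


def _load_inputs(config: PipelineConfig, scheme: LandTypeScheme):
    if config.scenario is not None:
        bundle = generate_scenario(config.scenario, scheme)
        return bundle.landuse, bundle.dem, bundle.levels
    landuse = {
        int(y): read_categorical(p, scheme)
        for y, p in config.landuse_paths.items()
    }
    for y, r in landuse.items():
        if r.year is None:
            r.year = y
    dem = read_continuous(config.dem_path) if config.dem_path else None
    levels = (
        read_categorical(config.levels_path,
                         _levels_scheme()) if config.levels_path else None
    )
    return landuse, dem, levels


def _levels_scheme() -> LandTypeScheme:
    return LandTypeScheme(
        tuple((i, f"level {i}", False) for i in range(1, 6))
    )


def run_pipeline(
    config: PipelineConfig,
    scheme: LandTypeScheme | None = None,
) -> PipelineResult:
    """Execute the requested stages over the inputs and write all outputs.

    Produces, per consecutive period: transition area/probability matrices
    with B/C statistics, net changes and gain/loss maps; per date: the
    landscape- and class-level metric report; plus the equivalent-area
    quality series, the ecological-land gravity track, and (if DEM and
    growth levels are available) the fitted transformation model, its
    holdout validation and the probability map for the final date.
    """
    scheme = scheme or default_scheme()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    landuse, dem, levels = _load_inputs(config, scheme)
    years = sorted(landuse)
    if len(years) < 2:
        raise ValueError("pipeline needs at least 2 dates")
    result = PipelineResult(outdir=out, years=years)

    if "transitions" in config.stages:
        log.info("stage transitions: %d periods", len(years) - 1)
        try:
            nets, glrows = [], []
            for y0, y1 in zip(years[:-1], years[1:]):
                tm = compute_transition_matrix(landuse[y0], landuse[y1], scheme)
                B, C = contribution_and_probability(tm)
                tag = f"{y0}_{y1}"
                for name, m in [("areas", tm.areas),
                                ("P", tm.probabilities), ("B", B), ("C", C)]:
                    df = pd.DataFrame(m, index=list(tm.labels),
                                      columns=list(tm.labels))
                    result.transition_tables[f"{name}_{tag}"] = df
                    df.to_csv(out / f"transitions_{name}_{tag}.csv")
                for nc in net_change(tm):
                    nets.append({"period": tag, "class": nc.label,
                                 "area_start_km2": nc.area_start,
                                 "area_end_km2": nc.area_end,
                                 "net_change_km2": nc.change})
                glmap, summary = gains_losses_map(landuse[y0], landuse[y1],
                                                  scheme)
                write_categorical(glmap, out / f"gainloss_{tag}.asc")
                glrows.append({"period": tag, **summary})
            result.net_changes = pd.DataFrame(nets)
            result.net_changes.to_csv(out / "net_changes.csv", index=False)
            result.gainloss_summary = pd.DataFrame(glrows)
            result.gainloss_summary.to_csv(out / "gainloss_summary.csv",
                                           index=False)
        except Exception as exc:
            raise PipelineError("transitions", exc) from exc

    if "metrics" in config.stages:
        log.info("stage metrics: %d dates", len(years))
        try:
            frames = []
            for y in years:
                frames.append(metrics_frame(
                    landscape_level(landuse[y], config.connectivity), year=y))
                present = set(np.unique(
                    landuse[y].values[~landuse[y].mask]))
                for code in scheme.codes:
                    if code in present:
                        frames.append(metrics_frame(
                            class_level(landuse[y], code,
                                        config.connectivity), year=y))
            result.metrics = pd.concat(frames, ignore_index=True)
            result.metrics.to_csv(out / "landscape_metrics.csv", index=False)
        except Exception as exc:
            raise PipelineError("metrics", exc) from exc

    if "quality" in config.stages:
        log.info("stage quality")
        try:
            table = default_service_values()
            result.quality = quality_series(
                [landuse[y] for y in years], table, scheme)
            result.quality.to_csv(out / "quality_series.csv", index=False)
        except Exception as exc:
            raise PipelineError("quality", exc) from exc

    if "gravity" in config.stages:
        log.info("stage gravity")
        try:
            rows = []
            centers = [center_of_gravity(landuse[y], scheme, eco_group=True)
                       for y in years]
            for c in centers:
                rows.append({"year": c.year, "group": c.group,
                             "x": c.x, "y": c.y, "area_km2": c.area_km2,
                             "dx_east_m": np.nan, "dy_north_m": np.nan,
                             "distance_m": np.nan, "octant": ""})
            for i in range(1, len(centers)):
                d = displacement(centers[i - 1], centers[i])
                rows[i].update({"dx_east_m": d.dx_east,
                                "dy_north_m": d.dy_north,
                                "distance_m": d.distance,
                                "octant": d.octant})
            result.gravity_track = pd.DataFrame(rows)
            result.gravity_track.to_csv(out / "gravity_track.csv", index=False)
        except Exception as exc:
            raise PipelineError("gravity", exc) from exc

    if "model" in config.stages:
        log.info("stage model")
        try:
            if dem is None or levels is None:
                raise ValueError("model stage needs a DEM and growth levels")
            y0, y1 = years[0], years[-1]
            stack = build_covariates(dem, landuse[y0], levels)
            train = draw_samples(landuse[y0], landuse[y1], stack, scheme,
                                 config.n_samples, seed=config.sample_seed)
            result.fit = fit_logistic(train, stepwise=config.stepwise)
            holdout = draw_samples(landuse[y0], landuse[y1], stack, scheme,
                                   config.holdout_samples,
                                   seed=config.sample_seed + 1)
            result.validation = validate(result.fit, holdout)
            prob, level_map, classprob = predict_probability_map(
                stack, landuse[y1], scheme,
                result.fit.to_transform_coefficients())
            write_continuous(prob, out / "transform_probability.asc")
            write_categorical(level_map, out / "transform_levels.asc")
            result.class_probabilities = classprob
            classprob.to_csv(out / "class_mean_probability.csv", index=False)
            fitdoc = {
                "intercept": result.fit.intercept,
                "coefficients": result.fit.coefficients,
                "std_errors": result.fit.std_errors,
                "included": result.fit.included,
                "neg2ll": result.fit.neg2ll,
                "lr_chi2": result.fit.lr_chi2,
                "lr_df": result.fit.lr_df,
                "n": result.fit.n,
                "validation": {
                    "matrix": result.validation.matrix.tolist(),
                    "overall_accuracy": result.validation.overall_accuracy,
                    "kappa": result.validation.kappa,
                },
            }
            (out / "logistic_fit.json").write_text(json.dumps(fitdoc, indent=2))
        except Exception as exc:
            raise PipelineError("model", exc) from exc

    result.manifest = {
        "version": __version__,
        "years": years,
        "stages": list(config.stages),
        "sample_seed": config.sample_seed,
        "n_samples": config.n_samples,
        "scenario_seed": (config.scenario.seed
                          if config.scenario is not None else None),
    }
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
    return result


def report_summary(result: PipelineResult) -> str:
    """Assemble a deterministic human-readable report from a result bundle.

    Missing sections (stages not run) are listed at the end.
    """
    lines = ["ecological land assessment summary",
             "=" * 34,
             f"dates: {', '.join(str(y) for y in result.years)}", ""]
    missing = []

    if result.net_changes is not None:
        lines.append("net change per period (km2):")
        for period, grp in result.net_changes.groupby("period", sort=True):
            eco = grp[grp["class"].isin(
                ["woodland", "grassland", "reservoirs and pit ponds",
                 "tidal flats", "rivers and shallow water"])]
            lines.append(
                f"  {period}: ecological net "
                f"{eco['net_change_km2'].sum():+.1f}"
            )
        lines.append("")
    else:
        missing.append("transitions")

    if result.metrics is not None:
        land = result.metrics[result.metrics["level"] == "landscape"]
        lines.append("landscape metrics (per date):")
        for y, grp in land.groupby("year", sort=True):
            vals = {r["metric"]: r["value"] for _, r in grp.iterrows()}
            lines.append(
                f"  {y}: ED={vals['ED']:.1f} PD={vals['PD']:.2f} "
                f"LSI={vals['LSI']:.1f} LPI={vals['LPI']:.1f} "
                f"CONTAG={vals['CONTAG']:.1f} SHDI={vals['SHDI']:.2f} "
                f"SHEI={vals['SHEI']:.2f}"
            )
        lines.append("")
    else:
        missing.append("metrics")

    if result.quality is not None:
        lines.append("equivalent ecological area (km2):")
        for _, r in result.quality.iterrows():
            pct = ("" if pd.isna(r["pct_reduction"])
                   else f"  (reduction {r['pct_reduction']:.1f}%)")
            lines.append(
                f"  {int(r['year'])}: {r['equivalent_area_km2']:.1f}"
                f"  Q={r['average_equivalent_area']:.3f}{pct}"
            )
        lines.append("")
    else:
        missing.append("quality")

    if result.gravity_track is not None:
        lines.append("ecological-land center of gravity:")
        for _, r in result.gravity_track.iterrows():
            move = ("" if pd.isna(r["distance_m"])
                    else f"  moved {r['distance_m']:.0f} m {r['octant']}")
            lines.append(f"  {int(r['year'])}: ({r['x']:.0f}, {r['y']:.0f}){move}")
        lines.append("")
    else:
        missing.append("gravity")

    if result.fit is not None:
        f = result.fit
        lines.append("transformation model:")
        lines.append(f"  variables: {', '.join(f.included)}")
        lines.append(f"  -2LL = {f.neg2ll:.1f}, LR chi2({f.lr_df}) = "
                     f"{f.lr_chi2:.1f}, n = {f.n}")
        if result.validation is not None:
            v = result.validation
            lines.append(
                f"  holdout accuracy {v.overall_accuracy:.1f}% "
                f"(kappa {v.kappa:.3f})"
            )
        if result.class_probabilities is not None:
            for _, r in result.class_probabilities.iterrows():
                lines.append(
                    f"  mean transform probability, {r['class']}: "
                    f"{r['mean_probability']:.3f}"
                )
        lines.append("")
    else:
        missing.append("model")

    if missing:
        lines.append(f"missing sections: {', '.join(missing)}")
    return "\n".join(lines) + "\n"
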