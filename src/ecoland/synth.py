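"""Synthetic multi-date landscapes with the statistical structure the
assessment pipeline assumes.

The generator emulates a coastal urbanizing land system: ten land classes
(five ecological) arranged in spatially cohesive patches, a smooth DEM,
administrative growth zones, and ecological→non-ecological conversion
whose log-odds depend on slope, elevation, distance to built-up land and
the zone's built-up growth level.  Everything is deterministic under the
configured seed.

Default conditions
------------------
The default class proportions mirror the study system's 1991 composition
(ecological share ≈ 0.54, dominated by woodland and rivers/shallow water);
dates are the four mapped years 1991/2000/2010/2018 at 30 m cells.  The
true conversion coefficients are chosen so that conversion is concentrated
on low, flat cells near built-up land in fast-growing zones and the
per-period ecological loss rate falls in the 10–25 % range the observed
transition statistics span.  Grids default to 128×128 cells, a size at
which every downstream stage is exercised in seconds.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import stats

from .grids import (
    BUILTUP_CODE,
    CategoricalRaster,
    ContinuousRaster,
    LandTypeScheme,
    default_scheme,
    write_categorical,
    write_continuous,
)
from .logistic import compute_slope, distance_to_builtup

__all__ = [
    "TrueCoefficients",
    "SyntheticConfig",
    "ScenarioBundle",
    "generate_landscape",
    "generate_dem",
    "generate_zones",
    "simulate_change",
    "generate_scenario",
    "write_scenario",
]


@dataclass(frozen=True)
class TrueCoefficients:
    """Generating coefficients of the conversion log-odds.

    P(convert) = σ(α + β_slope·slope + β_elev·elev + β_dist·dist +
    β_level4·D + β_level5·E).  Signs are the generative converse of the
    persistence model: conversion is less likely on steep, high, remote
    cells and more likely in fast-growing zones.
    """

    intercept: float = -1.0
    slope: float = -0.10      # per degree
    elevation: float = -0.02  # per meter
    distance: float = -0.80   # per km
    level4: float = 1.0
    level5: float = 1.3


_DEFAULT_PROPORTIONS = {
    1: 0.34,   # woodland
    2: 0.02,   # grassland
    3: 0.08,   # rainfed cropland
    4: 0.12,   # paddy fields
    5: 0.08,   # aquaculture areas
    6: 0.02,   # reservoirs and pit ponds
    7: 0.02,   # tidal flats
    8: 0.16,   # rivers and shallow water
    9: 0.14,   # built-up land
    10: 0.02,  # unutilized land
}


@dataclass
class SyntheticConfig:
    shape: tuple[int, int] = (128, 128)
    cell_size: float = 30.0
    proportions: dict[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_PROPORTIONS)
    )
    cohesion: float = 0.95
    coefficients: TrueCoefficients = field(default_factory=TrueCoefficients)
    n_zones: int = 13
    dates: tuple[int, ...] = (1991, 2000, 2010, 2018)
    seed: int = 0
    dem_bumps: int = 6
    dem_amplitude: float = 120.0
    allow_gains: bool = False
    gain_probability: float = 0.0

    def __post_init__(self) -> None:
        if self.shape[0] < 8 or self.shape[1] < 8:
            raise ValueError("grid must be at least 8×8")
        s = sum(self.proportions.values())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"class proportions must sum to 1, got {s}")
        if not 0.0 <= self.cohesion <= 1.0:
            raise ValueError("cohesion must lie in [0, 1]")


def _quotas(proportions: dict[int, float], n: int) -> dict[int, int]:
    """Integer cell quotas per class by largest remainder, summing to n."""
    raw = {c: p * n for c, p in proportions.items()}
    base = {c: int(np.floor(v)) for c, v in raw.items()}
    short = n - sum(base.values())
    order = sorted(raw, key=lambda c: raw[c] - base[c], reverse=True)
    for c in order[:short]:
        base[c] += 1
    return {c: q for c, q in base.items() if q > 0}


def generate_landscape(
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    year: int | None = None,
) -> CategoricalRaster:
    """Cohesive-patch landscape by capacity-constrained multi-seed growth.

    Each class gets a cell quota matching its requested proportion exactly
    (to rounding) and a number of seeds that shrinks as cohesion rises;
    regions grow from the seeds in random order until every quota is
    filled.  ``cohesion = 0`` degenerates to independent per-cell draws.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    nrows, ncols = config.shape
    n = nrows * ncols
    codes = sorted(config.proportions)
    if config.cohesion == 0.0:
        p = np.array([config.proportions[c] for c in codes])
        vals = rng.choice(codes, size=(nrows, ncols), p=p)
        return CategoricalRaster(vals, None, config.cell_size, (0.0, 0.0),
                                 year=year)

    quota = _quotas(config.proportions, n)
    k = len(quota)
    n_seeds = max(k, int(np.ceil(k + (1.0 - config.cohesion) * n / 8.0)))
    # seeds per class proportional to quota, at least one each
    seed_counts = _quotas({c: q / n for c, q in quota.items()},
                          max(n_seeds - k, 0))
    seed_counts = {c: seed_counts.get(c, 0) + 1 for c in quota}

    out = np.zeros((nrows, ncols), dtype=np.int64)
    remaining = dict(quota)
    heap: list[tuple[float, int, int, int]] = []
    flat = rng.choice(n, size=sum(seed_counts.values()), replace=False)
    i = 0
    for c, cnt in seed_counts.items():
        for _ in range(cnt):
            r, q = divmod(int(flat[i]), ncols)
            heapq.heappush(heap, (float(rng.random()), r, q, c))
            i += 1
    while heap:
        _, r, c_, cls = heapq.heappop(heap)
        if out[r, c_] != 0:
            continue
        if remaining.get(cls, 0) == 0:
            cls = max(remaining, key=remaining.get)
            if remaining[cls] == 0:
                break
        out[r, c_] = cls
        remaining[cls] -= 1
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c_ + dc
            if 0 <= rr < nrows and 0 <= cc < ncols and out[rr, cc] == 0:
                heapq.heappush(heap, (float(rng.random()), rr, cc, cls))
    # isolated unassigned cells (exhausted frontier): nearest class with quota
    if (out == 0).any():
        rs, cs = np.nonzero(out == 0)
        for r, c_ in zip(rs, cs):
            cls = max(remaining, key=remaining.get)
            out[r, c_] = cls
            remaining[cls] = max(remaining[cls] - 1, 0)
    return CategoricalRaster(out, None, config.cell_size, (0.0, 0.0), year=year)


def generate_dem(
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> ContinuousRaster:
    """Nonnegative smooth elevation surface: a seeded sum of Gaussian bumps."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    nrows, ncols = config.shape
    z = np.zeros((nrows, ncols))
    rr, cc = np.mgrid[0:nrows, 0:ncols]
    for _ in range(config.dem_bumps):
        r0 = rng.uniform(0, nrows)
        c0 = rng.uniform(0, ncols)
        width = rng.uniform(0.1, 0.25) * min(nrows, ncols)
        amp = rng.uniform(0.4, 1.0) * config.dem_amplitude
        z += amp * np.exp(-(((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * width**2)))
    return ContinuousRaster(z, None, config.cell_size, (0.0, 0.0), units="m")


def generate_zones(
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> tuple[CategoricalRaster, CategoricalRaster]:
    """Voronoi growth zones and their built-up growth levels.

    Returns (zone-id raster, level raster); each zone is the Voronoi cell
    of a random site and carries a growth level 1–5 (every level is
    represented when there are at least five zones).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    nrows, ncols = config.shape
    k = config.n_zones
    sites = np.column_stack(
        [rng.uniform(0, nrows, size=k), rng.uniform(0, ncols, size=k)]
    )
    rr, cc = np.mgrid[0:nrows, 0:ncols]
    d2 = (
        (rr[..., None] - sites[:, 0]) ** 2
        + (cc[..., None] - sites[:, 1]) ** 2
    )
    zone = d2.argmin(axis=2) + 1
    levels_per_zone = np.empty(k, dtype=np.int64)
    base = np.arange(1, 6)
    levels_per_zone[: min(k, 5)] = rng.permutation(base)[: min(k, 5)]
    if k > 5:
        levels_per_zone[5:] = rng.integers(1, 6, size=k - 5)
    level = levels_per_zone[zone - 1]
    zr = CategoricalRaster(zone, None, config.cell_size, (0.0, 0.0))
    lr = CategoricalRaster(level, None, config.cell_size, (0.0, 0.0))
    return zr, lr


def simulate_change(
    landscape_t0: CategoricalRaster,
    dem: ContinuousRaster,
    levels: CategoricalRaster,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    scheme: LandTypeScheme | None = None,
    year: int | None = None,
) -> CategoricalRaster:
    """One conversion step: each ecological cell turns into built-up land
    with the true logistic probability of its covariates.

    Covariates are slope and elevation from the DEM, distance to the t0
    built-up land, and the zone growth-level dummies.  Non-ecological
    cells are unchanged (gains are off unless configured).
    """
    if dem is None or levels is None:
        raise ValueError("missing covariate layer (DEM or growth levels)")
    landscape_t0.require_registration(dem)
    landscape_t0.require_registration(levels)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    scheme = scheme or default_scheme()
    k = config.coefficients
    slope = compute_slope(dem).values
    dist = distance_to_builtup(landscape_t0).values
    lv = levels.values
    z = (
        k.intercept
        + k.slope * slope
        + k.elevation * dem.values
        + k.distance * dist
        + k.level4 * (lv == 4)
        + k.level5 * (lv == 5)
    )
    p_convert = stats.logistic.cdf(z)
    eco = np.isin(landscape_t0.values, scheme.ecological_codes) & ~landscape_t0.mask
    draw = rng.random(landscape_t0.shape)
    out = landscape_t0.values.copy()
    out[eco & (draw < p_convert)] = BUILTUP_CODE
    if config.allow_gains and config.gain_probability > 0:
        noneco = ~eco & ~landscape_t0.mask & (landscape_t0.values != BUILTUP_CODE)
        gain_draw = rng.random(landscape_t0.shape)
        gain_code = scheme.ecological_codes[0]
        out[noneco & (gain_draw < config.gain_probability)] = gain_code
    return CategoricalRaster(out, landscape_t0.mask.copy(),
                             landscape_t0.cell_size, landscape_t0.origin,
                             year=year)


@dataclass
class ScenarioBundle:
    """Self-consistent multi-date bundle: land-use rasters per date, DEM,
    zone and growth-level rasters, and the generating config."""

    landuse: dict[int, CategoricalRaster]
    dem: ContinuousRaster
    zones: CategoricalRaster
    levels: CategoricalRaster
    config: SyntheticConfig

    @property
    def years(self) -> list[int]:
        return sorted(self.landuse)


def generate_scenario(
    config: SyntheticConfig,
    scheme: LandTypeScheme | None = None,
) -> ScenarioBundle:
    """Chain landscape, DEM, zones and per-period conversions for all dates."""
    scheme = scheme or default_scheme()
    root = np.random.default_rng(config.seed)
    r_land, r_dem, r_zone, r_change = root.spawn(4)
    dem = generate_dem(config, r_dem)
    zones, levels = generate_zones(config, r_zone)
    first = generate_landscape(config, r_land, year=config.dates[0])
    landuse = {config.dates[0]: first}
    current = first
    for year in config.dates[1:]:
        current = simulate_change(current, dem, levels, config, r_change,
                                  scheme, year=year)
        landuse[year] = current
    return ScenarioBundle(landuse, dem, zones, levels, config)


def write_scenario(bundle: ScenarioBundle, outdir: str | Path) -> Path:
    """Write the bundle as ASCII-grid rasters plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for year, r in bundle.landuse.items():
        write_categorical(r, outdir / f"landuse_{year}.asc")
    write_continuous(bundle.dem, outdir / "dem.asc")
    write_categorical(bundle.zones, outdir / "zones.asc")
    write_categorical(bundle.levels, outdir / "growth_levels.asc")
    cfg = asdict(bundle.config)
    cfg["proportions"] = {str(k): v for k, v in cfg["proportions"].items()}
    manifest = {
        "seed": bundle.config.seed,
        "config": cfg,
        "files": {
            "landuse": {str(y): f"landuse_{y}.asc" for y in bundle.years},
            "dem": "dem.asc",
            "zones": "zones.asc",
            "growth_levels": "growth_levels.asc",
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir
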