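"""Equivalent ecological area and average-equivalent-area quality scoring.

Each land class carries a normalized ecosystem-service value δ ∈ [0, 1]
(woodland highest at 1.00, built-up lowest at 0.08).  The equivalent
ecological area of a landscape is Σ δ_i·A_i over the included classes and
the average equivalent area Q = Σ δ_i·A_i / Σ A_i, a dimensionless quality
score bounded by the δ of the included classes.  The headline series is
computed over the ecological classes; the all-class variant is also
reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .grids import CategoricalRaster, LandTypeScheme, class_area

__all__ = [
    "ServiceValueTable",
    "EcoQualityResult",
    "default_service_values",
    "equivalent_area",
    "quality_series",
    "percent_reduction",
]

#: Normalized ecosystem-service values of the default 10-class scheme,
#: keyed by class code (same ordering as the scheme).
_DEFAULT_DELTAS = {
    1: 1.00,   # woodland
    2: 0.47,   # grassland
    3: 0.16,   # rainfed cropland
    4: 0.29,   # paddy fields
    5: 0.23,   # aquaculture areas
    6: 0.63,   # reservoirs and pit ponds
    7: 0.72,   # tidal flats
    8: 0.92,   # rivers and shallow water
    9: 0.08,   # built-up land
    10: 0.10,  # unutilized land
}


@dataclass(frozen=True)
class ServiceValueTable:
    """Normalized ecosystem-service value δ per class code."""

    deltas: dict[int, float]

    def __post_init__(self) -> None:
        for c, d in self.deltas.items():
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"delta for class {c} outside [0, 1]: {d}")

    def __getitem__(self, code: int) -> float:
        return self.deltas[code]

    def __contains__(self, code: int) -> bool:
        return code in self.deltas

    @classmethod
    def from_csv(cls, path: str | Path) -> "ServiceValueTable":
        df = pd.read_csv(path)
        return cls({int(r["code"]): float(r["delta"]) for _, r in df.iterrows()})

    def to_csv(self, path: str | Path, scheme: LandTypeScheme | None = None) -> None:
        rows = [
            {
                "code": c,
                "name": scheme.name_of(c) if scheme else "",
                "delta": d,
            }
            for c, d in sorted(self.deltas.items())
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


def default_service_values() -> ServiceValueTable:
    return ServiceValueTable(dict(_DEFAULT_DELTAS))


@dataclass(frozen=True)
class EcoQualityResult:
    year: int | None
    class_areas: dict[int, float]      # A_i, km², included classes only
    equivalent_area: float             # Σ δ_i·A_i, km²
    total_area: float                  # Σ A_i over included classes, km²
    average_equivalent_area: float     # Q
    n_classes: int


def equivalent_area(
    raster: CategoricalRaster,
    table: ServiceValueTable,
    scheme: LandTypeScheme,
    subset: str = "ecological",
) -> EcoQualityResult:
    """Equivalent ecological area and Q of one raster.

    ``subset`` selects which classes enter the score: ``"ecological"``
    (default, the five ecological classes) or ``"all"``.
    """
    if subset not in ("ecological", "all"):
        raise ValueError("subset must be 'ecological' or 'all'")
    codes = scheme.ecological_codes if subset == "ecological" else scheme.codes
    present = set(int(c) for c in
                  raster.values[~raster.mask].ravel()) if raster.n_valid else set()
    missing = [c for c in present if c not in table]
    if missing:
        raise KeyError(f"no service value for present classes: {sorted(missing)}")
    areas = {c: class_area(raster, c, scheme) for c in codes}
    A = sum(areas.values())
    eq = sum(table[c] * a for c, a in areas.items())
    Q = eq / A if A > 0 else float("nan")
    return EcoQualityResult(
        year=raster.year,
        class_areas=areas,
        equivalent_area=eq,
        total_area=A,
        average_equivalent_area=Q,
        n_classes=len(codes),
    )


def percent_reduction(previous: float, current: float) -> float:
    """Period-over-period percentage reduction, (prev − cur)/prev × 100."""
    if previous == 0:
        return float("nan")
    return (previous - current) / previous * 100.0


def quality_series(
    rasters: list[CategoricalRaster],
    table: ServiceValueTable,
    scheme: LandTypeScheme,
    subset: str = "ecological",
) -> pd.DataFrame:
    """Equivalent-area time series with period-over-period % reductions.

    Rasters are sorted by year; the returned frame has one row per date
    with columns year, equivalent_area_km2, total_area_km2,
    average_equivalent_area, and pct_reduction (NaN for the first date,
    reported to one decimal).
    """
    if len(rasters) < 2:
        raise ValueError("quality series needs at least 2 dates")
    if any(r.year is None for r in rasters):
        raise ValueError("all rasters need a year for a time series")
    ordered = sorted(rasters, key=lambda r: r.year)
    results = [equivalent_area(r, table, scheme, subset) for r in ordered]
    rows = []
    for i, res in enumerate(results):
        pct = (
            round(percent_reduction(results[i - 1].equivalent_area,
                                    res.equivalent_area), 1)
            if i > 0 else float("nan")
        )
        rows.append(
            {
                "year": res.year,
                "equivalent_area_km2": res.equivalent_area,
                "total_area_km2": res.total_area,
                "average_equivalent_area": res.average_equivalent_area,
                "pct_reduction": pct,
            }
        )
    return pd.DataFrame(rows)
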