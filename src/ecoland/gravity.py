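"""Area-weighted center of gravity of a land class and its migration.

The center of gravity at date t is the area-weighted mean of the
coordinates of all contributing units, X_t = Σ C_ti·X_i / Σ C_ti (same
for Y).  With equal-area raster cells this is the arithmetic mean of the
contributing cell centers.  Displacements between two dates are reported
as east/north components, Euclidean distance, and an 8-sector compass
octant label (45° sectors centered on the 8 compass directions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .grids import CategoricalRaster, LandTypeScheme

__all__ = ["GravityCenter", "Displacement", "center_of_gravity", "displacement"]


@dataclass(frozen=True)
class GravityCenter:
    x: float
    y: float
    group: str        # class name or "ecological"
    year: int | None
    area_km2: float   # total contributing area


@dataclass(frozen=True)
class Displacement:
    dx_east: float
    dy_north: float
    distance: float
    octant: str


_OCTANTS = ["east", "northeast", "north", "northwest",
            "west", "southwest", "south", "southeast"]


def _octant(dx: float, dy: float) -> str:
    if dx == 0 and dy == 0:
        return "none"
    ang = math.degrees(math.atan2(dy, dx)) % 360.0
    return _OCTANTS[int(((ang + 22.5) % 360) // 45)]


def center_of_gravity(
    raster: CategoricalRaster,
    scheme: LandTypeScheme,
    code: int | None = None,
    eco_group: bool = False,
) -> GravityCenter:
    """Center of gravity of one class, or of all ecological land.

    Pass ``code`` for a single class or ``eco_group=True`` for the union of
    ecological classes.  Raises on zero contributing area (undefined
    center).
    """
    if eco_group:
        sel = np.isin(raster.values, scheme.ecological_codes)
        group = "ecological"
    else:
        if code is None:
            raise ValueError("give a class code or eco_group=True")
        if code not in scheme.codes:
            raise ValueError(f"code {code} not in scheme")
        sel = raster.values == code
        group = scheme.name_of(code)
    sel &= ~raster.mask
    n = int(sel.sum())
    if n == 0:
        raise ValueError(f"zero-area group '{group}': center undefined")
    X, Y = raster.cell_centers()
    return GravityCenter(
        x=float(X[sel].mean()),
        y=float(Y[sel].mean()),
        group=group,
        year=raster.year,
        area_km2=n * raster.cell_size**2 / 1e6,
    )


def displacement(a: GravityCenter, b: GravityCenter) -> Displacement:
    """Migration vector from center *a* to center *b* (meters)."""
    if a.group != b.group:
        raise ValueError(f"mismatched groups: {a.group!r} vs {b.group!r}")
    dx = b.x - a.x
    dy = b.y - a.y
    return Displacement(
        dx_east=dx,
        dy_north=dy,
        distance=math.hypot(dx, dy),
        octant=_octant(dx, dy),
    )
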