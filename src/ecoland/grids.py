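"""Grid data model, land-class scheme, area accounting, and raster I/O.

All spatial analysis in this package runs on two light-weight raster
containers, :class:`CategoricalRaster` (integer land-class codes) and
:class:`ContinuousRaster` (elevation, slope, distance, probability
surfaces).  Coordinates are planar projected meters; cell centers sit at
``corner + (index + 0.5) * cell_size``; areas are obtained by cell
counting, matching the 30 m Landsat-grid mapping the analysis assumes.

Rasters are exchanged as single-band ESRI ASCII grids (``.asc``), a plain
text format carrying the grid shape, lower-left corner, cell size and
nodata value.  A JSON sidecar (``<name>.asc.meta.json``) optionally carries
the acquisition year, value units and the CRS unit, which must be meters —
geographic (degree) grids are rejected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "LandTypeScheme",
    "CategoricalRaster",
    "ContinuousRaster",
    "SchemeError",
    "RasterError",
    "default_scheme",
    "binary_eco_scheme",
    "read_categorical",
    "write_categorical",
    "read_continuous",
    "write_continuous",
    "class_area",
    "to_binary_eco",
]


class SchemeError(ValueError):
    """A land-class scheme is invalid or a code is not in the scheme."""


class RasterError(ValueError):
    """A raster violates a structural precondition (shape, CRS, registration)."""


@dataclass(frozen=True)
class LandTypeScheme:
    """An ordered set of land-class codes with names and ecological flags.

    The default 10-class scheme (see :func:`default_scheme`) covers the
    urban land system under study: five ecological classes (woodland,
    grassland, reservoirs and pit ponds, tidal flats, rivers and shallow
    water) and five non-ecological ones (rainfed cropland, paddy fields,
    aquaculture areas, built-up land, unutilized land).
    """

    entries: tuple[tuple[int, str, bool], ...]

    def __post_init__(self) -> None:
        codes = [c for c, _, _ in self.entries]
        if len(codes) < 2:
            raise SchemeError("scheme needs at least 2 classes")
        if len(set(codes)) != len(codes):
            raise SchemeError(f"duplicate class codes: {sorted(codes)}")
        if any(c <= 0 for c in codes):
            raise SchemeError("class codes must be positive integers")

    @property
    def codes(self) -> tuple[int, ...]:
        return tuple(c for c, _, _ in self.entries)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for _, n, _ in self.entries)

    @property
    def n(self) -> int:
        return len(self.entries)

    def name_of(self, code: int) -> str:
        for c, n, _ in self.entries:
            if c == code:
                return n
        raise SchemeError(f"code {code} not in scheme")

    def is_ecological(self, code: int) -> bool:
        for c, _, eco in self.entries:
            if c == code:
                return eco
        raise SchemeError(f"code {code} not in scheme")

    @property
    def ecological_codes(self) -> tuple[int, ...]:
        return tuple(c for c, _, eco in self.entries if eco)

    def validate_codes(self, values: np.ndarray, mask: np.ndarray) -> None:
        present = np.unique(values[~mask]) if mask.any() else np.unique(values)
        unknown = sorted(set(int(v) for v in present) - set(self.codes))
        if unknown:
            raise SchemeError(f"codes not in scheme: {unknown}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "LandTypeScheme":
        """Read a scheme from a CSV with columns code,name,is_ecological."""
        import pandas as pd

        df = pd.read_csv(path)
        entries = tuple(
            (int(r["code"]), str(r["name"]), bool(int(r["is_ecological"])))
            for _, r in df.iterrows()
        )
        return cls(entries)

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "code": self.codes,
                "name": self.names,
                "is_ecological": [int(e) for _, _, e in self.entries],
            }
        ).to_csv(path, index=False)


def default_scheme() -> LandTypeScheme:
    """The canonical 10-class urban land scheme, codes 1-10.

    Ordering follows the ecosystem-service coefficient table so a single
    code order serves every coefficient lookup in the package.
    """
    return LandTypeScheme(
        (
            (1, "woodland", True),
            (2, "grassland", True),
            (3, "rainfed cropland", False),
            (4, "paddy fields", False),
            (5, "aquaculture areas", False),
            (6, "reservoirs and pit ponds", True),
            (7, "tidal flats", True),
            (8, "rivers and shallow water", True),
            (9, "built-up land", False),
            (10, "unutilized land", False),
        )
    )


#: Code for the built-up class in the default scheme.
BUILTUP_CODE = 9

#: Codes of the binary ecological/non-ecological grouping.
ECO_CODE = 1
NONECO_CODE = 2


def binary_eco_scheme() -> LandTypeScheme:
    """Two-class scheme used after grouping into ecological / non-ecological."""
    return LandTypeScheme(
        ((ECO_CODE, "ecological", True), (NONECO_CODE, "non-ecological", False))
    )


def _check_grid(values: np.ndarray, mask: np.ndarray | None, cell_size: float):
    values = np.asarray(values)
    if values.ndim != 2:
        raise RasterError(f"raster must be 2-D, got shape {values.shape}")
    if cell_size <= 0:
        raise RasterError(f"cell_size must be positive, got {cell_size}")
    if mask is None:
        mask = np.zeros(values.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != values.shape:
            raise RasterError("mask shape does not match values")
    return values, mask


@dataclass
class _BaseRaster:
    values: np.ndarray
    mask: np.ndarray = None  # True where nodata
    cell_size: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)  # (x, y) of the lower-left corner

    def __post_init__(self) -> None:
        self.values, self.mask = _check_grid(self.values, self.mask, self.cell_size)
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_valid(self) -> int:
        return int((~self.mask).sum())

    def co_registered_with(self, other: "_BaseRaster") -> bool:
        return (
            self.shape == other.shape
            and self.cell_size == other.cell_size
            and self.origin == other.origin
        )

    def require_registration(self, other: "_BaseRaster") -> None:
        if self.shape != other.shape:
            raise RasterError(
                f"shape mismatch: {self.shape} vs {other.shape}"
            )
        if not self.co_registered_with(other):
            raise RasterError("rasters are not co-registered (cell size or origin)")

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Projected (x, y) coordinates of every cell center, row-major arrays.

        Row 0 is the northernmost row, as stored.
        """
        nrows, ncols = self.shape
        x0, y0 = self.origin
        cols = np.arange(ncols)
        rows = np.arange(nrows)
        x = x0 + (cols + 0.5) * self.cell_size
        y = y0 + (nrows - rows - 0.5) * self.cell_size
        return np.meshgrid(x, y)


@dataclass
class CategoricalRaster(_BaseRaster):
    """Grid of integer land-class codes with a nodata mask."""

    year: int | None = None

    def __post_init__(self) -> None:
        super().__post_init__()
        self.values = self.values.astype(np.int64)


@dataclass
class ContinuousRaster(_BaseRaster):
    """Grid of real values (elevation m, slope degrees, distance km, probability)."""

    units: str = ""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.values = self.values.astype(float)
        if self.units == "probability":
            v = self.values[~self.mask]
            if v.size and (np.nanmin(v) < -1e-9 or np.nanmax(v) > 1 + 1e-9):
                raise RasterError("probability raster outside [0, 1]")


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O

_NODATA_INT = -9999


def _write_asc(path: Path, values: np.ndarray, mask: np.ndarray,
               cell_size: float, origin: tuple[float, float],
               nodata, fmt: str) -> None:
    nrows, ncols = values.shape
    out = values.copy()
    out[mask] = nodata
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {origin[0]!r}\n"
        f"yllcorner {origin[1]!r}\n"
        f"cellsize {cell_size!r}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt=fmt)


def _read_asc(path: Path):
    with open(path) as fh:
        header: dict[str, float] = {}
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, val = line.partition(" ")
            key = key.strip().lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner",
                       "cellsize", "nodata_value"}:
                header[key] = float(val)
                pos = fh.tell()
            else:  # nodata line is optional in the wild
                break
        fh.seek(pos)
        data = np.loadtxt(fh, ndmin=2)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if data.shape != (nrows, ncols):
        raise RasterError(
            f"grid body {data.shape} does not match header ({nrows}, {ncols})"
        )
    nodata = header.get("nodata_value", _NODATA_INT)
    mask = data == nodata
    origin = (header["xllcorner"], header["yllcorner"])
    return data, mask, header["cellsize"], origin


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def _check_sidecar_crs(meta: dict) -> None:
    unit = str(meta.get("crs_units", "m")).lower()
    if unit in {"degree", "degrees", "deg"}:
        raise RasterError(
            "geographic (degree) CRS is not supported; reproject to a "
            "projected CRS in meters"
        )


def write_categorical(raster: CategoricalRaster, path: str | Path) -> None:
    path = Path(path)
    _write_asc(path, raster.values, raster.mask, raster.cell_size,
               raster.origin, _NODATA_INT, "%d")
    meta = {"kind": "categorical", "crs_units": "m"}
    if raster.year is not None:
        meta["year"] = int(raster.year)
    _sidecar(path).write_text(json.dumps(meta))


def read_categorical(path: str | Path, scheme: LandTypeScheme) -> CategoricalRaster:
    """Read a single-band categorical raster and validate codes against *scheme*."""
    path = Path(path)
    data, mask, cell_size, origin = _read_asc(path)
    year = None
    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
        _check_sidecar_crs(meta)
        year = meta.get("year")
    if not np.all(np.isclose(data[~mask] % 1, 0)):
        raise RasterError(f"{path} contains non-integer class codes")
    scheme.validate_codes(data.astype(np.int64), mask)
    return CategoricalRaster(data.astype(np.int64), mask, cell_size, origin,
                             year=year)


def write_continuous(raster: ContinuousRaster, path: str | Path) -> None:
    path = Path(path)
    _write_asc(path, raster.values, raster.mask, raster.cell_size,
               raster.origin, float(_NODATA_INT), "%.10g")
    _sidecar(path).write_text(
        json.dumps({"kind": "continuous", "units": raster.units, "crs_units": "m"})
    )


def read_continuous(path: str | Path) -> ContinuousRaster:
    path = Path(path)
    data, mask, cell_size, origin = _read_asc(path)
    units = ""
    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
        _check_sidecar_crs(meta)
        units = meta.get("units", "")
    return ContinuousRaster(data, mask, cell_size, origin, units=units)


# ---------------------------------------------------------------------------
# Area accounting

def class_area(raster: CategoricalRaster, code: int,
               scheme: LandTypeScheme) -> float:
    """Area of one class in km²: unmasked cell count × cell_size² / 10⁶."""
    if code not in scheme.codes:
        raise SchemeError(f"code {code} not in scheme")
    n = int(((raster.values == code) & ~raster.mask).sum())
    return n * raster.cell_size**2 / 1e6


def all_class_areas(raster: CategoricalRaster,
                    scheme: LandTypeScheme) -> dict[int, float]:
    return {c: class_area(raster, c, scheme) for c in scheme.codes}


def total_area(raster: _BaseRaster) -> float:
    """Unmasked landscape area in km²."""
    return raster.n_valid * raster.cell_size**2 / 1e6


def to_binary_eco(raster: CategoricalRaster,
                  scheme: LandTypeScheme) -> CategoricalRaster:
    """Collapse a raster into the two-class ecological / non-ecological grouping.

    The mask is preserved; each unmasked cell maps to :data:`ECO_CODE` or
    :data:`NONECO_CODE` by the scheme's ecological flag.
    """
    scheme.validate_codes(raster.values, raster.mask)
    eco = np.isin(raster.values, scheme.ecological_codes)
    out = np.where(eco, ECO_CODE, NONECO_CODE).astype(np.int64)
    return CategoricalRaster(out, raster.mask.copy(), raster.cell_size,
                             raster.origin, year=raster.year)
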