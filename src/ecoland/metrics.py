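"""Patch identification and landscape pattern indices.

Implements the raster landscape-metric suite used to track fragmentation
and aggregation of land classes: edge density (ED), patch density (PD),
landscape shape index (LSI), largest patch index (LPI), contagion
(CONTAG), Shannon diversity and evenness (SHDI, SHEI) at the landscape
level, and PD / LSI / LPI / area-weighted mean contiguity (CONTIG_AM) at
the class level.

Conventions (the standard raster ones):

* patch membership uses 8-connectivity; edges and adjacencies use
  4-neighbor cell sides;
* ED counts only internal unlike-class edges, while LSI's total edge E'
  also includes the landscape boundary (nodata cells count as boundary);
* patch perimeter counts every exposed cell side (unlike class, nodata, or
  grid boundary);
* CONTIG uses the 3×3 template with weights 1 (center), 2 (orthogonal),
  1 (diagonal), template sum v = 13: a single-cell patch scores 0 and a
  cell fully surrounded by its own patch scores 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import CategoricalRaster

__all__ = [
    "Patch",
    "PatchSet",
    "MetricValue",
    "UndefinedMetric",
    "label_patches",
    "adjacency_table",
    "landscape_level",
    "class_level",
    "CONTIG_WEIGHTS",
]

#: 3×3 contiguity template: center 1, orthogonal 2, diagonal 1 (sum 13).
CONTIG_WEIGHTS = np.array([[1, 2, 1], [2, 1, 2], [1, 2, 1]], dtype=float)
_CONTIG_V = float(CONTIG_WEIGHTS.sum())  # 13

_EIGHT = np.ones((3, 3), dtype=int)
_FOUR = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int)


class UndefinedMetric(ValueError):
    """Raised when a metric is undefined for the given input (e.g. CONTAG
    with a single class, or class metrics for an absent class)."""


@dataclass(frozen=True)
class Patch:
    id: int
    code: int
    cells: int
    area_m2: float
    area_ha: float
    perimeter_m: float
    contiguity: float


@dataclass
class PatchSet:
    patches: list[Patch]
    labels: np.ndarray  # 0 = nodata, 1..n patch ids

    def __len__(self) -> int:
        return len(self.patches)

    def of_class(self, code: int) -> list[Patch]:
        return [p for p in self.patches if p.code == code]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([p.__dict__ for p in self.patches])


@dataclass(frozen=True)
class MetricValue:
    level: str   # "landscape" | "class"
    metric: str
    value: float
    units: str
    code: int | None = None


def _neighbor_shifts(connectivity: int):
    if connectivity == 8:
        return [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    return [(-1, 0), (0, -1), (0, 1), (1, 0)]


def _shifted_pairs(arr: np.ndarray, dr: int, dc: int):
    """View pairs (a, b) of cells and their (dr, dc)-neighbors."""
    nr, nc = arr.shape
    r0, r1 = max(dr, 0), nr + min(dr, 0)
    c0, c1 = max(dc, 0), nc + min(dc, 0)
    a = arr[r0 - dr:r1 - dr, c0 - dc:c1 - dc]
    b = arr[r0:r1, c0:c1]
    return a, b


def label_patches(raster: CategoricalRaster, connectivity: int = 8) -> PatchSet:
    """Identify per-class connected components and their geometry.

    Each patch is a maximal set of same-class cells connected under the
    chosen connectivity (8 by default).  Per-patch perimeter and contiguity
    are computed vectorized over the labeled grid.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    structure = _EIGHT if connectivity == 8 else _FOUR
    valid = ~raster.mask
    labels = np.zeros(raster.shape, dtype=np.int64)
    patch_code: list[int] = []
    next_id = 1
    for code in np.unique(raster.values[valid]) if valid.any() else []:
        m = (raster.values == code) & valid
        lab, n = ndimage.label(m, structure=structure)
        labels[m] = lab[m] + next_id - 1
        patch_code.extend([int(code)] * n)
        next_id += n
    n_patches = next_id - 1
    if n_patches == 0:
        return PatchSet([], labels)

    cs = raster.cell_size
    cells = np.bincount(labels[valid], minlength=n_patches + 1)[1:]

    # perimeter: exposed 4-neighbor sides (different class, nodata, or grid edge)
    exposed = np.zeros(raster.shape, dtype=np.int64)
    code_grid = np.where(valid, raster.values, -1)
    for dr, dc in _neighbor_shifts(4):
        nbr, cell = _shifted_pairs(code_grid, dr, dc)
        interior = np.zeros(raster.shape, dtype=bool)
        r0, r1 = max(dr, 0), raster.shape[0] + min(dr, 0)
        c0, c1 = max(dc, 0), raster.shape[1] + min(dc, 0)
        interior[r0:r1, c0:c1] = nbr == cell
        exposed += np.where(valid, 1 - interior, 0)
    perim = np.bincount(labels[valid], weights=exposed[valid],
                        minlength=n_patches + 1)[1:] * cs

    # contiguity: per-cell template sum over same-patch neighbors
    tmpl = np.ones(raster.shape, dtype=float)  # center weight
    for (dr, dc), w in zip(
        _neighbor_shifts(8), [1, 2, 1, 2, 2, 1, 2, 1]
    ):
        nbr, _cell = _shifted_pairs(labels, dr, dc)
        same = np.zeros(raster.shape, dtype=bool)
        r0, r1 = max(dr, 0), raster.shape[0] + min(dr, 0)
        c0, c1 = max(dc, 0), raster.shape[1] + min(dc, 0)
        same[r0:r1, c0:c1] = (nbr == labels[r0:r1, c0:c1]) & (nbr > 0)
        tmpl += w * same
    mean_tmpl = (
        np.bincount(labels[valid], weights=tmpl[valid], minlength=n_patches + 1)[1:]
        / cells
    )
    contig = (mean_tmpl - 1.0) / (_CONTIG_V - 1.0)

    patches = [
        Patch(
            id=i + 1,
            code=patch_code[i],
            cells=int(cells[i]),
            area_m2=float(cells[i] * cs * cs),
            area_ha=float(cells[i] * cs * cs / 1e4),
            perimeter_m=float(perim[i]),
            contiguity=float(contig[i]),
        )
        for i in range(n_patches)
    ]
    return PatchSet(patches, labels)


def adjacency_table(raster: CategoricalRaster) -> tuple[np.ndarray, np.ndarray]:
    """Double-count 4-neighbor side adjacencies g_ik between classes.

    Returns (codes, g) where g[i, k] counts ordered adjacencies, so g is
    symmetric and sums to twice the number of internal unmasked sides.
    """
    valid = ~raster.mask
    codes = np.unique(raster.values[valid]) if valid.any() else np.array([], int)
    idx = {int(c): i for i, c in enumerate(codes)}
    g = np.zeros((len(codes), len(codes)), dtype=np.int64)
    vals = np.where(valid, raster.values, -1)
    for dr, dc in _neighbor_shifts(4):
        a, b = _shifted_pairs(vals, dr, dc)
        ok = (a >= 0) & (b >= 0)
        if ok.any():
            ia = np.vectorize(idx.get)(a[ok])
            ib = np.vectorize(idx.get)(b[ok])
            np.add.at(g, (ib, ia), 1)
    return codes, g


def _edges(raster: CategoricalRaster) -> tuple[float, float]:
    """(internal unlike-class edge length, landscape-boundary length), meters.

    Boundary = sides facing nodata or the grid edge.  Each internal side is
    counted once.
    """
    valid = ~raster.mask
    vals = np.where(valid, raster.values, -1)
    cs = raster.cell_size
    unlike = 0
    boundary = 0
    for dr, dc in [(0, 1), (1, 0)]:  # each internal side once
        a, b = _shifted_pairs(vals, dr, dc)
        both = (a >= 0) & (b >= 0)
        unlike += int((both & (a != b)).sum())
        boundary += int(((a >= 0) ^ (b >= 0)).sum())
    # grid-edge sides of valid cells
    boundary += int(valid[0, :].sum() + valid[-1, :].sum()
                    + valid[:, 0].sum() + valid[:, -1].sum())
    return unlike * cs, boundary * cs


def landscape_level(raster: CategoricalRaster,
                    connectivity: int = 8) -> dict[str, MetricValue]:
    """The seven landscape-level indices for one date.

    ED (m/ha), PD (patches/100 ha), LSI, LPI (%), CONTAG (%), SHDI, SHEI.
    CONTAG and SHEI are undefined (NaN) with fewer than two classes present.
    """
    valid = ~raster.mask
    if not valid.any():
        raise UndefinedMetric("empty raster: no unmasked cells")
    ps = label_patches(raster, connectivity)
    cs = raster.cell_size
    A_m2 = valid.sum() * cs * cs
    A_ha = A_m2 / 1e4

    unlike_m, boundary_m = _edges(raster)
    ED = unlike_m / A_ha
    PD = len(ps) / (A_ha / 100.0)
    LPI = 100.0 * max(p.area_m2 for p in ps.patches) / A_m2
    LSI = 0.25 * (unlike_m + boundary_m) / np.sqrt(A_m2)

    codes, counts = np.unique(raster.values[valid], return_counts=True)
    p_i = counts / counts.sum()
    SHDI = float(-(p_i * np.log(p_i)).sum())
    n = len(codes)
    SHEI = SHDI / np.log(n) if n > 1 else float("nan")

    if n > 1:
        _, g = adjacency_table(raster)
        gsum = g.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            q = p_i[:, None] * np.where(gsum > 0, g / np.where(gsum > 0, gsum, 1), 0)
        terms = np.where(q > 0, q, 0.0) * np.log(np.where(q > 0, q, 1.0))
        CONTAG = 100.0 * (1.0 + terms.sum() / (2.0 * np.log(n)))
    else:
        CONTAG = float("nan")

    mk = lambda name, val, units: MetricValue("landscape", name, float(val), units)
    return {
        "ED": mk("ED", ED, "m/ha"),
        "PD": mk("PD", PD, "patches/100 ha"),
        "LSI": mk("LSI", LSI, "dimensionless"),
        "LPI": mk("LPI", LPI, "%"),
        "CONTAG": mk("CONTAG", CONTAG, "%"),
        "SHDI": mk("SHDI", SHDI, "dimensionless"),
        "SHEI": mk("SHEI", SHEI, "dimensionless"),
    }


def class_level(raster: CategoricalRaster, code: int,
                connectivity: int = 8) -> dict[str, MetricValue]:
    """Class-level PD, LSI, LPI and CONTIG_AM for one land class.

    PD and LPI use the total landscape area as denominator (the reporting
    convention for class tables); LSI and CONTIG_AM are intrinsic to the
    class: LSI = 0.25·E_class/√A_class with E_class the summed patch
    perimeter, CONTIG_AM the patch-area-weighted mean contiguity.
    """
    valid = ~raster.mask
    present = ((raster.values == code) & valid).any()
    if not present:
        raise UndefinedMetric(f"class {code} absent from raster")
    ps = label_patches(raster, connectivity)
    cls = ps.of_class(code)
    cs = raster.cell_size
    A_m2 = valid.sum() * cs * cs
    A_ha = A_m2 / 1e4
    A_cls = sum(p.area_m2 for p in cls)
    E_cls = sum(p.perimeter_m for p in cls)

    PD = len(cls) / (A_ha / 100.0)
    LPI = 100.0 * max(p.area_m2 for p in cls) / A_m2
    LSI = 0.25 * E_cls / np.sqrt(A_cls)
    CONTIG_AM = sum(p.area_m2 * p.contiguity for p in cls) / A_cls

    mk = lambda name, val, units: MetricValue("class", name, float(val), units, code)
    return {
        "PD": mk("PD", PD, "patches/100 ha"),
        "LSI": mk("LSI", LSI, "dimensionless"),
        "LPI": mk("LPI", LPI, "%"),
        "CONTIG_AM": mk("CONTIG_AM", CONTIG_AM, "dimensionless"),
    }


def metrics_frame(values: dict[str, MetricValue], year: int | None = None) -> pd.DataFrame:
    """Tidy one metric dict into (year, level, class, metric, value, units)."""
    rows = [
        {
            "year": year,
            "level": v.level,
            "class": v.code,
            "metric": v.metric,
            "value": v.value,
            "units": v.units,
        }
        for v in values.values()
    ]
    return pd.DataFrame(rows)
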