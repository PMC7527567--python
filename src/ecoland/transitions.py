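"""Land-change accounting between two dates.

Transformation (transition) matrices in area and probability form, the
derived contribution/probability (B/C) percentage statistics, net change
per class, Markov projection of a class-area state vector, and binary
ecological gain/loss maps.

Conventions
-----------
Rows of the transition matrix index the origin class at t0, columns the
destination class at t1.  The probability matrix is the row-normalized
area matrix; rows whose class is absent at t0 are reported as undefined
(NaN) rather than fabricated zeros.  C is the row-normalized matrix in
percent (origin's transition probability); B is the column-normalized
matrix in percent (share of each destination class at t1 contributed by
each origin class), so columns of B and rows of C each sum to 100 where
defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import (
    ECO_CODE,
    CategoricalRaster,
    LandTypeScheme,
    RasterError,
    to_binary_eco,
)

__all__ = [
    "TransitionMatrix",
    "NetChange",
    "compute_transition_matrix",
    "net_change",
    "contribution_and_probability",
    "markov_project",
    "gains_losses_map",
    "GAIN",
    "LOSS",
    "STABLE_ECO",
    "STABLE_NONECO",
]


@dataclass
class TransitionMatrix:
    """Per-period class×class transition areas (km²) and probabilities."""

    labels: tuple[str, ...]
    codes: tuple[int, ...]
    areas: np.ndarray          # T_ij, km²
    probabilities: np.ndarray  # P_ij, NaN rows where t0 area is zero
    period: tuple[int | None, int | None] = (None, None)

    @property
    def t0_areas(self) -> np.ndarray:
        return self.areas.sum(axis=1)

    @property
    def t1_areas(self) -> np.ndarray:
        return self.areas.sum(axis=0)

    def to_frame(self, which: str = "areas") -> pd.DataFrame:
        m = {"areas": self.areas, "probabilities": self.probabilities}[which]
        return pd.DataFrame(m, index=list(self.labels), columns=list(self.labels))


@dataclass(frozen=True)
class NetChange:
    """Signed area change of one class: A = A_b − A_a (km²)."""

    code: int
    label: str
    area_start: float  # A_a
    area_end: float    # A_b

    @property
    def change(self) -> float:
        return self.area_end - self.area_start


def compute_transition_matrix(
    r_t0: CategoricalRaster,
    r_t1: CategoricalRaster,
    scheme: LandTypeScheme,
) -> TransitionMatrix:
    """Cross-tabulate two co-registered rasters into a transition matrix.

    T_ij is the joint cell count (class i at t0, class j at t1) times cell
    area; P is T row-normalized.  Raises if shapes, registration or masks
    differ.
    """
    r_t0.require_registration(r_t1)
    if not np.array_equal(r_t0.mask, r_t1.mask):
        raise RasterError("nodata masks differ between the two dates")
    scheme.validate_codes(r_t0.values, r_t0.mask)
    scheme.validate_codes(r_t1.values, r_t1.mask)

    codes = np.asarray(scheme.codes)
    idx = {c: i for i, c in enumerate(scheme.codes)}
    valid = ~r_t0.mask
    i0 = np.vectorize(idx.get)(r_t0.values[valid]) if valid.any() else np.array([], int)
    i1 = np.vectorize(idx.get)(r_t1.values[valid]) if valid.any() else np.array([], int)
    n = len(codes)
    counts = np.zeros((n, n), dtype=np.int64)
    np.add.at(counts, (i0, i1), 1)
    areas = counts * r_t0.cell_size**2 / 1e6

    row = areas.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(row > 0, areas / np.where(row > 0, row, 1.0), np.nan)
    return TransitionMatrix(
        labels=scheme.names,
        codes=scheme.codes,
        areas=areas,
        probabilities=probs,
        period=(r_t0.year, r_t1.year),
    )


def net_change(matrix: TransitionMatrix) -> list[NetChange]:
    """Per-class net change A = A_b − A_a from the matrix margins.

    In a closed landscape the signed changes sum to zero.
    """
    a0 = matrix.t0_areas
    a1 = matrix.t1_areas
    return [
        NetChange(code=c, label=l, area_start=float(a0[i]), area_end=float(a1[i]))
        for i, (c, l) in enumerate(zip(matrix.codes, matrix.labels))
    ]


def contribution_and_probability(
    matrix: TransitionMatrix,
) -> tuple[np.ndarray, np.ndarray]:
    """The (B, C) percentage statistics of a transition matrix.

    C_ij = 100·T_ij / Σ_j T_ij  — probability of origin class i turning
    into class j (rows sum to 100).
    B_ij = 100·T_ij / Σ_i T_ij  — contribution of origin class i to
    destination class j's area at t1 (columns sum to 100).
    Undefined entries (zero origin row / zero destination column) are NaN.
    """
    T = matrix.areas
    row = T.sum(axis=1, keepdims=True)
    col = T.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.where(row > 0, 100.0 * T / np.where(row > 0, row, 1.0), np.nan)
        B = np.where(col > 0, 100.0 * T / np.where(col > 0, col, 1.0), np.nan)
    return B, C


def markov_project(P: np.ndarray, S_t: np.ndarray, steps: int = 1) -> np.ndarray:
    """Propagate a class-area (or probability) state vector S through P.

    S_{t+1}[j] = Σ_i S_t[i]·P_ij, applied ``steps`` times; total mass is
    conserved at every step because P is row-stochastic.
    """
    P = np.asarray(P, dtype=float)
    S = np.asarray(S_t, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("P must be a square matrix")
    if S.shape[-1] != P.shape[0]:
        raise ValueError("state vector not conformable with P")
    if np.any(P < -1e-12) or np.any(P > 1 + 1e-12):
        raise ValueError("P entries must lie in [0, 1]")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("P rows must sum to 1 (row-stochastic)")
    if np.any(S < 0):
        raise ValueError("state vector must be nonnegative")
    for _ in range(int(steps)):
        S = S @ P
    return S


# Legend codes of the gain/loss map.
STABLE_ECO = 1
STABLE_NONECO = 2
GAIN = 3
LOSS = 4

_GAINLOSS_LABELS = {
    STABLE_ECO: "stable ecological",
    STABLE_NONECO: "stable non-ecological",
    GAIN: "ecological gain",
    LOSS: "ecological loss",
}


def gains_losses_map(
    r_t0: CategoricalRaster,
    r_t1: CategoricalRaster,
    scheme: LandTypeScheme,
) -> tuple[CategoricalRaster, dict[str, float]]:
    """Per-cell ecological gain/loss classification between two dates.

    Returns the 4-code map (stable-eco / stable-non-eco / gain / loss) and a
    summary dict of gain, loss and net-change areas in km².
    """
    r_t0.require_registration(r_t1)
    if not np.array_equal(r_t0.mask, r_t1.mask):
        raise RasterError("nodata masks differ between the two dates")
    b0 = to_binary_eco(r_t0, scheme)
    b1 = to_binary_eco(r_t1, scheme)
    e0 = b0.values == ECO_CODE
    e1 = b1.values == ECO_CODE
    out = np.full(r_t0.shape, STABLE_NONECO, dtype=np.int64)
    out[e0 & e1] = STABLE_ECO
    out[~e0 & e1] = GAIN
    out[e0 & ~e1] = LOSS
    cell_km2 = r_t0.cell_size**2 / 1e6
    valid = ~r_t0.mask
    gain = float((valid & (out == GAIN)).sum()) * cell_km2
    loss = float((valid & (out == LOSS)).sum()) * cell_km2
    summary = {"gain_km2": gain, "loss_km2": loss, "net_km2": gain - loss}
    m = CategoricalRaster(out, r_t0.mask.copy(), r_t0.cell_size, r_t0.origin,
                          year=r_t1.year)
    return m, summary
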