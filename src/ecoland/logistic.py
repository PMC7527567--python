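"""Driving-factor analysis of ecological-land transformation.

Builds the covariate stack (slope from the DEM by Horn's method, elevation,
Euclidean distance to built-up land, and a 5-level categorical built-up
growth rate per administrative zone), draws cell samples from ecological
land, fits a binary logistic model by maximum likelihood (optionally with
forward stepwise selection), validates it on a holdout confusion matrix,
and maps the transformation probability with a fixed 5-level
classification.

Outcome coding
--------------
Samples are drawn from cells that are ecological at t0; the fitted outcome
is y = 1 when the cell is *still ecological* at t1 (persistence).  The
transformation probability is then P = 1 − σ(z) with z the fitted (or
supplied) linear predictor — equivalently σ(−z) — so a positive distance
coefficient in z means cells far from built-up land are *less* likely to
transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .grids import (
    BUILTUP_CODE,
    CategoricalRaster,
    ContinuousRaster,
    LandTypeScheme,
    RasterError,
)

__all__ = [
    "TransformCoefficients",
    "CovariateStack",
    "SampleSet",
    "LogisticFit",
    "ValidationResult",
    "SeparationError",
    "compute_slope",
    "distance_to_builtup",
    "annual_growth_rate",
    "growth_level",
    "growth_rate_levels",
    "build_covariates",
    "draw_samples",
    "fit_logistic",
    "evaluate_transform_probability",
    "confusion_stats",
    "validate",
    "predict_probability_map",
    "classify_probability",
    "PROBABILITY_CUTS",
    "PROBABILITY_LEVEL_NAMES",
]

#: Level-raster cuts of the 5-level transformation-probability classes:
#: low ≤ 0.1 < relatively low ≤ 0.3 < medium ≤ 0.45 < relatively high
#: ≤ 0.65 < high.
PROBABILITY_CUTS = (0.1, 0.3, 0.45, 0.65)
PROBABILITY_LEVEL_NAMES = {
    1: "low",
    2: "relatively low",
    3: "medium",
    4: "relatively high",
    5: "high",
}

#: Upper bounds (%) of the five annual built-up growth-rate levels.
GROWTH_LEVEL_BOUNDS = (0.05, 0.10, 0.20, 0.35)

#: Covariate column order used throughout: slope (°), elevation (m),
#: distance to built-up land (km), growth-level dummies (level 1 reference).
COVARIATE_COLUMNS = ("slope", "elevation", "distance",
                     "level2", "level3", "level4", "level5")


class SeparationError(RuntimeError):
    """Maximum-likelihood fit failed because the outcome is perfectly
    separated by one or more covariates."""


@dataclass(frozen=True)
class TransformCoefficients:
    """Linear predictor z of the transformation model, P(transform) = 1 − σ(z).

    Defaults are the published driving-factor estimates for the study
    system: z = 0.069·slope + 0.033·elevation + 0.473·distance −
    1.079·level4 − 0.963·level5 − 0.853.
    """

    slope: float = 0.069
    elevation: float = 0.033
    distance: float = 0.473
    level4: float = -1.079
    level5: float = -0.963
    intercept: float = -0.853
    level2: float = 0.0
    level3: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return {
            "intercept": self.intercept,
            "slope": self.slope,
            "elevation": self.elevation,
            "distance": self.distance,
            "level2": self.level2,
            "level3": self.level3,
            "level4": self.level4,
            "level5": self.level5,
        }


def evaluate_transform_probability(
    A, B, C, D, E,
    coefficients: TransformCoefficients | None = None,
):
    """Transformation probability P = 1 − 1/(1 + e^{−z}).

    A slope (°), B elevation (m), C distance to built-up land (km), D and E
    the level-4 and level-5 growth-rate indicators.  Works elementwise on
    arrays; defaults to the published coefficients.
    """
    k = coefficients or TransformCoefficients()
    z = (
        k.slope * np.asarray(A, float)
        + k.elevation * np.asarray(B, float)
        + k.distance * np.asarray(C, float)
        + k.level4 * np.asarray(D, float)
        + k.level5 * np.asarray(E, float)
        + k.intercept
    )
    # 1 − σ(z) = σ(−z), computed stably
    return stats.logistic.cdf(-z)


# ---------------------------------------------------------------------------
# Covariate construction


def compute_slope(dem: ContinuousRaster) -> ContinuousRaster:
    """Slope in degrees from a DEM by Horn's 3×3 finite differences.

    p = ∂z/∂x and q = ∂z/∂y are estimated with the 1-2-1 weighted kernel
    over the 8 neighbors; slope = arctan(√(p²+q²)).  Border cells use edge
    replication.
    """
    z = dem.values
    if z.shape[0] < 2 or z.shape[1] < 2:
        raise RasterError("DEM must be at least 2×2 to compute slope")
    zp = np.pad(z, 1, mode="edge")
    cs = dem.cell_size
    # neighbors named by compass position
    nw, n_, ne = zp[:-2, :-2], zp[:-2, 1:-1], zp[:-2, 2:]
    w_, e_ = zp[1:-1, :-2], zp[1:-1, 2:]
    sw, s_, se = zp[2:, :-2], zp[2:, 1:-1], zp[2:, 2:]
    p = ((ne + 2 * e_ + se) - (nw + 2 * w_ + sw)) / (8 * cs)
    q = ((nw + 2 * n_ + ne) - (sw + 2 * s_ + se)) / (8 * cs)
    slope = np.degrees(np.arctan(np.hypot(p, q)))
    return ContinuousRaster(slope, dem.mask.copy(), dem.cell_size, dem.origin,
                            units="degrees")


def distance_to_builtup(
    landuse: CategoricalRaster,
    builtup_code: int = BUILTUP_CODE,
) -> ContinuousRaster:
    """Euclidean distance (km) from each cell center to the nearest
    built-up cell; built-up cells themselves get 0."""
    built = (landuse.values == builtup_code) & ~landuse.mask
    if not built.any():
        raise RasterError("no built-up cells: distance undefined")
    d = ndimage.distance_transform_edt(~built, sampling=landuse.cell_size)
    return ContinuousRaster(d / 1000.0, landuse.mask.copy(),
                            landuse.cell_size, landuse.origin, units="km")


def annual_growth_rate(a_t0: float, a_t1: float, years: float,
                       method: str = "geometric") -> float:
    """Average annual growth rate of an area over a period.

    Geometric (default): (A_t1/A_t0)^(1/years) − 1.  Arithmetic variant:
    (A_t1 − A_t0)/(A_t0·years).
    """
    if years <= 0:
        raise ValueError("years must be positive")
    if a_t0 <= 0:
        raise ValueError("zero start area: growth rate undefined")
    if method == "geometric":
        return (a_t1 / a_t0) ** (1.0 / years) - 1.0
    if method == "arithmetic":
        return (a_t1 - a_t0) / (a_t0 * years)
    raise ValueError(f"unknown method {method!r}")


def growth_level(rate: float) -> int:
    """Map an annual growth rate to its 5-level class.

    Levels 1–5 cover ≤5%, (5,10]%, (10,20]%, (20,35]% and >35% per year.
    """
    for lvl, bound in enumerate(GROWTH_LEVEL_BOUNDS, start=1):
        if rate <= bound:
            return lvl
    return 5


def growth_rate_levels(
    landuse_t0: CategoricalRaster,
    landuse_t1: CategoricalRaster,
    years: float,
    zones: CategoricalRaster,
    builtup_code: int = BUILTUP_CODE,
    method: str = "geometric",
) -> CategoricalRaster:
    """Per-zone built-up growth-rate level, broadcast to every zone cell.

    For each administrative zone the built-up area at t0 and t1 gives the
    average annual growth rate, binned into levels 1–5.  A zone with zero
    built-up area at t0 has an undefined rate and raises.
    """
    landuse_t0.require_registration(landuse_t1)
    landuse_t0.require_registration(zones)
    valid = ~landuse_t0.mask
    out = np.zeros(landuse_t0.shape, dtype=np.int64)
    for zid in np.unique(zones.values[valid]):
        zm = (zones.values == zid) & valid
        a0 = int(((landuse_t0.values == builtup_code) & zm).sum())
        a1 = int(((landuse_t1.values == builtup_code) & zm).sum())
        if a0 == 0:
            raise ValueError(f"zone {zid}: zero built-up area at t0, "
                             "growth rate undefined")
        r = annual_growth_rate(a0, a1, years, method)
        out[zm] = growth_level(r)
    return CategoricalRaster(out, landuse_t0.mask.copy(),
                             landuse_t0.cell_size, landuse_t0.origin,
                             year=landuse_t1.year)


@dataclass
class CovariateStack:
    """Co-registered covariate layers for the transformation model."""

    slope: ContinuousRaster          # degrees
    elevation: ContinuousRaster      # m
    distance: ContinuousRaster       # km
    levels: CategoricalRaster        # growth levels 1–5

    def __post_init__(self) -> None:
        for layer in (self.elevation, self.distance, self.levels):
            self.slope.require_registration(layer)
        lv = self.levels.values[~self.levels.mask]
        if lv.size and (lv.min() < 1 or lv.max() > 5):
            raise ValueError("growth levels must lie in 1..5")

    def table(self, rows: np.ndarray, cols: np.ndarray) -> pd.DataFrame:
        """Covariate values at cell indices, with level dummies (ref = 1)."""
        lv = self.levels.values[rows, cols]
        return pd.DataFrame(
            {
                "slope": self.slope.values[rows, cols],
                "elevation": self.elevation.values[rows, cols],
                "distance": self.distance.values[rows, cols],
                "level2": (lv == 2).astype(float),
                "level3": (lv == 3).astype(float),
                "level4": (lv == 4).astype(float),
                "level5": (lv == 5).astype(float),
            }
        )


def build_covariates(
    dem: ContinuousRaster,
    landuse_ref: CategoricalRaster,
    levels: CategoricalRaster,
    builtup_code: int = BUILTUP_CODE,
) -> CovariateStack:
    """Assemble the stack from a DEM, a reference land-use map (for the
    distance layer) and a precomputed growth-level raster."""
    return CovariateStack(
        slope=compute_slope(dem),
        elevation=dem,
        distance=distance_to_builtup(landuse_ref, builtup_code),
        levels=levels,
    )


# ---------------------------------------------------------------------------
# Sampling and fitting


@dataclass
class SampleSet:
    """Cell samples from ecological land at t0 with persistence outcome.

    ``y`` is 1 where the cell is still ecological at t1, 0 where it
    transformed.  ``X`` holds the covariate columns; rows/cols are the
    sampled cell indices.
    """

    X: pd.DataFrame
    y: np.ndarray
    rows: np.ndarray
    cols: np.ndarray
    seed: int | None = None
    years: tuple[int | None, int | None] = (None, None)

    @property
    def n(self) -> int:
        return len(self.y)


def draw_samples(
    eco_t0: CategoricalRaster,
    eco_t1: CategoricalRaster,
    stack: CovariateStack,
    scheme: LandTypeScheme,
    n: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> SampleSet:
    """Uniform sampling without replacement from cells ecological at t0."""
    eco_t0.require_registration(eco_t1)
    eco_t0.require_registration(stack.slope)
    eco0 = np.isin(eco_t0.values, scheme.ecological_codes) & ~eco_t0.mask
    eco1 = np.isin(eco_t1.values, scheme.ecological_codes) & ~eco_t1.mask
    pool_r, pool_c = np.nonzero(eco0)
    if n > len(pool_r):
        raise ValueError(
            f"requested {n} samples but only {len(pool_r)} ecological cells"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    pick = rng.choice(len(pool_r), size=n, replace=False)
    rows, cols = pool_r[pick], pool_c[pick]
    X = stack.table(rows, cols)
    y = eco1[rows, cols].astype(int)
    return SampleSet(X=X, y=y, rows=rows, cols=cols, seed=seed,
                     years=(eco_t0.year, eco_t1.year))


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit of the persistence outcome."""

    intercept: float
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    included: list[str]
    llf: float
    neg2ll: float
    lr_chi2: float
    lr_df: int
    lr_pvalue: float
    n: int
    converged: bool

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        z = np.full(len(X), self.intercept)
        for name, b in self.coefficients.items():
            z = z + b * X[name].to_numpy(float)
        return z

    def predict_persistence(self, X: pd.DataFrame) -> np.ndarray:
        return stats.logistic.cdf(self.linear_predictor(X))

    def predict_transform(self, X: pd.DataFrame) -> np.ndarray:
        return stats.logistic.cdf(-self.linear_predictor(X))

    def to_transform_coefficients(self) -> TransformCoefficients:
        """Express the fit in the transformation-equation convention.

        The fitted predictor z models persistence, so P(transform) =
        1 − σ(z) directly matches the published equation's form.
        """
        c = self.coefficients
        return TransformCoefficients(
            intercept=self.intercept,
            slope=c.get("slope", 0.0),
            elevation=c.get("elevation", 0.0),
            distance=c.get("distance", 0.0),
            level2=c.get("level2", 0.0),
            level3=c.get("level3", 0.0),
            level4=c.get("level4", 0.0),
            level5=c.get("level5", 0.0),
        )


def _check_separation(X: pd.DataFrame, y: np.ndarray) -> str | None:
    for col in X.columns:
        x = X[col].to_numpy(float)
        if x.std() == 0:
            continue
        if x[y == 1].size and x[y == 0].size:
            if x[y == 1].min() > x[y == 0].max() or x[y == 0].min() > x[y == 1].max():
                return col
    return None


def _ml_fit(X: pd.DataFrame, y: np.ndarray):
    import statsmodels.api as sm

    design = sm.add_constant(X, has_constant="add")
    model = sm.Logit(y, design)
    try:
        import warnings

        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(method="newton", maxiter=100, tol=1e-8, disp=0)
    except Exception as exc:  # statsmodels raises on perfect separation
        sep = _check_separation(X, y)
        raise SeparationError(
            f"logistic fit failed ({exc}); separating variable: {sep or 'unknown'}"
        ) from exc
    if not res.mle_retvals.get("converged", False):
        sep = _check_separation(X, y)
        if sep is not None:
            raise SeparationError(
                f"logistic fit did not converge; variable {sep!r} perfectly "
                "separates the outcome"
            )
    return res


def fit_logistic(
    samples: SampleSet,
    variables: list[str] | None = None,
    stepwise: bool = False,
    entry_p: float = 0.05,
) -> LogisticFit:
    """Fit the persistence logistic model by maximum likelihood.

    With ``stepwise=True`` variables enter forward one at a time by the
    largest likelihood-ratio improvement, as long as the entry test passes
    p < ``entry_p``; otherwise all ``variables`` (default: every covariate
    column) enter at once.  Reports −2 log-likelihood and the
    likelihood-ratio χ² against the intercept-only model.
    """
    y = np.asarray(samples.y)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class: cannot fit")
    if variables is None:
        variables = [c for c in samples.X.columns]
    # drop constant columns (e.g. a dummy level absent from the sample)
    variables = [v for v in variables
                 if samples.X[v].to_numpy(float).std() > 0]

    import statsmodels.api as sm

    null_ll = sm.Logit(y, np.ones((len(y), 1))).fit(disp=0).llf

    if stepwise:
        included: list[str] = []
        current_ll = null_ll
        while True:
            best = None
            for cand in variables:
                if cand in included:
                    continue
                try:
                    res = _ml_fit(samples.X[included + [cand]], y)
                except SeparationError:
                    continue
                lr = 2 * (res.llf - current_ll)
                p = stats.chi2.sf(lr, 1)
                if best is None or lr > best[1]:
                    best = (cand, lr, p, res)
            if best is None or best[2] >= entry_p:
                break
            included.append(best[0])
            current_ll = best[3].llf
        if not included:
            raise ValueError("stepwise selection admitted no variables "
                             f"at p < {entry_p}")
        res = _ml_fit(samples.X[included], y)
    else:
        included = list(variables)
        res = _ml_fit(samples.X[included], y)

    params = res.params
    bse = res.bse
    lr = 2 * (res.llf - null_ll)
    return LogisticFit(
        intercept=float(params["const"]),
        coefficients={v: float(params[v]) for v in included},
        std_errors={v: float(bse[v]) for v in included} | {"intercept": float(bse["const"])},
        included=included,
        llf=float(res.llf),
        neg2ll=float(-2 * res.llf),
        lr_chi2=float(lr),
        lr_df=len(included),
        lr_pvalue=float(stats.chi2.sf(lr, len(included))),
        n=len(y),
        converged=bool(res.mle_retvals.get("converged", True)),
    )


# ---------------------------------------------------------------------------
# Validation and mapping


@dataclass(frozen=True)
class ValidationResult:
    """2×2 confusion matrix (observed × predicted) and its accuracies.

    Rows are observed (unchanged, changed), columns predicted; accuracies
    are exact rationals of the counts, reported in percent.
    """

    matrix: np.ndarray
    unchanged_accuracy: float
    changed_accuracy: float
    overall_accuracy: float
    kappa: float

    @property
    def diagonal_total(self) -> int:
        return int(self.matrix[0, 0] + self.matrix[1, 1])


def confusion_stats(matrix: np.ndarray) -> ValidationResult:
    """Accuracies and Cohen's kappa from a 2×2 observed×predicted matrix."""
    m = np.asarray(matrix, dtype=float)
    if m.shape != (2, 2):
        raise ValueError("confusion matrix must be 2×2")
    total = m.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    row = m.sum(axis=1)
    col = m.sum(axis=0)
    po = (m[0, 0] + m[1, 1]) / total
    pe = (row * col).sum() / total**2
    kappa = (po - pe) / (1 - pe) if pe < 1 else 1.0
    return ValidationResult(
        matrix=np.asarray(matrix),
        unchanged_accuracy=100.0 * m[0, 0] / row[0] if row[0] else float("nan"),
        changed_accuracy=100.0 * m[1, 1] / row[1] if row[1] else float("nan"),
        overall_accuracy=100.0 * po,
        kappa=float(kappa),
    )


def validate(
    fit: LogisticFit | TransformCoefficients,
    holdout: SampleSet,
    threshold: float = 0.5,
) -> ValidationResult:
    """Confusion-matrix validation of the model on a holdout sample.

    Observed "changed" means the cell transformed (y = 0 in persistence
    coding); predicted "changed" means transformation probability >
    ``threshold``.
    """
    if holdout.n == 0:
        raise ValueError("empty holdout sample")
    if isinstance(fit, LogisticFit):
        p_tr = fit.predict_transform(holdout.X)
    else:
        p_tr = evaluate_transform_probability(
            holdout.X["slope"], holdout.X["elevation"], holdout.X["distance"],
            holdout.X["level4"], holdout.X["level5"], coefficients=fit,
        )
    obs_changed = holdout.y == 0
    pred_changed = np.asarray(p_tr) > threshold
    m = np.array(
        [
            [int((~obs_changed & ~pred_changed).sum()),
             int((~obs_changed & pred_changed).sum())],
            [int((obs_changed & ~pred_changed).sum()),
             int((obs_changed & pred_changed).sum())],
        ]
    )
    return confusion_stats(m)


def classify_probability(p: np.ndarray) -> np.ndarray:
    """Bin probabilities into levels 1–5 at the fixed cuts (0.1, 0.3,
    0.45, 0.65], left-open right-closed."""
    p = np.asarray(p, dtype=float)
    lvl = np.ones(p.shape, dtype=np.int64)
    for cut in PROBABILITY_CUTS:
        lvl += (p > cut).astype(np.int64)
    return lvl


def predict_probability_map(
    stack: CovariateStack,
    landuse: CategoricalRaster,
    scheme: LandTypeScheme,
    coefficients: TransformCoefficients | None = None,
) -> tuple[ContinuousRaster, CategoricalRaster, pd.DataFrame]:
    """Transformation-probability surface over ecological land.

    Non-ecological and nodata cells are masked.  Returns the probability
    raster, the 5-level classification raster, and per-land-class mean
    probabilities (including the all-ecological mean).
    """
    stack.slope.require_registration(landuse)
    k = coefficients or TransformCoefficients()
    eco = np.isin(landuse.values, scheme.ecological_codes) & ~landuse.mask
    lv = stack.levels.values
    z = (
        k.slope * stack.slope.values
        + k.elevation * stack.elevation.values
        + k.distance * stack.distance.values
        + k.level2 * (lv == 2)
        + k.level3 * (lv == 3)
        + k.level4 * (lv == 4)
        + k.level5 * (lv == 5)
        + k.intercept
    )
    p = stats.logistic.cdf(-z)
    mask = ~eco
    prob = ContinuousRaster(np.where(eco, p, 0.0), mask, landuse.cell_size,
                            landuse.origin, units="probability")
    levels = CategoricalRaster(
        np.where(eco, classify_probability(p), 0), mask,
        landuse.cell_size, landuse.origin, year=landuse.year,
    )
    rows = [{"class": "ecological", "code": None,
             "mean_probability": float(p[eco].mean()) if eco.any() else float("nan")}]
    for code in scheme.ecological_codes:
        sel = (landuse.values == code) & eco
        rows.append(
            {
                "class": scheme.name_of(code),
                "code": code,
                "mean_probability": float(p[sel].mean()) if sel.any() else float("nan"),
            }
        )
    return prob, levels, pd.DataFrame(rows)
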