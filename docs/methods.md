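# Methods

## Data model

All analysis runs on single-band rasters in a projected CRS with meter
units and square cells. Cell centers sit at `corner + (index + 0.5)·cell_size`
with the origin at the lower-left corner; areas come from cell counting
(`count × cell_size² / 10⁶` km²). Two rasters are co-registered iff shape,
cell size and origin match exactly; every cross-raster operation enforces
this and, where masks matter (transitions, gain/loss), identical nodata
masks. Geographic (degree) grids are rejected: all reported displacements
and distances are metric, so a meter-unit CRS is a precondition, not a
convention.

The default land scheme has ten classes, codes 1–10 in the order of the
service-value table (woodland, grassland, rainfed cropland, paddy fields,
aquaculture areas, reservoirs and pit ponds, tidal flats, rivers and
shallow water, built-up land, unutilized land); the five ecological
classes are woodland, grassland, reservoirs/pit ponds, tidal flats and
rivers/shallow water. Agricultural classes are excluded from ecological
land because their services are dominated by production and heavily
disturbed; unutilized land is excluded as unsustainable.

Rasters are written as ESRI ASCII grids with a JSON sidecar carrying the
year, value units and CRS units. The format is plain text and lossless
for integer codes; continuous layers round-trip at `%.10g`.

## Transition accounting

The transition matrix is estimated definitionally: T_ij is the joint
per-cell count times cell area, P the row-normalized T. Rows whose class
is absent at t0 are reported as undefined (NaN), never fabricated zeros.
Two percentage statistics derive from T: C_ij = 100·T_ij/Σ_j T_ij (the
transition probability of origin class i) and B_ij = 100·T_ij/Σ_i T_ij
(the share of destination class j's t1 area contributed by origin i).
B is column-normalized by the destination's t1 area — this is the unique
normalization that reproduces the published binary-table contribution
values from the printed probabilities and aggregate areas, which is
asserted in the acceptance suite. Because the estimator is definitional,
projecting the t0 state vector through P returns the observed t1 areas
exactly; `markov_project` validates row-stochasticity (Σ_j P_ij = 1,
entries in [0,1]) before applying any step.

## Landscape metrics

Patches are connected components of same-class cells under
8-connectivity (the common default of raster landscape-metric tools);
edges and adjacencies use 4-neighbor cell sides. Conventions pinned
explicitly because sources often leave them implicit:

- **ED** counts only internal unlike-class edges, per hectare of
  landscape (m/ha). The landscape boundary — grid edge and nodata sides —
  is excluded from ED but included in the total edge E′ of
  **LSI** = 0.25·E′/√A′. Patch perimeter counts every exposed side.
- **CONTAG** = 100·[1 + Σ_i Σ_k q_ik ln q_ik/(2 ln n)] with
  q_ik = p_i·g_ik/Σ_k g_ik and g the double-counted 4-adjacency table
  (like-adjacencies included). It is undefined (NaN) with fewer than two
  classes, as is SHEI.
- **CONTIG** uses the 3×3 template with weights 1/2/1
  (center/orthogonal/diagonal), template sum v = 13: contiguity =
  (mean template value − 1)/(v − 1), so an isolated cell scores 0.
  CONTIG_AM weights patch contiguity by patch area within the class.
- Class-level PD and LPI use the total landscape area as denominator
  (the convention of class-level report tables); class LSI is intrinsic,
  0.25·E_class/√A_class.

Every metric is checked against an independent brute-force implementation
(explicit loops and BFS) on random small grids across 100 seeds.

## Equivalent ecological area

Each class carries a normalized service value δ ∈ [0,1] (woodland 1.00,
rivers/shallow water 0.92, tidal flats 0.72, reservoirs/pit ponds 0.63,
grassland 0.47, paddy fields 0.29, aquaculture 0.23, rainfed cropland
0.16, unutilized 0.10, built-up 0.08). Equivalent area = Σ δ_i A_i;
average equivalent area Q = Σ δ_i A_i / Σ A_i. With δ ≤ 1 the equivalent
area can never exceed the raw area and Q is bounded by the δ of the
included classes — so Q is a dimensionless quality score in (0, 1], not
an area multiplier. The headline series uses the ecological subset (the
concept evaluates the service quality of ecological land); the all-class
variant is also reported. Period-over-period reductions are
(prev − cur)/prev·100, reported to one decimal.

## Center of gravity

With equal-area cells the area-weighted centroid reduces to the
arithmetic mean of contributing cell centers; computing over cells rather
than aggregated regions is exactly equivalent by the weighted-mean
property and avoids an arbitrary regionalization. Displacements report
east/north components, the exact Euclidean distance, and an octant label
from 45° sectors centered on the eight compass directions. A zero-area
class has an undefined center and raises.

## Transformation model

Covariates: slope in degrees by Horn's 3×3 weighted finite differences
(edge replication at borders); elevation directly from the DEM (m);
Euclidean distance from cell center to the nearest built-up cell (km);
and a categorical built-up growth rate — per administrative zone, the
geometric average annual rate r = (A_t1/A_t0)^(1/years) − 1 (arithmetic
variant available), binned into five levels at 5/10/20/35 % (left-open,
right-closed) and broadcast to the zone's cells. Level 1 is the dummy
reference; levels 2–5 get indicators.

Samples are drawn uniformly without replacement from cells ecological at
t0; the outcome is y = 1 if the cell is still ecological at t1. Fitting
the *persistence* probability and reporting the *transformation*
probability as P = 1 − σ(z) keeps the two published conventions
consistent: the same linear predictor z serves both, and a positive
distance coefficient in z means remote cells persist. Maximum likelihood
uses Newton/IRLS (tolerance 1e-8 on the log-likelihood, 100 iterations);
forward stepwise entry admits, at each step, the candidate with the
largest likelihood-ratio improvement if its χ²(1) p-value is below 0.05.
Perfect separation raises an error naming the separating variable.
Validation classifies a holdout at threshold 0.5 (configurable) into a
2×2 observed×predicted matrix with per-row accuracies, overall accuracy
and Cohen's κ, all exact rationals of the counts.

Probability maps evaluate P over ecological cells (others masked) and
classify it at the fixed cuts 0.1/0.3/0.45/0.65. The published breakpoint
values are used as fixed cuts rather than re-estimated natural breaks so
the levels are bit-reproducible across runs.

The packaged default coefficients of the transformation equation are
z = 0.069·slope + 0.033·elevation + 0.473·distance − 1.079·level4 −
0.963·level5 − 0.853, the published estimates for the reference study
system; at the origin this gives P = 0.7012, which the tests pin down.

## Synthetic scenarios

The generator emulates a coastal urbanizing land system, not any specific
geography:

- **Landscape**: capacity-constrained multi-seed region growing. Each
  class receives a cell quota equal to its requested proportion (largest
  remainder) and a seed count that shrinks as the cohesion parameter
  rises; regions grow in random heap order until quotas fill. Realized
  proportions therefore match requests to rounding while patches stay
  cohesive; cohesion 0 degenerates to independent per-cell draws.
  Default proportions put the ecological share at 0.56, dominated by
  woodland (0.34) and rivers/shallow water (0.16), with built-up at 0.14
  — mirroring the reference system's initial composition.
- **DEM**: a seeded sum of 6 Gaussian bumps, amplitude ≤ 120 m — smooth,
  nonnegative, with hills the slope operator can resolve at 30 m.
- **Zones**: a Voronoi partition of 13 random sites (mirroring the
  reference system's 13 administrative units), each carrying a growth
  level 1–5; all five levels are represented when there are ≥5 zones.
- **Change**: each ecological cell converts to built-up with probability
  σ(α* + β*·x) on its covariates. Default truth: α* = −1.0,
  β*_slope = −0.10/°, β*_elev = −0.02/m, β*_dist = −0.80/km,
  β*_level4 = +1.0, β*_level5 = +1.3 — conversion concentrated on low,
  flat cells near built-up land in fast-growing zones, producing
  per-period ecological losses of roughly 10 %, inside the 14–25 % range
  the observed transition statistics span. Gains (non-eco → eco) are a
  config flag, off by default: the fitted model concerns losses.

What the generator does **not** emulate: realistic geomorphology or
hydrography, autocorrelated conversion (draws are independent given the
covariates), classification error, multi-class conversion pathways, and
zone growth levels derived from the simulated built-up change itself
(levels are assigned, not measured). Passing tests therefore demonstrate
the correctness of the estimators and the identifiability of the
conversion model under its own assumptions — not robustness to the
misclassification and spatial dependence of real mapped data.

## Problem sizes and determinism

The reference scenario is 128×128 cells at 30 m (14.75 km²) over four
dates — large enough that every stage (≈660 patches, ≈9000 ecological
cells) is exercised meaningfully while the full analysis chain runs in
seconds. Parameter-recovery checks use 192×192 single-period scenarios so
that 20,000 training samples can be drawn, and verify each fitted
coefficient within 3 estimated standard errors over 20 seeds. All
randomness flows from a single `numpy` Generator seeded in the config and
spawned per stage, so every artifact — rasters, CSVs, reports — is
byte-reproducible under a fixed seed.

## Known limitations

- The published absolute metric tables, fitted −2LL/χ² and class-mean
  probabilities of the reference study depend on its actual mapped
  rasters and are out of reach at desk scale; the package reproduces the
  printed arithmetic and the method, not those absolute values.
- Published aggregate series mix conventions (an average equivalent area
  above 1 is impossible under normalized δ); the implementation follows
  the equation as defined and documents the discrepancy rather than
  imitating it.
- The logistic model assumes independent Bernoulli outcomes given
  covariates; no spatial autocorrelation correction is provided.
- No reprojection/resampling: inputs must already be co-registered.
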