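# Methods

## The model

`esvland` couples three standard pieces of land-system analysis into one
tested pipeline: a Markov chain over land-cover class areas, a cellular
automaton (CA) that gives the projected areas a spatial expression, and a
benefit-transfer valuation that prices the resulting landscapes.

### Markov area dynamics

Land cover is a 6-class categorical raster. Cross-tabulating two dated
maps gives transition areas A_ij (km² moving from class i to class j over
the calibration interval); row-normalising yields the row-stochastic
transition-probability matrix A, and class areas evolve as
S_{t+1} = S_t · A. One application of A advances the chain by one
calibration period; the matrix is *not* silently rescaled to other
intervals. `rescale_period` exposes matrix powers explicitly and records
an approximation note when the target is not an integer multiple of the
period; continuous-time embedding via the matrix logarithm is out of
scope (it is ill-posed for many empirical matrices).

Degenerate inputs: a class absent at the start date produces a zero row,
which is replaced by the identity row — the absent class trivially
persists. Any other convention is unfalsifiable from the data, and this
one keeps A row-stochastic so that total area is conserved exactly under
projection.

### CA allocation

The Markov step says how much area each class gains or loses; the CA says
where. Per projection step:

1. target areas come from the Markov projection of the current map's
   area vector;
2. targets are converted to whole-pixel quotas by largest-remainder
   (Hamilton) rounding, so quotas sum exactly to the number of valid
   pixels;
3. each pixel's score for converting from its current class i to class j
   is A_ij × s_j, where s_j is the fraction of class-j pixels in the
   (2r+1)×(2r+1) window centred on the pixel (edge-truncated, nodata
   excluded from numerator and denominator). The default radius r = 2
   (a 5×5 window) is the classical CA-Markov contiguity filter. No
   ancillary suitability layers (elevation, roads, climate) are used —
   contiguity-only suitability is the defensible default when no such
   layers are specified;
4. (pixel, class) pairs are visited in descending score order and each
   unassigned pixel takes the best class whose quota is unfilled. A
   seeded additive jitter of ε = 1e-9 breaks ties; it is the only
   stochastic element, so a fixed seed gives pixel-identical maps and
   different seeds can differ only in pixel arrangement, never in class
   areas.

Realised class counts therefore equal the rounded quotas exactly; the
`quota_tolerance` parameter (default 0.01, relative to total area) only
guards against pathological target/landscape mismatches. One allocation
pass per projection step is the default (`iterations = 1`); additional
passes recompute suitability from the evolving map under the same quotas.

### Validation

Map agreement uses the chance-corrected Kappa,
κ = (P₀ − P꜀)/(1 − P꜀), with P₀ the observed proportion of agreeing
pixels and P꜀ = Σᵢ rowᵢ·colᵢ / N² the agreement expected from the two
maps' marginals. Nodata is excluded pairwise. The degenerate case
P꜀ = 1 (two identical single-class maps) is reported as κ = 1 with a
flag. The conventional 0.70 pass threshold is a configurable report
field, not hard-coded logic. Per-class Kappa and quantity/allocation
disagreement decompositions are deliberately not implemented.

### Valuation

The valuation is the bilinear form ESV = Σᵢ Aᵢ·VCᵢ (per class) and
ESV_f = Σᵢ Aᵢ·VC_if (per service function), with VC a 9-function ×
6-class coefficient table in yuan·hm⁻²·a⁻¹. The table is anchored to the
regional equivalent factor

    E_a = (1/7) Σ_c M_c · p_c · q_c / M

over the grain crops c (rice, wheat, corn) with sown areas M_c (hm²),
prices p_c (yuan/t) and yields q_c (t/hm²): one standard equivalent unit
is one seventh of the economic value of a hectare's average annual grain
output. Built-up land carries negative coefficients (replacement cost of
degraded water-supply and waste-treatment services); the bilinear form
needs no special-casing for signs.

Bilinearity gives the exact identities the tests rely on: the
per-function values sum to the per-class total; zone totals sum to the
landscape total for any partition of the valid mask; doubling all areas
doubles every value.

**Unit convention.** Coefficient tables of this kind are per-hm² while
area tables are printed in km². Published summary tables in this
literature multiply the two directly on the 10⁸-yuan reporting scale —
i.e. omit the km²→hm² factor of 100. Rather than silently adopting
either reading, the package declares a `unit_convention` on every
result: `"paper-table"` (default; reproduces the published reporting
scale digit-for-digit) and `"strict-si"` (converts km²→hm² first;
values exactly 100× larger). Report tables round half-up to 2 decimals
on the 10⁸-yuan scale, matching the printing convention of the bundled
tables. The bundled cropland recreational-culture coefficient is kept at
its printed 3-decimal value 13.049.

The bundled reference tables (`esvland.study`) carry one further known
blemish: the printed per-class "Total" coefficient row deviates from the
column sums by up to 0.02 (the printed cells are themselves rounded to
0.01), so the consistency check uses a 0.025 tolerance; and four of the
54 per-function summary cells differ from the exact bilinear arithmetic
by one unit in the last printed digit. The package always reports the
exact arithmetic.

### Sensitivity

The coefficient of sensitivity CS_k is the standard elasticity: scale
class k's entire 9-function coefficient column by (1 + δ) (default
δ = 0.5, i.e. ±50%), recompute the total, and divide the relative change
of the total by δ. For a linear valuation CS_k equals class k's signed
share of total ESV and is independent of δ — both are asserted to 1e-12
rather than assumed: the implementation re-values with the perturbed
table, so the identity is a genuine cross-check. Whenever two or more
classes carry positive value, every CS_k < 1: the total is structurally
inelastic to any single class's coefficient, which is what makes
benefit-transfer totals robust to coefficient uncertainty.

## Synthetic data

The generator emulates what a multi-date Landsat-derived class raster
supplies, with known ground truth:

* `generate_initial` draws pixels i.i.d. from a target class-proportion
  simplex. The default mix (4% forest, 43% grassland, 11% cropland, 3%
  water, 1% built-up, 38% unutilized) is a plausible arid-basin
  composition: grassland slopes and desert dominant, an irrigated
  cropland belt, scarce water and settlement. `autocorrelation = r > 0`
  majority-filters the field over a (2r+1)² window to create contiguous
  patches for the CA's contiguity filter to exploit.
* `evolve` resamples every pixel independently from its class's
  transition-matrix row, so expected class areas follow the Markov
  projection exactly. This per-pixel independence is the stated
  statistical idealisation under which estimator-recovery tests are
  exact; real land change is spatially dependent, so passing recovery
  tests demonstrates correctness of the estimator under its model, not
  fidelity of any real-world calibration.
* `generate_zones` tiles the raster into contiguous rectangles (as
  square a tiling as the zone count allows), standing in for
  administrative regions in zonal accounting.

Two consequences worth knowing. Majority filtering shifts proportions
toward majority classes and can extinguish a ~1%-share class entirely;
the estimator then correctly returns an identity row for the absent
class, which differs from the generating row — recovery tests therefore
use unfiltered (i.i.d.) fields. And transition-matrix recovery error
scales like the per-row binomial error, so rare classes dominate the
max-abs error; at 10⁵ pixels with ≥10% shares the 3-seed median max-abs
error stays below 0.02.

## Problem sizes and determinism

Statistical tests use 250×400 (10⁵-pixel) fields — large enough that
3-standard-error binomial bounds are tight — and the end-to-end contract
runs a 200×200 landscape with two calibration dates and two horizons,
which completes in seconds. All randomness flows through explicit seeds
(`numpy.random.default_rng`); a fixed config and seed give byte-identical
CSV and raster outputs, which the tests assert by file comparison.

## I/O choices

ESRI ASCII grid is the primary raster format (plain text; carries cell
size, origin and nodata in its header). Single-band TIFF is supported
through `tifffile`, with the cell size supplied by the caller since plain
TIFF stores no georeference; geo-tagged GeoTIFF metadata is passed over,
not interpreted. Tables (areas, coefficient matrices, transition
matrices, reports) are CSV via pandas. Run configs are YAML key-value
files with a version field; unknown keys are rejected rather than
ignored.

## Known limitations

* Suitability is contiguity-only; multi-criteria transition potentials
  (terrain, accessibility, policy constraints) are out of scope.
* The Markov chain is first-order and stationary; applying a calibrated
  matrix to later periods assumes the drivers of change are unchanged.
* Valuation is static benefit transfer: no inflation adjustment,
  discounting, demand-side effects or biophysical process modelling.
* Published sensitivity tables in this literature are not always
  internally consistent with the elasticity definition; the package
  computes the standard elasticity and its exact identities rather than
  attempting to reproduce any inconsistent printed variant.
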