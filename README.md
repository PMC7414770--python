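# esvland

Land-use/land-cover change (LUCC) simulation and ecosystem-service
valuation for categorical rasters.

`esvland` is aimed at landscape ecologists and land-system modellers who
work with multi-date categorical land-cover maps (e.g. six-class Landsat
interpretations: cropland, forestland, grassland, water body, built-up
land, unutilized land) and want, in one tested pipeline:

* **CA-Markov land-change simulation** — a first-order Markov chain
  S<sub>t+1</sub> = S<sub>t</sub>·A over class areas, with the
  row-stochastic transition matrix A estimated from a cross-tabulation of
  two dates, coupled to a cellular automaton that allocates the projected
  areas spatially by neighbourhood suitability (a contiguity filter) under
  exact per-class pixel quotas;
* **Kappa validation** — chance-corrected map agreement
  κ = (P₀ − P꜀)/(1 − P꜀) between simulated and observed maps;
* **Equivalent-factor ESV accounting (benefit transfer)** — the bilinear
  valuation ESV = Σᵢ Aᵢ·VCᵢ and ESV_f = Σᵢ Aᵢ·VC_if with a 9-function ×
  6-class coefficient table anchored to the regional equivalent factor
  E_a = (1/7)·Σ꜀ M꜀p꜀q꜀/M (one seventh of the economic value of a
  hectare's average annual grain output), including per-zone accounting,
  change rates and contribution shares;
* **Coefficient sensitivity** — the elasticity CS of total ESV to ±50%
  perturbations of each class's coefficient column (CS < 1 ⇔ the estimate
  is robust to coefficient uncertainty);
* **Synthetic landscapes** — seeded generators for multi-date categorical
  rasters whose pixel transitions follow a prescribed matrix, so every
  stage is testable with known ground truth.

A reference coefficient table and six-date area series for an arid
economic zone on the northern slope of the Tianshan mountains
(1980–2030) are bundled (`esvland.study`) and drive the tables-only
reproduction path.

## Worked example

```python
import esvland as e

coeffs = e.study.study_coefficients()          # 9 functions × 6 classes, yuan/hm²/yr
areas  = e.study.study_area_table(1980)        # per-class areas, km²

result = e.compute_esv(areas, coeffs)          # default "paper-table" convention
print(result.report())                         # 10^8 yuan, rounded half-up
print("total:", result.report_total())
print(e.contribution_shares(result).round(2))
```

prints

```
forestland         1.06
grassland          3.87
cropland           0.92
water body         1.86
built-up land     -0.08
unutilized land    0.20
dtype: float64
total: 7.83
forestland         13.56
grassland          49.43
cropland           11.76
water body         23.71
built-up land      -1.07
unutilized land     2.61
dtype: float64
```

i.e. a total ecosystem-service value of 7.83 × 10⁸ yuan in 1980, with
grassland contributing 49.43% and built-up land a small negative value
(it is valued by the replacement cost of the water-supply and
waste-treatment services it degrades).

A synthetic end-to-end run — generate a two-date landscape under a known
transition matrix, calibrate, simulate two horizons, validate with Kappa,
and value everything:

```python
import numpy as np
A = np.full((6, 6), 0.05 / 5); np.fill_diagonal(A, 0.95)
cfg = e.RunConfig(
    output_dir="demo_run", mode="synthetic", seed=123, horizons=[2010, 2015],
    synthetic=dict(shape=(200, 200), autocorrelation=1,
                   transition_matrix=A.tolist(), dates=[2000, 2005]),
    n_zones=4,
)
e.run(cfg)   # writes CSV reports, simulated .asc rasters and run_log.txt
```

The same workflows are available from the shell:

```bash
esvland reproduce-tables --out reproduction
esvland value --areas my_areas.csv
esvland simulate --raster-a a.asc --raster-b b.asc \
    --date-a 2000 --date-b 2005 --horizon 2010 --horizon 2015
esvland validate --reference observed.asc --simulated simulated_2010.asc
```

### Unit convention

Coefficient tables of this kind are stated per hm² while area tables are
commonly printed in km²; published summary tables in this literature
multiply the two directly on the 10⁸-yuan scale (omitting the km²→hm²
factor of 100). Both conventions are supported — `"paper-table"`
(default, reproduces the published reporting scale) and `"strict-si"`
(areas converted to hm² first, values 100× larger) — and every result
records which one produced it.

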