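# Methods

`nitraqua` implements a complete groundwater-nitrate survey workflow:
laboratory QA/QC indicators, descriptive and inferential statistics over
climate zones and land uses, four spatial interpolators compared by
leave-one-out cross-validation, and two parametric vulnerability indices
(IPNOA for agricultural sources, IPNOC for sewer leakage). This note
records the models, the defaults and the genuinely open design choices.

## Coordinate model and data contracts

All coordinates are planar projected metres; every distance in the
package is Euclidean. No geodesy, reprojection or raster formats beyond
ESRI ASCII are supported. A well sample carries a closed vocabulary of
labels (climate: arid/semi-arid; land use: agricultural, steppe,
residential, mixed; season: spring/summer) — unknown labels are rejected
at construction, because the survey design defines the admissible
classes (there are, for instance, no industrial stations). The raster
container stores row 0 as the northernmost row with a lower-left-corner
georeference, matching the ESRI ASCII convention verbatim; values are
written with 10 significant digits so write→read round trips are exact
to well below 1e-4 mg/L.

## QA/QC statistics

* **Precision** is the relative standard deviation sd/mean of a
  triplicate, with the sample (n−1) standard deviation. It is returned
  as a fraction by default (`as_percent=True` gives the ×100 form). Note
  that for n = 3 the sample sd is biased low by the factor
  c4(3) ≈ 0.886, so simulated triplicates with coefficient of variation
  cv centre their RSD on 0.886·cv, not cv.
* **Accuracy** is percent recovery of a certified reference. Two
  conventions exist in the literature: the reporting form B/A × 100
  (measured over certified — the one consistent with accepted recovery
  tables, and the default) and the error form (A−B)/A × 100, which is
  negative for over-recovery (`convention="eq2"`). The 85–115% lab
  acceptance window is flagged on the result.
* **Sensitivity** passes when the instrument detection limit is at or
  below one tenth of the water-quality objective (50 mg/L for nitrate in
  drinking water ⇒ limit ≤ 5 mg/L), boundary inclusive.
* The **two-sample comparison** uses the Welch (unequal-variance) t
  statistic with Welch–Satterthwaite degrees of freedom; the **land-use
  comparison** is a classical one-way ANOVA. Both statistics are
  computed from their defining formulas; two-sided p-values come from
  the t and F CDFs expressed through the regularized incomplete beta
  function (`scipy.special.betainc`), accurate to well below 1e-6.
  Degenerate inputs are resolved by convention: two zero-variance groups
  with equal means give t = 0, p = 1; an all-identical ANOVA is an
  error.
* The **wellhead protection radius** uses the volumetric
  calculated-fixed-radius balance r = √(Q·t / (π·n·H)) — pumped volume
  equals the pore volume of the protected cylinder.

## Spatial interpolation

All four interpolators are implemented from first principles; they share
exactness guarantees that the test suite enforces (constant fields are
reproduced by every method; exact interpolators return the observed
value at sample locations to 1e-6 mg/L; everything is translation
invariant). A target within 1e-9 m of a sample coincides with it.

* **Semivariogram.** The Matheron estimator
  γ(h) = Σ(z_i−z_j)²/2N(h) over distance bins; default maximum lag is
  half the largest pairwise distance. Model fitting is weighted least
  squares (weights = pair counts) over nugget, partial sill and range
  for spherical, exponential and gaussian models (practical-range
  convention for the latter two: γ reaches ~95% of the sill at the
  range). A deterministic multi-start grid of initialisations makes the
  fit bit-stable; when the optimal range falls below the smallest
  informative lag, the structure is indistinguishable from nugget and is
  folded into it.
* **Ordinary kriging** solves the (n+1)-dimensional system
  [[Γ, 1],[1ᵀ, 0]] with a Lagrange multiplier, so weights sum to one at
  every target (enforced to 1e-9). The matrix is LU-factorized once per
  sample set; observations at coincident locations are pre-averaged
  (the system is singular otherwise). The kriging variance is
  w·γ₀ + μ, clipped at zero.
* **IDW** uses weights ∝ d^(−π), default power π = 2 over all points,
  with an optional k-nearest restriction. Predictions are convex
  combinations of the data.
* **Thin-plate spline**: radial kernel U(r) = r² log r plus an affine
  trend, solved as the exact-interpolation saddle system; `tension > 0`
  adds a ridge on the radial coefficients, relaxing exactness into
  smoothing. Requires ≥ 3 non-collinear, distinct points.
* **Natural neighbour (Sibson)**: the weight of sample i is the area its
  Voronoi cell cedes to the cell of the hypothetically inserted target,
  normalized. Cells are built by successive bisector half-plane clipping
  (Sutherland–Hodgman on convex polygons) and intersected exactly;
  candidate neighbours come from the Delaunay triangulation of the
  augmented point set. Outside the convex hull the inserted cell is
  unbounded and the weights undefined, so the method returns
  nodata/NaN rather than extrapolating.

Gridding applies the chosen method at cell centres; natural-neighbour
cells outside the hull receive the −9999 sentinel.

## Cross-validation and ranking

Leave-one-out: each sample is predicted from an interpolator rebuilt on
the remaining n−1 points (for kriging without a user-fixed variogram,
the variogram is refit per fold). Error statistics are RMSE, %RMSE
(RMSE over the observed mean, stored as a fraction) and MRE (mean
absolute relative error). MRE divides by the observed value, so folds
with an observed 0 mg/L (possible after truncation in synthetic data)
are excluded from MRE only; natural-neighbour folds outside the reduced
hull are excluded from all statistics and counted. Methods are ranked
ascending by the chosen criterion, ties broken by the other criterion
and then alphabetically. LOOCV is definitionally identical to the naive
per-point refit loop; a test enforces exact equality.

## Hazard indices

**IPNOA**: HI = (HF_f + HF_m + HF_s) · CF_n · CF_c · CF_ap · CF_i. The
band tables (fertilization rates → 1–5 scores; soil-N, irrigation,
climate and agronomic-practice multipliers; the six classification
bands) ship in an editable packaged YAML. Open points resolved here:

* *Absent fertilization.* The published band table assigns score 1 to a
  zero application rate, but the published per-land-use indices are only
  internally consistent if an absent fertilizer contributes 0 to the
  hazard sum (e.g. 6 = 3 + 3 + 0 for agricultural land). Default
  `absent_as_zero=True`; the literal table behaviour is available.
* *Rate ranges* score at their midpoint (70–120 kg/ha → 95 → score 3).
* *Climate factor.* Rows are evaluated in printed order; the first whose
  rainfall AND temperature bands both match wins. The table is not
  total: an arid site (≪ 600 mm) at 13 °C matches no row, so the
  fallback takes the first row matching rainfall alone (then the nearest
  rainfall band), flagged on the result; for this study's conditions
  that yields 0.98.
* *Agronomic practice.* The source table interleaves tillage and
  fertilization-type columns over one score column. Default: CF_ap is
  the fertilization-type score (fertirrigation 1.04 … localized 0.96),
  no-tillage taking its own 0.94 row; a product-of-both-columns variant
  is exposed as an exploratory option.
* *Classification.* The printed bands have small gaps (…3.18 | 3.19…); a
  value in a gap takes the lower band's level, and values outside
  [2.54, 17.66] clamp to levels 1/6 with an out-of-table flag. The
  strict bands classify HI 3.05 as level 1 although the source reports
  class 2 for that value; a reverse-engineered "paper_compat" band
  table (class-2 lower edge dropped to 3.05) is packaged for comparison
  and asserted nowhere.

**IPNOC**: per zone, the age-adjusted leakage fraction
L_c = L_e · age/life multiplies the transiting nitrogen load
N_i (= inhabitants · per-capita N · infiltration when not given) and the
pipe length L_i. The literal sum Σ L_c·N_i·L_i has units kg·m/year —
dimensionally odd but computed as published — and a per-metre-normalized
variant (kg/year) is returned alongside. No established mapping from
N_y to the six-class scale exists, so classification requires a
user-supplied breakpoint table.

## Synthetic data generator

The generator emulates the study design: n wells (default 162) uniform
over a 60 × 40 km plain; land-use labels assigned in contiguous
west-to-east blocks with largest-remainder counts matching the design
proportions (41/17/18/24%), so class means create spatial patterning;
the northern 74.7% of wells are semi-arid. Nitrate is the land-use mean
(22.45/21.05/26.58/29.43 mg/L) plus one draw of a zero-mean Gaussian
random field (spherical variogram; covariance C(h) = psill·ρ(h) with the
nugget on the diagonal only, Cholesky factorization with a jitter
ladder) plus iid N(0, noise_sd²) measurement noise, truncated at 0. A
single root `SeedSequence` fans out to location/field/noise substreams,
so outputs are pure functions of the spec and adding a draw never
perturbs earlier ones.

The packaged scenario's sill (nugget 20 + partial sill 240 (mg/L)²,
range 12 km, noise sd 2) and default seed were calibrated once so the
default draw spans the observed concentration range (≈5–77 mg/L). Two
features of real nitrate data are deliberately not emulated: the
right-skewed (lognormal-like) marginal distribution — the additive
Gaussian model is symmetric, so matching the observed maximum requires a
larger spread than the observed sd, and low tails truncate at 0 — and
any real hydrogeology (flow paths, recharge, depth effects). Passing
tests therefore demonstrate correctness of the estimators on fields
with known geostatistical structure, not fidelity to the real aquifer.

Triplicate QA data are Normal(true·(1+bias), (cv·true)²) floored at 0.

## Numerical choices and problem sizes

Coincidence tolerance 1e-9 m; kriging-weight sum tolerance 1e-9;
TPS sample residuals < 1e-6; variogram fits run `least_squares` to
1e-14 tolerances from a fixed start grid. Test problem sizes are kept
at survey scale or below (12–200 points; 50-seed averages for
distributional checks; a 1000²-pixel discretized-area oracle for the
Sibson weights) — sizes chosen so each check is statistically
informative while the whole suite runs in seconds. Because single-
realization variogram-range estimates are intrinsically noisy at
n = 200, the recovery check asserts the median error over ten fixed
seeds rather than a single draw.

## Known limitations

* Interpolators are 2-D and isotropic; no universal/co-kriging, no
  anisotropy, no 3-D.
* Natural-neighbour LOOCV loses the hull points of each fold by design.
* The IPNOC index has no defensible absolute scale (units ambiguity
  above); treat it as a relative screening quantity.
* The climate control-factor table is not total over climate space;
  fallbacks are flagged but remain heuristic.
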