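# Methods

This note documents the models and procedures implemented in `estuaryuse`,
the defaults chosen where the analysis conventions left the design open, and
what the synthetic experiments do and do not establish.

## Geodesy and coordinates

All distances are great-circle kilometres on the WGS84 mean Earth radius
(6371.0088 km). Over the ~150 km study extent the spherical approximation
differs from the full ellipsoidal geodesic by far less than Argos location
error, and the package's own tolerance tests (1° of latitude = 111.2 ±
0.5 km) hold with margin. Planar work — kernel density estimation, alpha
shapes, strip geometry — runs in a local azimuthal-equidistant projection
centred on the river mouth (Port Nelson, 57.0552° N, 92.5967° W), which
preserves distances from the centre exactly; the inverse projection is an
exact round trip. Coordinates stay geographic (lon/lat) at every module
boundary.

## Track quality control

Raw Argos fixes are filtered in three idempotent, order-preserving stages:

* **Dedupe** — one fix per duplicate-message group (same whale and
  timestamp, or an explicit group key): the best location class wins
  (3 > 2 > 1 > 0 > A > B > Z), ties break to the earliest receipt.
* **Quality** — only "guaranteed" classes 3/2/1 are retained by default;
  class Z and unknown symbols fail the screen (unknown symbols raise, naming
  the record).
* **Speed** — a forward single pass per whale: a fix is dropped when the
  great-circle speed from the last *retained* fix is ≥ 3.5 km/h (the
  sustained-travel ceiling used for this species); the first fix is always
  kept. A forward filter was chosen over root-mean or backward-looking
  variants because it is deterministic, O(n), and independent of later data.
  Zero/negative time gaps imply infinite speed and drop the later fix.
  Dedupe runs before the speed screen (the reverse order is not meaningful
  for duplicate message solutions).

The QC report asserts monotone stage counts. Retention on real data is a
joint property of the raw class mix and movement; on the synthetic defaults
it comes out near 28%, dominated by the ~35% guaranteed-class probability.

## Daily aggregation and covariates

A whale-day is summarised by the componentwise median of its fix lon/lat
(UTC calendar days). Distances to the river mouth and the nearest shoreline
are evaluated at that median point; taking instead the daily median of
per-fix distances is supported (`distance_of="fix"`), since either reading
of "median daily distance" is defensible. The shoreline distance densifies
the polyline to ≤ 100 m vertex spacing in the projected plane before the
point-to-segment minimisation. Cross-whale pooling of a day's distances is
the median by default, with the mean available. Missing whale-days (the
duty cycle guarantees some) stay missing — never zero, never interpolated.

## Change point (cumulative sign test)

Day *t* of the pooled distance series scores −1/0/+1 by comparison with the
overall series median (ties score 0, avoiding directional bias and letting a
constant series degenerate gracefully to a flagged all-zero trace). The
change point is the earliest day at which |cumulative score| peaks. Two
properties matter for interpretation:

* The statistic peaks where the series crosses its overall median, i.e. at
  the **last** predominantly-below-median day. For a residency→migration
  step the reported day is therefore the final residency day, one day
  before the first migration day.
* The overall median — and hence the crossing — depends on the observation
  window. A window heavily unbalanced around the transition drags the
  median into one regime and biases the estimate toward balancing the two
  sides. The synthetic season (10 Jul–9 Sep) brackets the configured switch
  (day 221) roughly symmetrically, matching the estuarine season the
  analysis targets; users applying the test to other windows should check
  this balance.

The recovery harness (`changepoint.recover_switch`) runs the *entire*
pipeline per replicate (simulate → QC → daily medians → pooled series →
change point) and reports bias and MAE against the configured switch day; at
the default noise the MAE is ≈1 day over 100 replicates.

## Hydrology

The seasonal mean is the arithmetic mean of daily discharge over 14 July–
31 August (49 days, inclusive; up to 10% of days may be missing, with a
warning). The baseline is the mean of yearly seasonal means over the
reference period — "averaged by year", not a grand mean of days, so years
with small gaps weigh equally. A year is wet iff its percent deviation from
baseline is strictly positive; the threshold is exposed for sensitivity
analysis but defaults to zero (years at the average count as dry). The
percent deviation is reported both unrounded and integer-rounded.

## Kernel utilization distributions

The UD is a fixed-kernel density with an isotropic bivariate normal kernel
on projected km coordinates, evaluated exactly (no binned approximation) on
a regular grid, 1 × 1 km cells by default. A single scalar bandwidth is
used; nothing in the workflow requires per-axis smoothing and the isotropic
kernel keeps LSCV one-dimensional. The LSCV criterion is closed-form for
Gaussian kernels (the kernel convolved with itself is a kernel at h√2):

    LSCV(h) = ∫f̂² − (2/n)Σᵢ f̂₋ᵢ(xᵢ)

scanned on a 60-point log grid over [0.05, 2] × h_ref (h_ref = σ·n^{−1/6}),
then refined by bounded minimisation between the best grid neighbours.
Minima pinned at the lower bound (duplicate-heavy data drive h → 0) are
clamped with a warning. The auto-grid covers the points with a 3h margin,
enlarged until kernel-mass truncation is below 10⁻³, and the density is
renormalised so total mass is 1 ± 10⁻⁶ by construction.

Probability contours accumulate cells in descending density order until the
target mass is reached; contained mass therefore lies within one cell's mass
above the level, and contours are nested by construction. The geometric
mean of locations is computed per axis after a false-origin shift making
every coordinate strictly positive (the shift is removed afterwards); the
centre of mass is the density-weighted mean cell centre over the 95%
contour.

The estuary polygon is an alpha shape: Delaunay triangles with circumradius
≤ α (default 15 km) unioned; α → ∞ recovers the convex hull exactly, and
degenerate inputs fall back to the convex hull with a warning. The α
default was set so the funnel fixture's occupancy excludes the unoccupied
land-side wedge that a convex hull would bridge; the original bounding
procedure is not recoverable, so α is a free parameter and is always
echoed in output. The summary reports area, offshore extent (maximum
boundary projection on the seaward estuary axis, default bearing 35°), and
the length of shoreline within 5 km of the polygon.

## AR1 regression and model ranking

Log distances are modelled as y = Xβ + e with AR1(φ) errors *within whale*
and independence between whales. Whale identity serves both as the AR1
blocking factor and (by default) as fixed treatment-coded effects; a "random
effect fitted by gls" is not a coherent specification, and blocking + AR1
reproduces the correlation structure actually intended. The likelihood is
exact Gaussian: the Prais–Winsten transform whitens each block (first row
scaled by √(1−φ²), later rows quasi-differenced), β and σ² are profiled out
by OLS on the transformed data, and φ is found by bounded scalar
minimisation on (−0.99, 0.99). With φ fixed at 0 the fit reduces exactly to
OLS (verified against statsmodels to 10⁻⁶). Non-convergence is reported on
the fitted object, never silently replaced.

AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) with n the number of whale-day rows in
the fitted data (always echoed, since sample size conventions vary); k
counts regression coefficients plus the innovation variance plus φ when
estimated. Akaike weights are exp(−Δ/2) normalised over the candidate set.
The Durbin–Watson statistic Σ(Δe)²/Σe² is provided separately from
likelihood machinery (the two are distinct procedures); the whitened
residuals of a correct AR1 fit score ≈2. Quartile summaries use linear
interpolation between order statistics (numpy's default), stated here
because percentile conventions differ across software.

The collinearity screen flags |Pearson r| ≥ 0.6 pairs and VIF > 3
covariates; constant covariates report infinite VIF rather than crashing.

## Surveys

Coverage is 2·(strip half-width)/spacing, capped at 1 — with the default
0.35 km half-strips and 3.7 km spacing, 18.9% ("ca. 19%"). Each 1-km
interval of a transect (≈15 s of flight), both observer sides pooled, is
one 1.0 × 0.7 km block (0.7 km²; a whale count c gives density c/0.7 per
km²). Empty intervals are emitted as zero-count blocks: absence is data for
density models. The density-weighted distance treats each counted whale as
one observation of its block's distance (weighted mean with SE from the
count-weighted variance). The abundance index is total count divided by
coverage, explicitly uncorrected for perception or availability bias.
Density models are Poisson GLMs with log link and offset log(0.7), ranked
by QAICc with the Pearson-χ²/df dispersion of the richest candidate and one
extra parameter for the dispersion; "quasi-Poisson + AICc" has no unique
convention, so this one is stated and tested. The effective strip
half-width is 350 m; the observers' 100–450 m scan band is retained as
design metadata only.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical *structure* the analysis assumes,
with defaults fixed from the study conditions: 13 whales, season 10 Jul–
9 Sep, switch day 221; Argos classes with probabilities
{3: .08, 2: .12, 1: .15, 0: .20, A: .20, B: .25} and 1σ errors
0.25/0.5/1.5/5/10/20 km (the guaranteed band matches the documented
250 m–1.5 km accuracy; 0/A/B exist to exercise the filter); Poisson duty
cycle around 12 fixes/day so missing whale-days occur; discharge year means
{2002: 3131, 2003: 2165, 2004: 2831, 2005: 5163} m³/s around the 3331
baseline, i.e. the deviation pattern −6/−35/−15/+55%; M2 tide (12.42 h)
with 14.77-day spring/neap envelope.

Residency is a discrete-time mean-reverting (OU-like) walk whose stationary
per-axis SD equals `residency_sd_km` (default 6 km) around a centre ~50 km
seaward of the mouth — placing daily median mouth-distances near the ~50 km
dry-year medians reported for this system; the reversion timescale is 0.5
day. Migration is a straight drift at 40 km/day (≈1.7 km/h, sustainable
under the 3.5 km/h QC gate) along bearing 35°. Tide coupling is a
cross-shore displacement proportional to tide height (default −1.5 km/m:
shoreward at high tide, matching greater estuary use on the flood); it is a
phenomenological stand-in, not a hydrodynamic mechanism. No movement model
was published, so these are convenience defaults, not estimates.

Consequently, passing synthetic tests establishes that the *machinery* is
correct — filters match brute-force oracles, the KDE equals the naive
kernel sum to 10⁻¹⁰, estimators recover known parameters without bias, the
change point recovers a known switch day — not that the published field
estimates are reproducible: raw telemetry and survey data were never
deposited, and quantities like the 29% retention or the published model
coefficients depend on them. Published *arithmetic* (percent deviations,
coverage, AICc and weight columns) is reproduced exactly from its printed
inputs.

## Problem sizes and numerical choices

Simulation experiments use 100 replicates (change-point recovery: 13 whales
× 61 days; AR1 recovery: 5 whales × 200 days), sizes at which Monte-Carlo
standard errors are small enough to detect meaningful bias while the full
suite stays fast. Ties: best-class dedupe → earliest receipt; |cumsum|
argmax → earliest day; sign scores at the median → 0. Degenerate inputs:
constant series → flagged degenerate change point; single-vertex shoreline
→ point distance with warning; collinear hull input → convex-hull fallback
with warning; zero strip width → zero counts with warning. All generators
are deterministic given their seed (numpy `default_rng` with derived
per-component seed sequences).

## Known limitations

* Spherical rather than ellipsoidal geodesy (error ≪ Argos noise at this
  scale, but not suitable for global reuse).
* The AR1 model assumes regular daily spacing within whale; gaps from the
  duty cycle are treated as adjacent steps rather than powered by the gap
  length.
* The change-point estimator inherits the window-balance sensitivity
  described above.
* The quasi-Poisson QAICc ranking depends on which model supplies the
  dispersion estimate; the richest-model convention is used throughout.
* No perception/availability correction, state-space re-estimation of
  positions, or hydrodynamic plume modelling — all out of scope by design.
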