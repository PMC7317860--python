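# Methods

This note documents the statistical procedures implemented in
`effortshift`, the defaults chosen where the design was genuinely open,
and what the synthetic study conditions do and do not establish.

## Data model

Effort arrives as monthly records on 1°×1° cell centres (fishing hours
plus catch tonnage split into FAD and free-school operation modes);
SST anomalies arrive on the 5°×5° grid, in °C relative to the product's
own climatological baseline. Both are restricted to the closed study box
29°N–30°S, 35°W–19°E and placed on a gap-free quarterly axis
(quarter q of month m is ⌈m/3⌉): effort is *summed* within cell-quarters,
SSTA is *averaged*. The 1991–2017 study period therefore spans exactly
108 quarters.

Two conventions matter throughout:

* **Missing is not zero.** A cell-quarter with no effort record is a data
  gap, to be reconstructed by DINEOF — writing a zero there would
  fabricate anomaly structure. (A sensitivity mode treating absences as
  zero effort can be emulated by densifying the input records.)
* **No area weighting.** Regional means and EOFs weight all cells
  equally. The region straddles the equator, so cos(latitude) weights
  vary only modestly across the box; an option could be added, but equal
  weights keep eigenvalue bookkeeping exact and comparable.

Deseasonalisation subtracts, per cell and per quarter-of-year, the mean
over all observed years ("quarterly climatology over the entire data
period"). Anomalies plus stored climatology reproduce observed values
exactly; a cell/quarter-of-year stratum with no observation at all stays
missing and is logged. The alternate reading — one overall per-cell
mean — is not the default because it leaves the seasonal cycle in the
anomalies, where it would dominate the leading EOF.

## Centre of gravity

The annual COG is the effort-weighted mean latitude of all records of a
year, computed strictly north (lat > 0) and south (lat < 0) of the
equator; on the default half-integer grid no cell centre sits on the
equator. COG is translation-consistent, invariant to rescaling all
efforts, and bounded by the contributing latitudes — all three are
tested. Trends are plain OLS in degrees per year with a t-test p-value
(n−2 df); serial autocorrelation is deliberately ignored, matching the
simple-regression convention, and this is a known limitation (effective
sample sizes are overstated when residuals are autocorrelated). The SSTA
series paired with annual COG is the annual mean of the quarterly
regional-mean SSTA; other seasonal pairings are possible but the annual
mean is the least arbitrary.

## DINEOF

Series selection keeps grid cells with strictly less than 25 % missing
quarters. Reconstruction then iterates, for ranks k = 1…k_max: truncated
SVD of the current matrix, replacement of missing entries by the rank-k
reconstruction, until the relative RMS change at replaced entries falls
below 1e-5 (at most 500 sweeps; ranks that fail to converge are flagged
and excluded from selection). Rank selection hides 5 % of the observed
entries (at least 30) as a validation set, and picks the k with the
smallest validation RMSE. Two numerical choices deserve note:

* **No extra centring.** The input is an anomaly matrix, centred per
  cell and quarter-of-year by construction. Column means recomputed over
  per-column observed subsets are not constant across columns, so
  subtracting them raises the rank of an exactly low-rank field by one
  and biases the rank selection; the implementation therefore applies no
  additional mean removal.
* **Tie rule.** Validation RMSEs within (tolerance × field scale) of the
  minimum are indistinguishable; the smallest such rank wins. Without
  this, warm-started higher ranks win on noise-free fields by epsilon.

The final fill re-runs at the selected rank with validation entries
restored as observed. Observed entries are never altered, bit for bit.
A caveat: on a field with *no* low-rank structure (pure white noise) the
EM iteration has nothing to anchor on and converges too slowly for the
sweep cap; every rank is then flagged and the call errors out, which is
the correct diagnosis for such input.

## EOF analysis

EOFs are eigenvectors of the space × space covariance matrix (n−1
denominator) of the column-centred anomaly matrix; principal components
are the projections of the data onto them. Eigenvalues are clipped at
zero (rank-deficient inputs yield trailing zeros), variance fractions
are 100·λᵢ/Σλ, and Σλ equals the total anomaly variance to 1e-8
relative (tested). Because field variance is spatially uneven, the local
explained variance LCⱼᵢ = eⱼᵢ²λᵢ / Σ_{k≤kmax} λₖeⱼₖ² reports each
leading mode's share of the reconstructed variance at each cell; rows
sum to one wherever the leading-mode reconstruction carries variance,
with k_max = 3 by default. The covariance (not correlation) matrix is
used; detrending before the EOF is not applied.

**Sign convention.** An EOF is defined up to sign. Each mode is flipped
so its largest-magnitude spatial loading is positive, and its PC is
flipped along. This makes PC cross-correlations between two fields
reproducible; when validating against synthetic truth, estimated modes
are additionally oriented by the sign of their inner product with the
true mode, which resolves flips without touching magnitudes.

## Driver attribution

Seven predictors enter the two regression forests (responses: quarterly
effort in hours, and effortA PC1): regional SSTA mean, calendar quarter
(unordered 4-level factor), % catch on FADs, TAC presence, closure
presence, SFPA count, SFPA vessel allowance. The quarter factor is
dummy-coded (level 1 reference) both for GVIF and for the trees; its
three indicator columns are permuted jointly when its importance is
measured.

* **GVIF** (Fox–Monette): with R the correlation matrix of all
  dummy-coded predictor columns, GVIF_j = det(R_jj)·det(R_(−j)(−j)) /
  det(R); single columns reduce to the classical VIF, multi-column
  groups report GVIF^(1/2df) alongside. Values ≥ 6 are flagged; a
  singular R reports an infinite GVIF with a perfect-collinearity
  diagnosis.
* **Forests**: 1000 trees (enough to stabilise the OOB MSE — adding 500
  more moves variance explained by under a point), mtry = ⌊p/3⌋ = 2,
  minimum leaf 5, bootstrap sampling, fixed seed, listwise deletion of
  incomplete rows (counted). Variance explained is
  100·(1 − OOB-MSE/var(y)).
* **%IncMSE**: per tree, the MSE on that tree's out-of-bag cases is
  recomputed after permuting one predictor; the importance is the mean
  increase over trees as a percentage of the baseline OOB MSE. The
  classic alternative scales each predictor's increase by its SD over
  trees; that normalisation is implementation-specific, whereas a
  percentage of baseline OOB MSE is reproducible across languages, and
  rankings — which carry the scientific conclusions — agree between the
  two on the recovery simulations.
* **Partial dependence**: predictions averaged over all rows with the
  predictor forced to each grid value (20-point grid for continuous
  predictors, the level set for factors and flags).

A practical caveat established while testing: with mtry < p, trees are
sometimes forced to split on irrelevant predictors, and autocorrelated
covariates (random walks, ramps, AR(1) series) correlate spuriously
in-sample — so an "ignored" predictor's partial dependence is only flat
when that predictor is genuinely independent of the drivers.

## Synthetic study conditions

The generator targets the statistical structure the analysis assumes —
not ocean realism (no fronts, eddies or advection):

* **SSTA**: 108 quarters × 132 cells; orthonormal spatial modes with a
  near-uniform, sign-coherent leading warming pattern; variance
  fractions (70, 10, 5) % with the remainder white noise; per-cell
  anomaly variance 0.09 °C²; regional offset 0.4 °C; a linear trend whose
  slope is fixed by a 0.82 °C total rise over 1856–2017. PC driver series
  are orthogonalised and standardised exactly, so the targeted fractions
  are exact in-sample, not just in expectation.
* **Effort**: a fished footprint of ~48 5° cells (two latitudinal bumps,
  at 10°N and 12°S, times a longitudinal bump at 10°W, thresholded at
  25 % of the peak weight — the same order as the ~26 reconstructable
  series of real Atlantic purse-seine data). The anomaly field has a
  north/south dipole leading mode and a slowly decaying spectrum
  (19, 12, 9, 8, 7, 6, 5, 4) % plus 30 % white noise, per-cell SD 75 h.
  A slowly decaying spectrum is the realistic regime for geophysical
  fields; it also keeps the small variance deficit at DINEOF-filled
  entries (reconstructions carry less white noise than observations)
  from materially biasing the leading-fraction estimate. The effortA PC1
  is built by Gaussian copula to have *exactly* the configured sample
  correlation (default 0.5) with the SSTA PC1.
* **Positivity** is additive, not exponential: hours = seasonal
  baseline × footprint weight + anomaly, with the baseline floor six
  anomaly SDs above zero (rare negatives clipped, counted, and in
  practice absent). An exponential link would modulate the anomaly
  covariance by the squared baseline pattern and distort the targeted
  variance fractions; the additive form makes them exact.
* **COG drift** (−0.05 °/yr southern) is injected as a within-parent
  tilt: each 5° cell's total is disaggregated to its 25 1° children with
  latitude-tilted weights, the tilt solved numerically per year so the
  expected southern COG moves exactly linearly. The 5°×5° sums — the
  entire EOF side of the analysis — are invariant to the tilt by
  construction, so the drift cannot leak into the variance budget.
* **Missingness** is MCAR at 15 % of footprint cell-quarters, applied
  *after* the true totals are recorded, so DINEOF error can be measured
  against held-out truth with no circularity.
* **Covariates** follow the documented ranges: FAD share a monotone ramp
  plus noise clipped to [25.9, 91.7] %; TAC on from 1998; seasonal
  closures (quarters 4 and 1) from 1997; SFPA count and vessel allowance
  bounded integer random walks in [4, 10] and [25, 41]. Responses are
  linear combinations of standardised predictors plus Gaussian noise
  (noise SD = 0.5 × signal SD by default), rescaled to realistic
  location/scale (26 559 ± 7 361 h; 0 ± 2.2).

Everything is bitwise-deterministic under a fixed seed; sub-streams are
spawned per component, and the pipeline fans one global seed out to
per-stage seeds by fixed offsets recorded in the run summary.

**What passing tests show — and don't.** Recovery of the injected
fractions, correlation, drift and driver ranking demonstrates that the
estimators are implemented correctly and are unbiased at the study's
scale (108 quarters, tens of cells, the stated noise levels). It does
not validate the scientific conclusions on real data: real effort is not
Gaussian around a smooth footprint, missingness in fisheries data is
anything but MCAR (ports, seasons and regulations structure it), and
covariates co-trend far more strongly than independence-based p-values
assume.

## Problem sizes

Default analyses run at the study's own scale: 108 quarters, a 12×11
5° grid (~48 fished cells, ~330 k monthly records), DINEOF ranks up to
10, 1000-tree forests. Multi-seed recovery checks use 20 seeds (100 for
the null correlation check), chosen so the full suite exercises every
path at full problem size while remaining quick to run.

## Known limitations

* Trend and correlation p-values ignore serial autocorrelation.
* The DINEOF iteration is not suited to structure-free fields (see
  above) and its filled entries are mildly over-smooth, slightly
  inflating leading variance fractions (~1–2 points at 15 % missing).
* GVIF with near-singular designs is numerically delicate; determinants
  are computed via log-determinants and floored at the theoretical
  minimum of 1.
* The optional external-data path (real ICCAT effort tables and Kaplan
  SSTA files through the documented CSV/NetCDF formats) is exercised
  only by the format readers' tests, not by an end-to-end run, since no
  real data ship with the package.
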