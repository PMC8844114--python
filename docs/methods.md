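# Methods notes

## Dispersion in trait space

Traits are species-level means, standardized column-wise to zero mean and
unit *sample* SD (n−1), which matches the convention of the R ecosystem
this analysis style comes from and makes the toy column (1,2,3) map to
(−1,0,1).  The species–species Euclidean distance matrix is embedded by
principal coordinates analysis.  For a Euclidean input no correction is
applied and the embedding reproduces the distances to 1e−8.  Otherwise the
default correction is the Cailliez constant shift — the smallest c such
that adding c to every off-diagonal distance makes the matrix Euclidean,
computed as the largest eigenvalue of the standard 2n × 2n companion matrix
— with Lingoes (constant added to squared distances) as an option; the
applied constant is recorded on the `TraitSpace`.  Axes with eigenvalue
below 1e−10 of the leading one are dropped as numerical noise; no further
truncation is applied, so FDis uses the full corrected geometry.

FDis is the abundance-weighted mean distance to the abundance-weighted
centroid.  It therefore depends only on relative abundances, is invariant
under rigid rotations of the embedding, equals the weighted mean absolute
deviation in one dimension, and is zero for monospecific quadrats (which
are retained, not dropped; empty quadrats are missing).

## The null model and ZFDis

One taxa-label permutation is drawn per randomization and applied to the
whole plot — every quadrat, every scale, every trait set.  This is the only
scheme that keeps each species' plot-level total abundance and occurrence
frequency exactly fixed while permuting which species carries which traits;
per-quadrat independent shuffles would break that invariance and were
rejected.  ZFDis uses the sample SD (n−1) of the null draws.  Quadrats
whose null SD is zero (empty or monospecific) get a missing ZFDis and are
dropped pairwise downstream.

A subtlety worth knowing: the SES is *compressed* in quadrats with very few
species, because the null SD there is large.  Under extreme filtering a
quadrat loses species, so the most-filtered quadrats can show less extreme
ZFDis than moderately filtered ones.  This is a property of the statistic,
not a bug; the synthetic generator's defaults keep most quadrats out of
that regime.

Note also that ZFDis values across quadrats share the single observed
trait-to-species assignment, so they are not independent: the plot-wide
mean of ZFDis converges to zero only when species identities decouple
across quadrats (as in the random-assembly calibration), not for an
arbitrary community.

## Soil surfaces

Sampling design: grid nodes at every multiple of 30 m inside the half-open
plot (a 500 × 400 m plot gives 17 × 14 = 238 nodes), each paired with two
extra points at a distance drawn from {2, 5, 15} m in a uniform random
bearing, clipped to the plot — 714 planned samples for the reference
geometry.

No geostatistics package in the dependency set provides variogram fitting
and kriging, so both are implemented directly.  The empirical semivariogram
is binned to half the maximum pairwise distance (15 lags) and fitted by
weighted least squares with Cressie weights (pair count over squared model
value); the spherical model is the default, exponential and Gaussian (both
in the effective-range convention, 95% of the sill at h = range) are
options.  Ordinary kriging uses a global neighborhood — with at most ~700
samples one LU factorization serves all prediction points — and predicts at
quadrat centers (point kriging; block kriging is out of scope).  Exact
duplicate sample coordinates are jittered by 1e−6 m.  Raw variables are
kriged without transformation or trend removal.

## Gradient axes

PCA is computed on the correlation matrix (the nine soil variables have
heterogeneous units).  Axis signs are arbitrary, so they are fixed by an
anchor rule: the loading of organic matter (configurable) is made
non-negative on every axis.  Horn's parallel analysis compares observed
eigenvalues to eigenvalues of standard-normal data of the same shape;
the benchmark is the 95th percentile of the random eigenvalues (1000
iterations by default, seeded).  The mean benchmark (Horn's original
bias-correction, `centile=0`) is also available, but under pure noise the
first observed eigenvalue exceeds the mean random eigenvalue about half the
time, so the mean rule flags a spurious axis in roughly half of noise
datasets; the percentile rule calibrates that error at ~5%, which is what a
retention decision needs.  Regardless of the verdict the first two axis
scores are exported for testing, with the verdict logged, so analyses stay
comparable across scales.

On the synthetic plot the parallel analysis tends to retain more than two
axes at fine scales: the quadrat values are spatially autocorrelated, so
the effective sample size is far below the quadrat count while the
random benchmark assumes independent rows.  This mirrors the behavior such
retention rules have on real gridded data.

## Torus-translation tests

The null set contains all 4·n_x·n_y translated maps — the four orientation
variants (original, left–right mirror, 180° rotation, rotated mirror) times
all cyclic shifts — *including* the identity translation, which makes the
test exact in the randomization-test sense (p ≥ 1/n_maps).  Which single
reflection is called "the mirror" is immaterial: the translation group
closure makes the 4-variant set identical either way (asserted by test).
The decision rule is two one-sided tests at 5% each (overall two-tailed
level 10%); quadrats with missing ZFDis are dropped pairwise, with the
valid-quadrat mask held fixed across translations.  The dispersion map
stays fixed and the environmental map is translated; by correlation
symmetry the null multiset is the same either way (tested).  Under
independence of two spatially autocorrelated fields the torus test stays
near its nominal level while the naive parametric Pearson test rejects far
above it — the reason this test exists (checked by seeded simulation).

The r-versus-area trend is an OLS fit of observed r on quadrat area (m²)
over the (≥3) analysis scales, with a 95% slope CI.  The 50 m estimate in
the small synthetic preset rests on 24 quadrats and is noisy; trend
conclusions there are drawn from seed-averaged r, not single runs.

## The synthetic study generator

The generator emulates the study conditions, not any particular dataset:

- **Geometry**: 500 × 400 m plot, DBH ≥ 1 cm, scales 5/10/20/50 m
  (defaults); soil sampled on the 30 m grid design above.
- **Species pool**: `n_species` (default 134) with six traits from an
  equicorrelated multivariate normal (ρ = 0.3) and regional abundances from
  a log-series (shape 0.95 — heavy-tailed but not so dominant that small
  quadrats collapse to one species).
- **Soil fields**: nine Gaussian random fields (white noise smoothed with a
  Gaussian kernel; correlation length `soil_range`, default 60 m) built
  from latent factors — a fertility factor (OM, TN, TP, pH⁻), a moisture
  factor (SM, TK), and one private latent each for AP, AK, AN — then scaled
  to realistic plot-level means/SDs (e.g. AP 1.81 ± 1.05 mg/kg, AN
  201.7 ± 35.5 mg/kg).  All component lattices are QR-orthogonalized first:
  on a small plot independent random fields show chance correlations up to
  |r| ≈ 0.7, which would both blur the planted factor structure and leak
  one resource's assembly signal into another's verdict.  Samples add white
  measurement noise contributing `nugget_frac` (default 0.2) of the sample
  variance; `nugget_frac = 1` yields spatially unstructured samples.
- **Assembly**: stems are allocated to 10 m assembly quadrats uniformly;
  within quadrat *q* species are drawn with weights
  `regional_s · exp(−‖t_s − θ_q‖² / 2σ_q²)` where the optimum θ_q drifts
  smoothly across the plot (amplitude 0.5 trait-SD, range 150 m) and the
  filter width is `σ_q = σ0 · exp(β_lim z_lim + β_non z_non + β_sat z_sat)`
  with z the standardized local resource values and (β_lim, β_non, β_sat) =
  (−0.8, +0.8, 0) by default.  σ0 = 1.2 keeps the bulk of quadrats in the
  regime where expected ZFDis responds monotonically to log σ (see the SES
  compression note above).  Ground truth (σ_q, z, θ, true fields) is stored
  on the study object for recovery tests and is never an input to any
  pipeline stage.

**Desk-scale preset** (`desk_preset`): 300 × 200 m plot (every analysis
scale divides both dimensions), 60 species, 12,000 stems (0.2 stems/m²),
soil_range 40 m and optimum_range 100 m — the correlation lengths shrink
with the plot so the count of independent environmental patches, and hence
torus-test power, stays comparable to the reference geometry.  With 199
randomizations the full four-scale pipeline runs in ~2 s; twenty replicate
studies plus calibrations run in about a minute.

What the generator does **not** emulate: demographic dynamics, dispersal
limitation, topography, point-pattern clustering of stems within quadrats,
trait measurement error, non-Gaussian soil marginals (fields can produce
occasional negative nutrient values on wide-SD variables), and any
particular real plot's numeric tables.  Passing tests therefore show that
the pipeline recovers planted dispersion–resource relationships of
realistic magnitude under realistic spatial structure — not that any
specific empirical estimate is reproduced.

## Numerical choices and degenerate inputs

- Quadrat assignment uses half-open intervals [i·s, (i+1)·s); a coordinate
  exactly at the plot's upper edge is invalid input.  Scales must divide
  the plot exactly — no partial quadrats.
- Stems of species absent from the trait table are dropped with a count
  recorded on the census object.
- Pearson correlations need ≥3 valid pairs and nonzero variance on both
  sides; otherwise the value is missing and flagged.
- Summary SEs are sample SD over √(number of quadrats); IQRs use
  linear-interpolation quantiles (rule tagged in the output).
- Seeds: every stochastic component (generator, permutations, parallel
  analysis) takes a `numpy.random.Generator` or integer seed; identical
  seeds give bit-identical outputs.

## Known limitations

- Kriging assumes isotropy and second-order stationarity; no co-kriging,
  anisotropy, or cross-validated model selection (RMSE of the variogram fit
  is logged).
- The torus test requires a complete rectangular grid; irregular plot
  outlines are unsupported.
- No multiple-testing correction is applied across the environment × trait
  set × scale grid of tests, by design of the analysis being reproduced.
- Single-trait dispersion uses the same abundance-weighted index in one
  dimension; mixed or categorical traits (Gower distances) are out of
  scope.
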