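# Methods

## Model

`geostatmap` performs topological inference on sparse, irregularly sampled
point data: it asks *where* in a planar domain a set of observed variables
is expressed more strongly than chance would allow, and returns maps of
significant cells with family-wise error (FWE) control.

The chain has three stages.

**1. Rasterization.** Each observation i at location x_i is distributed
over a regular grid by an isotropic bivariate Gaussian kernel: the response
raster of observation i holds the kernel density, centred at x_i, sampled
at cell centres and multiplied by the cell area, so an interior kernel sums
to ~1. The kernel width is parameterized by its 95% iso-density diameter s
(the diameter of the circle containing 95% of the kernel mass), giving the
closed form sigma = (s/2) / sqrt(2 ln 20). The kernel is hard-truncated at
4 sigma (< 0.04% mass loss). Density is sampled at cell centres rather than
integrated over cells; at the resolutions enforced by the under-resolution
guard (sigma >= cell/2) the difference is negligible against the smoothing
itself.

**2. Mass-univariate GLM.** The same linear model y = X b + e is fitted by
ordinary least squares independently at every cell, with the N per-
observation raster values at that cell as the dependent variable and the
observation covariates as regressors. Solving goes through the
pseudoinverse, so rank-deficient designs degrade gracefully (with a
warning); residual degrees of freedom use the numerical rank, nu = N -
rank(X). Contrast t maps are t = c'b / sqrt(sigma2 c'(X'X)^- c). Because t
statistics are normalized effect sizes, the maps are invariant to global
rescaling of the responses — the arbitrary total mass of the kernels is
harmless.

For large grids the engine never materializes the N residual maps: the
residual sum of squares is y'y - b'(X'y) per cell, and residual smoothness
(below) comes from neighbour cross-products
r(a)'r(b) = y(a)'y(b) - (X'y(a))'(X'X)^-(X'y(b)). Both identities hold
exactly for the least-squares solution; the test suite verifies the reduced
route against the explicit residual route to float precision.

**3. Random-field-theory inference.** Residual fields are treated as
realizations of a smooth stationary Gaussian field. Unit-normalized
residuals u_i = r_i / ||r|| give per-axis roughness
lambda_d = mean over cell pairs of sum_i (forward difference of u_i)^2,
and FWHM_d = sqrt(4 ln 2 / lambda_d). The search region is converted to
resel counts (R0 = Euler characteristic, R1 from half the boundary length
split by axis, R2 = area / (FWHM_x FWHM_y)), and the voxel-level FWE
threshold solves

    E[EC(t)] = R0 rho_0(t) + R1 rho_1(t) + R2 rho_2(t) = alpha

by Brent root finding on t in (0, 100) (|E[EC] - alpha| <= 1e-10), where
rho_d are the Euler-characteristic densities of a t field. The returned
threshold never exceeds the Bonferroni bound over the masked cells (the
smaller of the two corrections is used). Two-tailed tests threshold |t| at
alpha/2 per tail. Conjunctions of thresholded maps are plain intersections.

No small-sample degrees-of-freedom bias correction is applied to the
smoothness estimate; instead the estimator is calibrated by simulation
(white noise smoothed to a known FWHM must be recovered within 10%, which
forward differences achieve comfortably at the field sizes used here).
Cluster-extent and peak-level inference are out of scope: all inference is
voxel-level, per scale (no joint correction across the scale dimension).

## Synthetic generative models

Validation data are generated from fractal-boundary region layouts — Koch
snowflakes and anti-snowflakes — because fractal boundaries carry detail at
every spatial scale and are therefore demanding recovery targets for a
smoothing-based method. The standard Koch construction is used (order-0
shape = equilateral triangle of the given circumradius, middle-third
triangles erected outward or inward). One geometric subtlety: the first
inward (anti-snowflake) iteration's three spikes meet exactly at the
centroid, so the raw ring touches itself at one point; the shape is
repaired into an equivalent valid multipolygon of identical area for all
region operations.

Default layouts (region sizes are grid-relative and configurable):

* univariate models, 120 x 120 unit cells: one centred shape, circumradius
  45 (the largest smoothing diameter, 60, is half the grid height); the
  snowflake field is a 3 x 3 array at circumradius 14 — small enough that
  the nine shapes stay disjoint, which circumradius 28 would not be;
* bivariate and interaction models, 240 x 120: three shapes left to right —
  R1 (Z1 only), R3 (joint / interaction), R2 (Z2 only) — at circumradius
  28, snowflake order 4 throughout.

Locations are sampled uniformly over the grid extent (continuous
coordinates). Outcomes are binary with region-dependent probabilities:

* univariate noise models: P(Z=1) = 1-gamma inside the shape, gamma
  outside, for gamma in [0, 0.5) — the noise parameter is the success
  probability itself, so the "probability > 0.5" target rule is exact;
* bivariate noise models: Z1, Z2 independent with Z1 active over R1 u R3
  and Z2 over R2 u R3, same gamma rule;
* interaction model: outside R3 the noise-free bivariate rule; inside R3
  the joint distribution over {(0,0),(1,0),(0,1),(1,1)} is
  p0 = 0.025, p1 = p2 = 0.25 - 0.25 c3, p3 = 0.475 + 0.5 c3 for
  c3 in [0, 0.5]. This parameterization is pinned simultaneously by
  p3(0.25) = 0.6, p3(0.5) = 0.725, p1(0.5) = 0.125 (half of p1(0) = 0.25),
  a constant p0, and the independence product at c3 = 0,
  0.725^2 ~ 0.525. A useful identity: the saturated interaction contrast
  p3 - p1 - p2 + p0 equals c3 exactly, so c3 is the interaction effect
  size.

Target maps contain every cell whose outcome probability (the variable's
marginal, or P(1,1) for the interaction term) at the cell centre exceeds
0.5.

What the generator does *not* emulate: spatially varying sampling
intensity, measurement error in coordinates, non-binary marks, and spatial
correlation in the noise itself (noise is independent across observations
given location). Passing recovery tests therefore demonstrates correctness
of the inferential machinery under the stated generative assumptions, not
robustness to survey-design artifacts in real data.

## Replicated experiments

Noise experiments follow the grid {models} x {N} x {gamma 0..0.35 step
0.01} x 10 repetitions (univariate N in {600, 1200, 1800}; bivariate N in
{1600, 3200}) at smoothing diameters s = 10, 15, ..., 60. For each dataset:

1. every observation is assigned its *spatial condition* (the tuple of
   indicators value > 0.5) and one-hot encoded; a per-scale analysis of the
   condition dummies (no intercept, contrast e_k per condition, one-tailed
   FWE 0.05) yields per-condition significance maps;
2. the *coverage score* of a scale is the number of cells significant for
   exactly one condition; the scale with the highest score is selected,
   ties going to the smallest scale;
3. the scored per-variable maps come from the main analysis at the
   selected scale — a no-intercept regression of the responses on the
   observed variables themselves, each term tested one-tailed at FWE 0.05;
4. each variable's map is scored against its target with the Jaccard
   index, Dice score, Matthews correlation coefficient, symmetric
   uncertainty (base-2 entropies of the joint binary cell distribution;
   defined as 0 when both maps are constant) and the modified Hausdorff
   distance between significant and target cell centres as a fraction of
   the grid-extent diagonal. An empty recovered map scores 0 on the
   overlap metrics and reports the Hausdorff fraction as missing (excluded
   from means rather than treated as infinite).

The design choice in step 3 deserves a note. Testing each condition's own
density (e_k) rather than a between-condition difference makes the
background condition significant over the whole empty area at moderate
scales, which is what gives the coverage profile its interior maximum (at
gamma = 0.1, N = 1600 the profile peaks at s = 30-40); a difference
contrast starves the background map and pushes selection to the largest
scale. Conversely, a bare e_k-style test is *not* appropriate for null
calibration: the package's FWE validation uses the between-condition
difference (condition 1 minus condition 0), which is genuinely null when
labels carry no spatial structure.

Interaction experiments use the printed augmented design y' = (y1, y2,
y1*y2) with *no intercept* at a single scale s = 60, N = 15000, c3 from
0.25 to 0.5 in steps of 0.05, 10 repetitions. Without an intercept the
empty background is the implicit zero baseline and the interaction
coefficient reduces to m11 - m10 - m01 (group mean responses), which
vanishes away from the signal regions; a saturated design with intercept
would make the interaction coefficient equal the background mean outside
all regions and flood the map. Note that with this design the interaction
*effect size* (mean t over R3) grows monotonically with c3, while overlap
scores can saturate once the whole of R3 is recovered — at high sampling
density larger effects mainly widen the smoothing halo outside R3.

Externally produced prediction surfaces (e.g. kriging means with their
positional prediction variances) are compared through
z = (prediction - 0.5) / sqrt(variance), thresholded at the upper-tail
alpha = 0.05 critical value of the standard normal. Kriging itself is not
implemented.

## Numerical and interface choices

* Master seeds fan out through `numpy.random.SeedSequence.spawn`, one child
  per dataset, so every experiment is bit-reproducible and individual
  repetitions are independent.
* Internal computation is double precision; experiment response stacks use
  float32 (the t maps are identical to ~1e-6 relative, far below any
  thresholding sensitivity), and rasters are written as float32.
* Rasters are exported as CSV matrices or single-band GeoTIFFs whose
  affine geotransform is carried by the ModelPixelScale / ModelTiepoint
  tags; rows are written north-to-south. Coordinates are planar
  (projected); there is no CRS handling or reprojection.
* Auto-extent grids pad the data bounding box by one truncation radius of
  the largest scale; the default cell size makes the smallest smoothing
  diameter span five cells.
* Degenerate cells (zero residual variance) are flagged and excluded from
  smoothness estimation and thresholding; a value exactly at the one-hot
  threshold counts as "not exceeding".
* The test suite and the acceptance script run the replicated experiments
  at reduced sizes (3 gamma levels x 10 repetitions for the bivariate
  recovery check; 200 null simulations for FWE calibration; interaction
  checks at N = 1500-2000 with 2 repetitions). The full study grids (1,440
  bivariate and 60 interaction datasets) are enumerated and available
  through the same configuration objects.

## Known limitations

* Voxel-level inference only; no cluster-extent or peak p-values, no
  nonstationary smoothness, no joint scale-space correction.
* The resel computation for irregular masks approximates boundary length
  by axis-split face counting; exact per-voxel resel counting as used in
  mature neuroimaging pipelines would differ slightly on ragged masks.
* RFT thresholds on these kernels are conservative (the empirical
  family-wise error rate under pure noise runs well below the nominal
  0.05), which is the expected behaviour of the expected-Euler-
  characteristic bound on smooth fields.
* F contrasts, robust/weighted regression, temporal models and Bayesian
  extensions are out of scope.
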