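# geostatmap

Topological inference on sparse geospatial point data.

Many questions in spatial epidemiology and public health reduce to: *where*
is a variable — disease status, an exposure, a demographic trait —
expressed more strongly than chance would allow, given irregular, sparse
and noisy point sampling? `geostatmap` answers this with the machinery of
statistical parametric mapping. Point observations are distributed over a
regular grid with isotropic Gaussian kernels of 95% iso-density diameter
`s` (so `sigma = (s/2)/sqrt(2 ln 20)`); the same general linear model

    y(j,k) = X b(j,k) + e(j,k)

is fitted by ordinary least squares independently at every grid cell
`(j,k)`, with the per-observation kernel responses as the dependent
variable and the observation covariates as the design `X`; and contrast
maps `t = c'b / sqrt(sigma2 c'(X'X)^- c)` are thresholded at a voxel-level
family-wise-error corrected level derived from random field theory: the
threshold solves

    E[EC(t)] = R0 rho_0(t) + R1 rho_1(t) + R2 rho_2(t) = alpha,

where the resel counts `R_d` measure the search region in units of the
residual fields' FWHM smoothness (estimated from unit-normalized
residuals) and `rho_d` are the Euler-characteristic densities of a t
field; the smaller of the RFT and Bonferroni thresholds is used.
Conjunctions of thresholded maps are plain intersections.

The package also contains the full synthetic validation suite: Koch
snowflake / anti-snowflake region layouts (fractal boundaries carry detail
at every spatial scale), binary outcome models with a noise parameter
`gamma` and an interaction parameter `c3`, ground-truth target maps,
segmentation metrics (Jaccard, Dice, Matthews correlation, symmetric
uncertainty, modified Hausdorff distance), coverage-based smoothing-scale
selection, and replicated experiment drivers.

## Worked example

Simulate a noise-free univariate snowflake dataset (600 points on a
120 x 120 grid; inside the fractal shape `z = 1` with certainty, outside
`z = 0`), analyse it at smoothing diameter 40, and score the significant
area against the generative target:

```python
import geostatmap as gm

obs = gm.sample_dataset("snowflake", 600, 0.0, seed=123)
grid = gm.synthetic_models.default_grid("snowflake")

analysis = gm.analyze_scale(
    obs,
    gm.DesignSpec(("z",)),            # regress responses on z, no intercept
    {"z": [1.0]},                     # one-tailed t test of the z coefficient
    diameter=40.0, grid=grid, alpha=0.05,
)
sig = analysis.significance["z"]
print(f"threshold t = {analysis.threshold_t:.3f}")
print(f"residual FWHM = ({analysis.smoothness.fwhm_x:.1f}, "
      f"{analysis.smoothness.fwhm_y:.1f}) cells")
print(f"significant cells = {sig.n_significant}")

target = gm.target_map("snowflake", "z", 0.0)
scores = gm.segmentation_scores(sig.significant, target, grid)
print(f"dice = {scores.dice:.3f}, jaccard = {scores.jaccard:.3f}")
```

Output:

```
threshold t = 3.568
residual FWHM = (19.6, 19.6) cells
significant cells = 4965
dice = 0.887, jaccard = 0.797
```

The corrected threshold (t = 3.57 instead of a pointwise ~1.65) reflects
the 14,400-cell search region measured in resels of the residual
smoothness; the significant area recovers the snowflake interior (Dice
0.89 — the smoothing halo slightly inflates the shape, and fractal
boundary detail below the kernel width is unresolvable by construction).

The same pipeline is available from the shell:

```
geostat-mapper simulate --model snowflake --n 600 --gamma 0 --seed 123 --out data.csv
geostat-mapper run config.yaml        # rasters + summary.csv per scale/contrast
geostat-mapper evaluate --recovered sig.csv --target target.csv
geostat-mapper experiment exp.yaml --kind noise --out results.csv
```

`docs/methods.md` describes the model, the generative validation suite and
all numerical choices in detail.

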