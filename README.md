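# gsspatial

Genomic prediction for plant-breeding field trials with parametric
spatial correlation kernels.

Field heterogeneity — soil gradients, moisture, topography — inflates
the error of breeding-value estimates, especially in modern trials where
most test genotypes are planted once and only a handful of check
genotypes are replicated. `gsspatial` fits a GBLUP mixed model in which
the plot error is split into a spatially correlated component and an
independent residual:

    y = μ1 + Z g + s + r,
    g ~ N(0, K σ²g),   s ~ N(0, S σ²s),   r ~ N(0, I σ²r)

where **K** is the marker-based additive relationship matrix (VanRaden
method 1) and **S** is a parametric correlation kernel on the
center-to-center distance *D* (meters) between plots:

* Power: `θ^D` (the continuous-distance generalization of AR(1)),
* Gaussian: `exp(−D²/ϕ²)`,
* Spherical: `1 − 1.5(D/ϕ) + 0.5(D/ϕ)³` for `D ≤ ϕ`, else exactly 0,

with distance taken either isotropically (Pythagorean, using the plot
dimension to convert Range/Column index differences to meters) or along
the Range or Column direction only. Variance components are estimated by
REML (Fisher scoring); the kernel family, direction and standardizing
parameter are chosen by repeated genotype-level cross-validation against
the no-spatial base model, selecting the lowest prediction RMSE. Random
Range/Column effects (extraneous variation from field operations) can be
added on top, tested with a boundary-aware likelihood-ratio test
(thresholds 2.706 / 4.605 at α = 0.1 for one / two added components).
The package also includes a trial simulator for studying when spatial
modeling improves accuracy, and Cullis heritability from BLUP
prediction-error variances.

## Worked example

`examples/fit_spatial_model.py` simulates a 160-plot trial (120
genotypes, 10 replicated checks) where 70% of the non-genetic variance
is a smooth Gaussian spatial field (true variances
σ²g = 1, σ²s = 0.7, σ²r = 0.3), then fits both models:

```
--- base model ---
sigma2_g: 0.459431
sigma2_r: 0.855178
--- spatial model ---
sigma2_g: 0.561866
sigma2_s: 0.858332
sigma2_r: 0.340001
LRT: chi2 = 35.800 vs threshold 2.706 -> significant (mixture p = 0.0000)
Cullis h2 (spatial model): 0.592
```

The base model cannot see the field: it absorbs the spatial variance
into the residual (0.86 ≈ 0.7 + 0.3 shared out) while the spatial model
separates the three components near their true values, and the
likelihood-ratio test strongly favors it. The other examples show
kernel selection by cross-validation (`select_spatial_kernel.py`) and a
miniature simulation grid (`simulation_study.py`), e.g.:

```
fra_sp=0.5: COR base 0.635 -> spatial 0.677  (relative gain 10.4%)
fra_sp=0.9: COR base 0.689 -> spatial 0.875  (relative gain 56.9%)
```

— the payoff of spatial modeling grows with the spatial share of the
error variance.

## Command line

```sh
gsspatial analyze --trial trial.csv --markers snps.csv \
    --trait DM --plot-length 5 --plot-width 1 --outdir out/
gsspatial simulate --h-grid 0.3,0.9 --fra-grid 0.3,0.9 --n-seeds 20
```

`analyze` runs the full pipeline per trait (load → genotype matching →
base fit → outlier removal at 2.5 residual SD → kernel search →
Range/Column extension) and writes BLUP tables, CV metrics, a selection
summary and a plot-level grid export. `simulate` runs a simulation grid
and writes a long-format results table plus a reproducibility manifest.

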