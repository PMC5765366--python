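# Methods

## Model

A trial is a set of plots on a regular grid, addressed by a Range index
(North–South) and a Column index (East–West). For one trait the model is

    y = μ1 + Z g + s + Z₂ ra + Z₃ cl + r

with genotypic effects g ~ N(0, K σ²g), plot-level spatial effects
s ~ N(0, S σ²s), optional Range and Column effects ra ~ N(0, I σ²ra),
cl ~ N(0, I σ²cl), and residuals r ~ N(0, I σ²r). "Base" contains only
g and r; "Model 1" adds s; "Model 2" adds Range/Column effects on top of
whichever of Base/Model 1 won the cross-validation. K is either the
VanRaden (method 1) additive relationship matrix computed from SNP
dosages (markers with minor allele frequency ≤ 1% dropped, missing
dosages mean-imputed per marker) or, for simulated data whose genotypic
effects are drawn independently, the identity on the genotype labels.

Distances are in meters. The plot dimension (length along Columns ×
width along Ranges) converts index differences to distance: range
distance = |Δrange|·width, column distance = |Δcol|·length, and the
isotropic distance is the hypotenuse of the two. Directional kernels use
only their own component — the special-case anisotropy in which a whole
Range (or Column) shares one spatial effect value. The three correlation
families are Power `θ^D` (0 < θ < 1), Gaussian `exp(−D²/ϕ²)` and
Spherical `1 − 1.5(D/ϕ) + 0.5(D/ϕ)³` truncated to exactly 0 beyond ϕ.
The Gaussian form deliberately has no factor 2 in the denominator. On a
unit-spaced transect the Power kernel is exactly the AR(1) matrix with
ρ = θ, which the tests assert entrywise.

Directional kernels repeat values across plots that share a Range or
Column and can be numerically rank-deficient. If a kernel's smallest
eigenvalue is below −1e−8 a diagonal jitter of |λmin| + 1e−8 is added
and the matrix rescaled back to unit diagonal; isotropic kernels on the
layouts used here never trigger this.

## REML solver

Variance components maximize the restricted log-likelihood with an
intercept-only fixed part, profiled out analytically. Updates are Fisher
scoring (expected information) with step halving until the likelihood
does not decrease; convergence is declared when the likelihood changes
by less than 1e−6 (max 100 iterations). Components proposed negative are
projected to a floor of 1e−9 × the phenotypic variance. A floored
component is held out of the update while its score is non-positive and
re-enters as soon as increasing it would raise the likelihood (an
active-set rule — a fixed "stuck for k iterations" cutoff was tried
first and could lock out components whose optimum is small but
positive). Components still floored at convergence are reported as
exactly 0 with a boundary flag; the spatial or residual variance pinning
to the boundary is an expected behavior when the two are weakly
separated. A constant response short-circuits to μ̂ = that constant with
all components zero.

Correctness anchors: the solver reproduces lme4's REML variance
components, intercept and restricted log-likelihood to 1e−6 on a frozen
balanced dataset; matches the one-way ANOVA closed form on balanced
designs; and on ≥ 20 random instances with n ≤ 30 its optimum is never
below a dense variance-component grid search (tolerance 1e−4).

BLUPs come from the mixed-model equations at the estimates:
ĝ = σ²g K Z' P y covers every genotype in K, observed or not (that is
what lets genotype-disjoint CV predict held-out genotypes through the
relationship matrix). Prediction-error variances for ĝ are computed over
all genotype pairs, giving Cullis heritability
h² = 1 − V̄Δ / (2σ̂²g) with V̄Δ the mean PEV of BLUP differences;
the value is reported unclamped with a warning outside [0, 1]. On
balanced identity-K designs it agrees with the classical line-mean form
to 1e−6. Held-out plots are predicted as Ŷ = μ̂ + ĝ(genotype) + ŝ(plot),
with ŝ the joint-BLUP (kriging) given training observations,
σ̂²s S(test, train) V⁻¹(y − μ̂1). Range/Column BLUPs carry over to
held-out plots for levels seen in training (zero otherwise); without
that, extension models could never show a cross-validation benefit.

## Likelihood-ratio testing

The statistic is 2(llk_model − llk_base), floored at 0. Because the null
hypothesis puts variance components on the boundary, the statistic
follows a ½χ²(0):½χ²(df) mixture; the reported p-value uses the mixture,
while the significance decision uses the plain upper-α χ²(df) quantile
(2.706 at α = 0.1 for one added component, 4.605 for two) — the more
conservative convention, and the one the decision thresholds in this
field are usually quoted from. Both numbers are exposed.

## Model selection

Cross-validation is at genotype level: genotypes are partitioned into
k near-equal folds per repeat (default 10 folds × 5 repeats, seed
20170307), and a plot follows its genotype, so training and test sets
never share a genotype. Every candidate (family × direction × parameter)
is evaluated under the identical plan (paired comparison; plan hashes
are asserted equal) and the lowest mean prediction RMSE wins; prediction
correlation is reported but never used for selection. The standardizing
parameter is selected on the same CV surface as the family and direction
— no nested CV, which makes the reported predictability of the winner
slightly optimistic; the full-data likelihood-ratio test against Base is
reported alongside as an independent check.

Ties are resolved toward higher pCOR, then the base model, then the
smaller parameter. "Tie" uses a relative tolerance of 1e−6: a candidate
whose spatial variance pins to zero predicts identically to Base up to
solver noise (~1e−10), and exact float comparison would turn those ties
into coin flips. Default parameter grids are θ ∈ {0.1, …, 0.9} for Power
and 10 log-spaced values between the smallest nonzero and the largest
plot distance for Gaussian/Spherical; grids are user-overridable, and
the ones used in the test suite are reduced for runtime.

Fold fits that fail or do not converge are trapped, logged and counted
(`n_failed_fits`); a candidate is dropped if more than half its fold
fits fail. A fold whose observed or predicted values have zero variance
records a correlation of 0 with a warning rather than dropping the fold.

## Preprocessing

Per trait: plots with missing values are dropped; plots whose genotype
is absent from the relationship matrix are removed (count reported);
then a single outlier pass removes plots whose base-model residual
exceeds 2.5 × the sample SD (ddof = 1) of the residuals — strict
inequality, one pass, no refit loop. Matching precedes outlier removal.
All preprocessing is idempotent on its own output. Note the rule cannot
fire at very small n: for n plots the largest possible |r|/SD is
(n−1)/√n, so at c = 2.5 at least seven plots are needed.

## Simulator

`simulate_trial` draws, per plot, y = g(genotype) + s + r with g i.i.d.
standard normal per genotype (no relationship matrix — analysis of
simulated data uses the identity kinship on labels), s multivariate
normal with covariance σ²s × (kernel on the layout's isotropic distance
matrix, drawn on the replication-extended layout), and r i.i.d. normal.
Two ratios set the variance budget: the genotypic ratio h gives
σ²e = (1 − h)/h with σ²g = 1, and fra_sp splits σ²e into
σ²s = fra_sp·σ²e and σ²r = (1 − fra_sp)·σ²e. fra_sp = 0 is accepted and
means "no spatial effect", used for null experiments.

The default layout is a synthetic stand-in for a large single-site
screening trial: 829 genotypes of which 11 are checks planted 6 times
each (884 plots), filled row-major onto a 22-column grid of 2 m × 1 m
plots (~41 × 44 m field), checks spread evenly through the planting
order. Check replication at roughly 7% of plots is typical of
preliminary yield trials; it is also what identifies σ²g against σ²r
when the kinship is the identity. Replication scenarios: checks_only
(test genotypes once), half_replicated (a seeded random half of test
genotypes twice), fully_replicated (all twice), with replicate plots
appended on extended grid rows. Default grids follow the study design
ranges: h, fra_sp ∈ {0.3, 0.5, 0.7, 0.9}, θ ∈ {0.2, 0.5, 0.8},
ϕ ∈ {0.5, 10.5, 30.5, 60.5}, 20 seeds per cell, per-cell seeds derived
from a master seed.

What the simulator does not emulate: marker genotypes and LD (so
CV-style prediction of unobserved genotypes is degenerate under the
identity kinship — selection-engine tests instead build genotypic
effects from a synthetic marker panel's VanRaden matrix), non-Gaussian
traits, genotype-by-environment structure, and real field layouts with
missing plots or serpentine artifacts. Passing tests therefore show the
estimator and selector behave correctly under the stated generative
model, not that any particular real trial has spatial structure.

## Problem sizes in the test suite

Unit tests run on layouts of 10–160 plots. The headline simulation
check uses the full 884-plot layout with 10 seeds per cell and two
Gaussian cells; variance-component recovery uses 10 replicates at the
same scale; the null-behavior check uses 20 replicate searches on a
126-plot marker panel with 10-fold × 5-repeat CV and an 8-candidate
grid. These sizes keep the full suite within a few minutes while leaving
each claim at the scale it is stated for.

## Known limitations

* Dense-matrix REML: O(n³) per iteration; practical to a few thousand
  plots, not tens of thousands.
* No nested CV for the standardizing parameter (see above).
* The LRT boundary mixture is approximate for two added components
  (½:½ between χ²(0) and χ²(2) rather than the exact three-way mix).
* Spatial prediction at held-out plots assumes the training fit's
  variance components transfer unchanged.
* The PSD jitter repair slightly shrinks off-diagonal correlations of
  rank-deficient directional kernels.
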