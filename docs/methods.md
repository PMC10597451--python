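# Methods

`fbgeo` implements the full analysis chain behind a national-scale map of
the soil fungal:bacterial (F:B) ratio: qPCR calibration to absolute rDNA
copy densities, geostatistical modelling and mapping, environmental-driver
ranking, and land-use contrasts, together with a synthetic survey
generator that plants every parameter the chain is supposed to recover.

## qPCR master-curve calibration

Absolute quantification across many plates drifts because amplification
efficiency varies between runs. The master-curve method corrects this
with a reference environmental DNA sample run in triplicate on every
plate:

1. the grand mean reference Ct over all plates is computed per target
   (16S and 18S are calibrated fully independently — separate chemistry,
   separate reference means, derivations and curves);
2. each plate's *derivation* (plate reference mean − grand mean) is
   subtracted from every Ct on that plate;
3. one calibration line `Ct = slope·log10(copies) + intercept` is fitted
   by OLS to the corrected Cts of all plasmid-standard wells pooled over
   plates (10-fold dilution ladders);
4. sample copies per reaction are `10**((Ct_corr − intercept)/slope)`,
   scaled to copies per gram of soil by a conversion factor.

After correction every plate's mean reference Ct equals the grand mean
identically, and recomputing derivations on corrected data yields zeros
(idempotence). Derivations are identifiable only up to one additive
constant: adding the same offset to every plate moves the grand mean and
the master-curve intercept together and leaves all copy numbers
unchanged. Recovery tests therefore compare *centred* planted offsets,
which the calibration reproduces exactly in the noiseless limit.

The reaction→gram conversion is not derivable from the assay itself; it
is an explicit configuration parameter (default 1e4 copies/g per
copy/reaction, i.e. ~20 µg extractable DNA per g soil against a 2 ng
template). Absolute densities are comparable only within one conversion
convention; the F:B ratio, `100 × (18S copies/g)/(16S copies/g)`, is
invariant to it when both assays share the convention.

Failed wells (missing Ct) propagate as missing densities and the
calibration report carries the success count. Replicate groups with Ct
SD > 0.5 cycles are flagged, not trimmed.

## Spatial model

Responses (F:B ratio and log densities, conditioned as below) are
modelled as a second-order stationary Gaussian process with unknown
constant mean on planar projected coordinates (km):

    C(h) = c · ρ_Matérn(h; a, ν) + c0 · 1{h = 0}

with nugget `c0`, partial sill `c`, range parameter `a` and smoothness
`ν` (`ν = 0.5` is the exponential model). Fitting maximises the Gaussian
likelihood with the mean profiled out in closed form and the total sill
profiled as well, so the numerical search (Nelder-Mead on log range and
logit correlated-fraction) is two-dimensional per candidate ν. ν is
optimised over the discrete grid {0.5, 1.5, 2.5}: the continuous
profile likelihood in ν is extremely flat, and a discrete grid keeps
fits reproducible. The *effective range* reported is the practical 95%
range — the smallest h where the semivariance reaches `c0 + 0.95·c`
(≈ 3a for the exponential model).

Two numerical safeguards matter in practice:

* fits that do not beat the closed-form white-noise likelihood by more
  than 2 units are returned as flagged pure-nugget models (on the
  likelihood surface, `c ≈ var` with range → 0 is equivalent to a pure
  nugget, so the raw optimum is a ridge there);
* smoothness and nugget are confounded when the closest site spacing is
  of the order of the range parameter — on a 16-km grid with a 28-km
  range the ν candidates differ by <2 likelihood units. Smoothness
  selection is therefore only meaningful on layouts with close pairs,
  which is how the selection property is tested (irregular layout,
  nugget-free field).

The empirical (Matheron) variogram with 10-km lags up to one-third of
the bounding-box diagonal is computed as a diagnostic and to initialise
the optimiser; fitting itself never uses the bins.

Prediction is ordinary kriging (weights constrained to sum to one) on
the 64 nearest samples by default; with all samples in the neighborhood
it coincides with the GLS predictor built from the full covariance. At
a data location the predictor reproduces the observation (zero variance
when `c0 = 0`). Duplicate coordinates are jittered by 1e-6 km only when
there is no nugget to absorb them. Model quality is evaluated by
leave-one-out cross-validation with the fitted model held fixed: the
standardized squared prediction errors `(z_i − ẑ_{−i})²/σ²_{k,−i}` are
approximately χ²(1) under a well-specified model (mean 1, median
0.455), and the LOO observed-vs-predicted squared correlation is
reported as `r_squared` without claiming equivalence to any other map
quality statistic.

## Response conditioning

Before modelling, each response passes Shapiro-Wilk normality screening
(3 ≤ n ≤ 5000); if rejected, a Box-Cox transform with λ chosen by
profile maximum likelihood over [−2, 2] (λ = 0 is the natural log; a
shift handles non-positive values). Outliers are then removed on the
transformed scale by iterative two-sided Grubbs tests at α = 0.05, at
most 5 passes, first index winning ties — a single-outlier test applied
repeatedly, capped to prevent pathological stripping. The chosen
transform and removal list are serialized in the run report so any
downstream number is reproducible from raw data. (Rank-based group
tests are invariant to the monotone transform; the chain still applies
it first because the outlier decisions depend on the scale.)

## Driver analysis

Quantitative predictors are standardized, categoricals treatment-coded.
Collinearity is reduced by iteratively removing the predictor with the
largest VIF until all VIF ≤ 5 (dummies exempt); an exhaustive best-subset
screen by BIC (≤ 20 columns) is available as a second filter. For a
univariate standardized response, redundancy analysis reduces to OLS:
R² is the explained fraction and the Ezekiel-adjusted R²
(`1 − (1−R²)(n−1)/(n−p−1)`) is the currency of all partitioning.

Forward selection adds the candidate with the largest adjusted-R² gain,
admitting it only if its Freedman-Lane permutation p < α *and* the
running adjusted R² stays at or below the full-model ceiling. The
ceiling rule has a known consequence: when the remaining scope is pure
noise, a true subset's adjusted R² can exceed the diluted full model's
and selection stops early. This matches the reference stepwise-RDA
implementation (verified against vegan's `ordiR2step` on planted data)
and is retained deliberately; what the procedure guarantees — and what
is tested — is that strong predictors enter first, noise columns do
not enter, and the reported adjusted R² never exceeds the full model's.

Variance partitioning assigns each explanatory group (soil covariates,
land management, climate, spatial descriptors) its unique fraction
`adjR²(all) − adjR²(all − g)` via partial RDA; the remainder of the
total is the shared ("interactions") fraction, so unique fractions plus
shared equal the full-model adjusted R² exactly, and small negative
unique fractions are reported as-is. Group p-values come from
residual-permutation pseudo-F tests conditioned on the other groups,
with `p = (1 + #{F* ≥ F})/(1 + n_perm)`. Spatial descriptors are a
convention — standardized x, y and their second-order terms (x², y²,
xy) — and are labelled as such in reports. Sand never enters any model:
it is the complement of clay + silt and would be exactly collinear.

## Land-use contrasts

The omnibus test is the tie-corrected Kruskal-Wallis H against
χ²(k−1). Pairwise follow-up uses the rank-LSD convention (mean-rank
differences against a Student-t quantile with the pooled rank variance
scaled by `(N−1−H)/(N−k)`), with Dunn's z-tests available as an
alternative; raw p-values are Bonferroni-multiplied by k(k−1)/2 and
capped at 1, and groups not separated by any significant pair share a
letter in the compact letter display. Tail summaries report the
per-group percentage of ratios below 1 and above 5.

## Synthetic surveys

The generator emulates a national systematic soil survey: ~2,171 sites
at jittered centers of a 16-km grid, soil covariates with realistic
marginals (pH 3.8–8.6, organic C lognormal ~25 g/kg, C:N 6–30,
Dirichlet texture, lognormal trace metals), spatially clustered land
use (crop 45%, grassland 27%, forest 22%, vineyard/orchard 6%) and
latitudinal climate bands with a Mediterranean class in the south.

Log densities follow a linear model plus Gaussian random fields drawn
exactly by Cholesky factorisation of the Matérn covariance (effective
range 84 km, nugget 0.2 / partial sill 0.8 in normalized units).
Bacterial and fungal log densities share one spatial component and each
carries its own, so the ratio has spatial structure distinct from
either density. Planted standardized effects on ln(F:B): pH −0.17,
organic C −0.08, C:N +0.08, coarse elements +0.07, silt −0.04,
available P +0.045; Mediterranean climate +0.15; a weak north–south
trend (−0.10 per sd of y); land-use class medians 2.12 (grassland),
2.40 (vineyard/orchard), 2.54 (crop), 3.91 (forest). Direct class
effects are self-calibrating: they absorb only what the covariate and
climate channels do not already express of the configured class
medians, so realized class medians track the configuration while the
*unique* land-management fraction stays modest. The overall sample
median is recentred to 2.72 exactly on the log scale. With these
defaults the expected variance partition lands near soil ≈ 0.10 unique
and total ≈ 0.30 (seed-to-seed spread roughly ±0.05), and the marginal
F:B distribution has median 2.72 and mean ≈ 3.2.

qPCR plates carry 24 samples each (single wells), triplicate reference
DNA and a triplicate 6-level 10-fold standard ladder; Ct = intercept +
slope·log10(copies/reaction) + plate offset (SD 0.5 cycles) + well
noise (SD 0.15 cycles), with 6.6% of sample wells failing, mirroring a
2,030-of-2,173 success rate. Assay truth: slope −3.3219 / intercept 40
(16S), −3.4 / 39 (18S).

What the generator does *not* emulate: coastline geometry (the grid
bounding box stands in for the territory; a mask hook exists),
pedogenetic dependence among covariates beyond the planted
correlations, non-Gaussian residuals, spatially varying qPCR
efficiency, and copy-number variation between taxa. Passing recovery
tests therefore demonstrates the correctness of the estimators under
the stated model, not the field accuracy of the original measurements.

## Problem sizes and runtime choices

Each ML variogram likelihood evaluation costs one Cholesky of an n×n
matrix, so fits scale as n³. The test suite runs the range-recovery
study at 500 sites × 50 replicates and the sign-recovery study at
2,000 sites × 50 seeds; the acceptance script runs 50 replicate fields
on a 1,200-site jittered 16-km subgrid (≈ 8 s per fit single-threaded),
a size at which the median recovered effective range is within ~2% of
the planted 84 km in pilot runs. Cholesky factors of the correlation
matrix are cached across replicate draws on a fixed layout.

## Known limitations

* ML over continuous ν is intentionally not offered; the grid keeps
  results reproducible but cannot represent intermediate smoothness.
* Kriging is strictly Euclidean/planar: lon/lat inputs must be
  projected upstream, and no spherical-distance mode exists.
* The permutation engine is a plain Python loop; at 10,000 permutations
  × many groups it is the slowest stage of a full run (use fewer
  permutations for exploration).
* Variance partitioning assumes a univariate response; multi-axis RDA
  is out of scope.
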