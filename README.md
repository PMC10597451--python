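# fbgeo

Biogeography of the soil fungal:bacterial (F:B) ratio at territorial
scale: a tested Python pipeline that turns raw multi-plate qPCR runs
into absolute 16S/18S rDNA copy densities, maps their ratio by
maximum-likelihood Matérn kriging, and ranks the environmental drivers
by variance partitioning — with a synthetic survey generator so every
stage can be validated against planted ground truth without any
download.

It is written for soil microbial ecologists working with systematic
monitoring networks (grids of ~10³ sites with soil physico-chemistry,
land-use and climate metadata) who need the whole chain — calibration,
geostatistics, driver analysis, group contrasts — reproducible from one
seed.

## What it computes

**qPCR master-curve calibration.** Each plate carries triplicate
reference DNA and a 10-fold plasmid standard ladder. Per target
(16S = bacteria, 18S = fungi): the per-plate *derivation* (plate
reference mean Ct − grand reference mean) is subtracted from every Ct,
one pooled calibration line `Ct = slope·log10(copies) + intercept` is
fitted to all corrected standards, and sample densities follow as

    copies/g = conversion × 10^((Ct_corr − intercept)/slope),
    F:B = 100 × (18S copies/g) / (16S copies/g).

**Geostatistics.** The transformed response is modelled as a Gaussian
process with constant unknown mean and semivariance
`γ(h) = c₀ + c·[1 − 2^(1−ν)/Γ(ν)·(h/a)^ν·K_ν(h/a)]` (nugget c₀, partial
sill c, range a, Matérn smoothness ν). Parameters are fitted by maximum
likelihood (mean and total sill profiled out; ν over {0.5, 1.5, 2.5});
maps come from ordinary kriging on a local neighborhood, and model
quality from leave-one-out cross-validation via standardized squared
prediction errors `(z−ẑ)²/σ²_k` (≈ χ²₁ when the model is right). The
reported effective range is the practical 95% range (≈ 3a for ν = 0.5).

**Drivers.** Predictors pass a VIF ≤ 5 collinearity filter and optional
BIC best-subset screen; a univariate RDA (= OLS on standardized data)
with forward selection and permutation tests partitions the
Ezekiel-adjusted R² into unique fractions for soil, land management,
climate and spatial descriptors plus a shared "interactions" fraction
(the fractions close exactly by construction).

**Contrasts.** Tie-corrected Kruskal-Wallis across land uses with
Bonferroni-adjusted rank-LSD pairwise comparisons and a compact letter
display, plus tail summaries (% of soils with ratios < 1 or > 5).

## Worked example

Generate a 300-site synthetic survey, calibrate both targets, derive
ratios, fit a variogram and cross-validate:

```sh
fbgeo simulate --seed 42 --out demo --n-sites 300
fbgeo calibrate --plates demo/plates_16S.csv --target 16S --out d16.csv --report calib16.json
fbgeo calibrate --plates demo/plates_18S.csv --target 18S --out d18.csv
fbgeo ratios --densities-16s d16.csv --densities-18s d18.csv --out ratios.csv
fbgeo variogram --samples demo/sites.csv --response fb_ratio --nu-grid 0.5 --out vgm.json
fbgeo cv --samples demo/sites.csv --model vgm.json --response fb_ratio
fbgeo compare --sites demo/sites.csv --response fb_ratio
```

prints

```
wrote 300 sites and plates to demo
16S: quantified 281/300 samples; efficiency 1.000, r2 0.9991
18S: quantified 274/300 samples; efficiency 0.970, r2 0.9989
median F:B ratio 2.806 over 300 samples
{"nugget": 2.77, "partial_sill": 1.30, "range_km": 38.2, "nu": 0.5,
 "effective_range_km": 114.5, "neg_loglik": 619.38, "pure_nugget": false}
{"mean_sspe": 1.0005, "median_sspe": 0.3135, "r_squared": 0.137, "n": 300}
{"H": 43.32, "df": 3, "p_value": 2.1e-09,
 "letters": {"forest": "a", "vineyard_orchard": "ab", "crop": "b", "grassland": "b"}}
```

Reading the numbers: 281/300 and 274/300 are the per-target
quantification success counts (the generator plants a ~6.6% well
failure rate); efficiency ≈ 1.0 means near-perfect doubling per cycle;
the median F:B of 2.81 sits near the planted 2.72. The variogram block
gives the fitted nugget/partial sill (here on the raw, right-skewed
ratio scale — the full pipeline transforms first), and a mean SSPE of
1.0005 says the kriging variances are well calibrated. The contrast
block shows forest ratios separated from crop and grassland
(distinct letters), with vineyards/orchards intermediate.

The full chain — conditioning, variogram + LOO-CV + gridded map,
variance partitioning, contrasts, one JSON run report — is
`fbgeo run --sites demo/sites.csv --seed 1 --out results/`, or
`fbgeo.pipeline.run_pipeline` from Python.

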