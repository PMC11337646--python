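# Methods

This note documents the models and numerical choices behind canopy-calib:
what each stage assumes, which parameters matter, and what the synthetic
scenes do and do not establish about real UAV data.

## Synthetic trials and growth

Trial designs follow two templates. The 21-plot BioCal crosses 6 genotypes
with sowing densities {75, 150, 225} plants/m plus a check genotype at
{150, 187, 112}; the 27-plot variant crosses 7 genotypes with
{75, 150, 300} once each plus a check at all three densities twice
(7·3 + 1·3·2 = 27 — the template reproduces the printed plot total under
this reading, which is documented rather than guessed further). NVT
templates place each genotype in exactly `n_reps` plots on a row-column
grid. Only plot positions are randomized; the treatment list is fixed.

Plot biomass is logistic in cumulative thermal time,

    DW(tt) = A_g · d · (1 + a·f(row, col)) / (1 + exp(−r (tt − t_i))) · ε,

with per-genotype asymptotes `A_g` drawn lognormally around 1400 g/m²
(CV 0.10 by default — the genetic signal the repeatability stage must
recover), inflection `t_i = 1100` °C·day and rate `r = 0.004` /°C·day
(placing the rapid-growth phase in the flowering window of a winter wheat
season), a density multiplier `d` (0.85/1.0/1.1/1.15 at 75/150/225/300
plants/m, interpolated between; densities mainly spread mid-season biomass
rather than final yield), a smooth low-order spatial field `f` scaled by
the trend amplitude relative to the mean asymptote, and a mean-one
lognormal residual with CV `residual_cv` (default 0.10). Canopy state
derives monotonically from residual-free biomass: height saturates as
`h_max·DW/(DW + K)` (h_max = 1 m, K = 250 g/m²), ground cover as
`1 − exp(−DW/300)`, and greenness declines linearly over 600 °C·day after
senescence onset (1600 °C·day). Because height and cover are shared
monotone maps of biomass, rank correlations between geometric traits and
true biomass are exactly 1 when noise is off — a deliberate identifiability
property used by the tests.

Quadrat sampling emits (FW_quad, FW_sub, DW_sub, Quad_area) records with a
dry:fresh ratio drawn uniformly in [0.15, 0.40] and a mean-one lognormal
measurement factor, so the dry-weight arithmetic inverts to the true value
exactly at zero noise and in expectation otherwise.

## Scenes and ROIs

A scene is a two-component pixel mixture: each pixel is plant with
probability equal to the local green-cover fraction, otherwise soil. Plant
pixels take Gaussian-jittered heights (SD 0.05 m) and a plant spectrum
interpolating green → senesced with the senescence index; soil pixels sit
at height 0 with a fixed soil spectrum; 3% multiplicative band noise. The
default ground sample distance of 1/64 m makes the 1 m² ROIs 64×64 pixels.
The permanent ROI is fixed at the plot end; one precise ROI per cut
occupies its own slot along the plot, never overlapping the permanent ROI.
A heterogeneity knob imposes a smooth sinusoidal biomass multiplier along
the plot (random phase per plot); the destructive cut measures the profile
at the precise-ROI position, which is what makes the permanent vs precise
comparison non-trivial when the knob is non-zero.

Not emulated: radiative transfer, view/illumination geometry, wind, mixed
pixels at canopy edges, georeferencing error, and structure-from-motion
artefacts in the CHM. Passing tests therefore demonstrate that the
*pipeline* recovers what the scene model encodes, not that any particular
accuracy carries over to real orthomosaics.

## Phenology and staging

Trial-mean Zadoks score is regressed on thermal time with a cubic B-spline
on 10 equally spaced knots and a second-order difference penalty; the
penalty weight is chosen by generalized cross-validation over a log-spaced
grid (1e-4..1e6, 41 points). Predictions are clamped to [0, 99]. Stage
boundaries are the smallest crossings of the fitted curve at Zadoks 50 and
70, bracketed on a 2048-point grid and polished by bisection to
0.5 °C·day. Thermal time uses base temperature 0 °C (the standard wheat
convention; configurable). Stage classification is inclusive on the
earlier stage: tt ≤ boundary stays in the earlier stage. Where a Zadoks
range and the solved thermal-time thresholds would disagree for an
observation, the thermal-time thresholds govern.

## Trait extraction

The 33 vegetation indices are canonical literature forms over the five
bands, chosen so every formula is finite on strictly positive reflectances;
the registry is a single auditable table. Medians are taken over ROI
pixels (pixel-center-in-polygon inclusion) and over the OSAVI–Otsu canopy
mask; non-finite pixels are excluded. Otsu uses a 256-bin histogram. A
guard handles effectively unimodal ROIs, where Otsu would bisect sensor
noise: if the between-class share of variance at the Otsu split falls
below 0.8 (a single Gaussian mode yields ≈0.64 however it is split; true
soil/plant mixtures on these scenes exceed 0.90 even at 3% cover), the ROI
is treated as a single class — all-soil or all-canopy by comparing its
OSAVI level to the soil/plant midpoint. Masked medians supported by fewer
than 10 pixels are flagged low-support rather than dropped.

Geometric traits use linear-interpolation percentiles; area-below traits
count pixels strictly below the same-ROI percentile times the pixel area
(so a constant canopy has area 0) and are reported in m² (a fraction-of-ROI
option exists); volume divides summed pixel heights × pixel area by the
ROI polygon area, hence equals mean pixel height for pixel-aligned ROIs.
The trait record carries exactly 9 geometric values (4 height percentiles,
3 areas, volume, coverage); the height standard deviation is available
behind an opt-in flag but excluded from the canonical 9 so downstream
column counts stay fixed.

## Feature selection

The correlation filter iteratively removes, from the worst-correlated
pair, the member with the larger mean absolute correlation to all other
retained columns, until no pairwise |r| exceeds 0.95 — the behaviour of the
common reference implementations of this filter. RFE uses an in-package
PLS1 (NIPALS, univariate response) that exposes the cumulative
per-component coefficient path, so a single fit at A components yields
validation predictions for every component count 1..A and the per-component
coefficient contributions; this is what keeps 30 resamples × p subset
sizes × 10 inner folds affordable. Importance is the sum over components
of |rotation × y-loading| weighted by each component's captured response
sum of squares; predictors are standardized inside every resample, never
on pooled data. Inner CV fold assignments derive deterministically from
(outer seed, resample index). Ranks aggregate as mean elimination order
(ties alphabetical); the 1-SE rule picks the smallest subset whose mean
RMSE is within one standard error (over the 30 resample RMSEs) of the best
subset's mean. A `step_fraction` speed option can drop a fraction of
features per iteration for very wide matrices; it is off by default.

## Prediction models

Grid search under 10-fold, 10-repeat cross-validation (fold assignment
reseeded per repeat from the model seed), winner by mean CV RMSE over the
100 fold × repeat evaluations, refit on the full training set. Default
grids stay inside the tuning ranges (PLSR: 1..p components; RF: integer
mtry over 1..p with min node size 5 and variance splitting; SVM: degree
1–2, C {100, 550, 1000}, kernel scale {1e-4, 1e-3, 1e-2}; boosted trees:
20–40 rounds, depth 9–10, eta {0.1, 0.2, 0.3}, gamma 0.8, column
subsampling {0.7, 1.0}); three values per continuous range keeps the
10×10-CV grid search tractable while covering each range's extremes, and
all grids are user-configurable. `plsr_refined` is accepted as an alias of
PLSR — its "refinement" is the RFE-selected subset it is trained on, not a
different learner. Metrics follow the standard definitions R² = 1 −
SSE/SST, RMSE = √(SSE/n), rRMSE = RMSE/mean(obs); an `as_printed` audit
flag reproduces the variant forms (R² as the unexplained-variance ratio,
RMSE without 1/n) that sometimes appear in print. Train/test splits are
stratified by experiment at 80:20.

## Spatial model and repeatability

Per experiment × cut, predicted biomass is modelled as a fixed bilinear
surface plus random genotype, row and column effects and a 2-D
tensor-product cubic B-spline over (row, column) with independent
second-order difference penalties per axis (anisotropic smoothing). The
penalty's bilinear null space {1, r, c, rc} is moved into the fixed
effects, making the penalized block proper; marginal bases use up to 10
knots per axis, capped at the grid dimension. REML runs on the dense
representation (trials here are ≤ ~100 plots) over log variance ratios and
log smoothing parameters, L-BFGS-B, bounds ±16 on the log scale, relative
tolerance 1e-6, 200 iterations maximum, with a convergence flag on the
result. The response is centred internally so translation moves only the
intercept, exactly. Effective dimensions come from the mixed-model
equations, ED_k = q_k − trace(G_k⁻¹ C⁻¹_kk), equal to the trace of the
component's hat-matrix block; fixed dimensions + ΣED + residual ED = n by
construction.

Repeatability is w² = ED_g / (n_genotypes − 1). The alternative printed
normalization — total observation count in the denominator, with the
shrinkage term absorbed as the constant 1 — cannot reach 1 even in the
noiseless limit with replicated genotypes, so it is offered only as an
`as_printed` audit option. w² is computed on out-of-fold CV predictions
(each training row's prediction averaged over the 10 CV repeats), so the
repeatability of a model's predictions is assessed without the optimism of
in-sample fits. Row/column random effects sit alongside the smooth; the
penalties arbitrate their overlap, and effective dimensions make the
trade-off visible.

## Study defaults and problem sizes

The default study uses 8 experiments (seven 21-plot and one 27-plot
BioCal), 5 cuts per plot at thermal-time targets {500, 850, 1200, 1550,
1900} °C·day spanning all three broad stages, 64×64-pixel ROIs, both ROI
types, all 12 stage × variable-set cells and all four learners. Tests and
the acceptance suite run reduced configurations (2 experiments, 3 cuts,
32×32-pixel ROIs, fewer CV repeats) chosen so each check still exercises
the full code path at the package's chosen desk scale; the comparison
structure (12 cells, both ROI types, general vs specific axes) is never
reduced away.

## Known limitations

- The scene model's iid plant/soil pixel draw has no spatial texture, so
  Otsu masking is easier than on real orthomosaics with shadows and mixed
  pixels; coverage is correspondingly clean.
- BioCal designs confound genotype with density within a genotype's three
  plots, so per-experiment w² on BioCal data is intrinsically modest; NVT
  layouts are the right input for genotype-ranking questions.
- REML boundary estimates: with no genetic signal, V_G estimates sit at 0
  in most replicates but are occasionally small and positive — standard
  boundary behaviour, visible in the effective dimensions.
- The phenology spline is fit to trial means; per-genotype phenology is
  out of scope.
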