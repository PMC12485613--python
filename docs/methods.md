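# Methods

This note documents the models implemented in `diazoniche`, their
assumptions, the defaults that matter, and the design choices made
where the underlying field practice leaves room.

## Isotope-tracer rate calculation

A ¹⁵N₂-dissolution incubation enriches the dissolved N₂ pool to
A_N₂ atom% ¹⁵N; fixation transfers that label into particulate
nitrogen. The volumetric rate is

ρ = (A_PN^final − A_PN^initial) / (A_N₂ − A_PN^initial) · [PN] / Δt,

with [PN] in µmol N L⁻¹ and Δt in days, reported in nmol N L⁻¹ d⁻¹.
The model assumes the N₂-pool enrichment is constant over the
incubation and that PN turnover is small relative to Δt. Defaults:
A_PN^initial = 0.3663 atom% (natural abundance, used when no t₀ filter
is available and logged), A_N₂ = 1.41 atom% (SD 0.083) for bulk and
1.56 atom% (SD 0.077) for <10 µm incubations — fixed assay-level
values measured by membrane-inlet mass spectrometry over many bottles.
Negative enrichment is clipped to zero and flagged rather than
propagated into integrals, matching how "no detectable fixation" is
treated in practice.

**Detection limits.** LOD-1 substitutes the minimum atom% difference
the mass spectrometer can resolve (ᵐⁱⁿΔA_PN) into the rate equation;
the generic 0.00146 atom% is the default, and `min_delta_apn` computes
the sample-specific alternative as 3 × SD of replicate standards
(0.00017 atom% → 0.0005 atom%). LOD-2 propagates, by first-order
(delta-method) expansion around the duplicate means, the
between-duplicate SDs of A_PN^final and [PN] together with the fixed
A_N₂ SD; LOD-2 = 3 × propagated SD, the multiplier chosen symmetric
with LOD-1's 3σ convention and configurable. Which terms enter the
propagation is a documented choice here (duplicate spread + enrichment
uncertainty); the delta-method SD agrees with a 10⁵-draw Monte-Carlo
to within 5% for inputs with coefficients of variation ≲10%, which the
acceptance script verifies.

**Depth integration.** Areal rates use the trapezoid over the sampled
PAR depths (100–0.1% of surface light), extending the shallowest
measured rate unchanged to 0 m and truncating at the deepest sampled
depth. Edge rules are a stated choice: surface extension reflects the
well-mixed upper bottle, truncation avoids extrapolating below the
sampled euphotic zone. nmol L⁻¹ d⁻¹ × m converts to µmol m⁻² d⁻¹ with
factor 1.

## qPCR quantification

Standard curves are ordinary least squares of mean Ct on log₁₀ copies
per well over a ≥3-decade dilution series; efficiency is
(10^(−1/slope) − 1) × 100 (slope −3.3219 ⇔ 100%). Unknowns invert the
curve at the mean of amplified replicate wells (≥2 required for a
quantitative call); copies per well convert to copies L⁻¹ via an
explicit scaling factor (elution volume / template volume) divided by
the filtered volume — there is deliberately no hidden default for this
factor. Flags: <25 copies L⁻¹ → `<LOD`, <250 → `<LOQ`. In depth
integration, `<LOD` values are substituted with 0 (configurable) and
`<LOQ` values enter at face value: substitution rules are not
standardized in the field, so both behaviors are explicit options.

## Niche models

Each taxon's niche is a Gaussian-family additive model of log₁₀
depth-integrated *nifH* abundance on SST (°C), dissolved iron (nM) and
phosphate (µM):

log₁₀(N) ~ s(SST) + s(dFe) + s(P),

one penalized cubic B-spline per covariate with basis dimension 6
(configurable). The basis dimension caps each response at gently
multimodal shapes — appropriate for thermal optima and nutrient ramps —
and keeps the model identifiable at a few hundred observations.
Smoothing weights are selected per term by generalized cross-validation
(coordinate search over a log-spaced 10⁻⁴…10⁸ grid, two passes; fits
are cheap so the search is exact on the grid and deterministic);
statsmodels' AIC-based optimizer is available via `select="aic"`.
Non-detect (zero) abundances cannot enter a log response and are
dropped by default; substituting a detection floor is the alternative
option. Confidence bands use the coefficient covariance of the
penalized fit (95%, pointwise).

**Prediction and extrapolation.** The additive structure means a
prediction is the intercept plus one univariate spline evaluation per
covariate. Outside the training range each covariate is clamped to the
hull boundary and the point flagged — free spline extrapolation is
never used, because projections onto global grids routinely leave the
observed covariate hull. Serialized fits (JSON) carry the spline knots,
degree, coefficients and penalty weights for the record, plus dense
512-point per-term effect grids; a reloaded fit predicts by linear
interpolation on those grids (clamped), with interpolation error below
10⁻⁴ log₁₀ units — far below any projection uncertainty — while a live
fit predicts through the exact basis.

## Global projection and dominance

Monthly 1° fields of SST, dFe and P are fed cellwise through the fitted
model; log₁₀ predictions are back-transformed and the 12 monthly
abundance fields averaged in linear space (abundance, not its log, is
the mapped quantity; log-space averaging is an option). Cells missing
any covariate are excluded per month; land stays missing.

A cell is dominated by a taxon when that taxon exceeds 75% (strict) of
the summed predicted abundance of the modelled taxa and the sum
exceeds an abundance floor (strict). Two floors exist as named presets
and both are kept: 10⁴ copies m⁻² (`dominance-map`, for mapping where a
taxon leads the community) and 10⁸ copies m⁻² (`hotspot`, for
delineating candidate high-rate regions); they serve different
purposes and the package does not collapse them. Qualifying cells are
grouped by 8-connected component labeling with longitudinal wrap at
the date line — the operational definition of a "region" here — and
region areas sum spherical cell areas A = R²Δλ(sin φ₂ − sin φ₁) with
R = 6371 km (budget-level accuracy; no ellipsoid). An optional rate
map with a 100 µmol N m⁻² d⁻¹ floor further restricts hot-spot cells.

## Flux budgets and contribution

Regional means come in two flavours: arithmetic (plain mean) and
geometric (exp of the mean log over strictly positive rates; zeros are
excluded and counted, since a single non-detect would otherwise
annihilate the mean). Records measured by the ¹⁵N₂ gas-bubble method or
the acetylene reduction assay can be excluded — both are known to bias
low. Flux conversion uses molar mass 14.007 g mol⁻¹ and a 365-day
year:

1 µmol N m⁻² d⁻¹ over 10⁶ km² = 0.005113 Tg N yr⁻¹.

Budget tables apply one (geometric, arithmetic) rate pair across all
region areas — the construction used when only one region has rate
observations — report totals as exact column sums before any rounding,
and display at one decimal in Tg.

The contribution estimate converts areal gene abundance to cells
(dividing by per-cell gene copy number, "polyploidy"), multiplies by a
cell-specific fixation rate (fmol N cell⁻¹ d⁻¹) and compares with the
measured bulk areal rate. The fraction is never clipped at 100%
(upper confidence bounds can legitimately exceed it). Uncertainty is
propagated by seeded Monte-Carlo over lognormal input distributions
(default 10⁵ draws) rather than the delta method, because the ratio of
lognormal-ish inputs is skewed and its CI asymmetric. Numeric values
for polyploidy and cell-specific rates are required user inputs; the
examples use illustrative synthetic values labelled as such.

## Synthetic data

The generator emulates the study conditions end to end: stations at
six PAR depths (surface bottle at 5 m, deeper depths from exponential
light attenuation at 0.06 m⁻¹), 24 h duplicate bulk incubations plus
one <10 µm bottle, true volumetric rates decaying with depth from a
lognormal surface rate (median 5 nmol N L⁻¹ d⁻¹, geometric SD 2 —
typical of subtropical gyre stations); measured A_PN^final is obtained
by exactly inverting the rate equation at the bottle's drawn N₂-pool
enrichment and adding Gaussian IRMS noise (SD 0.00017 atom%). qPCR
plates use a prescribed curve (slope −3.3219, intercept 37) with 0.1 Ct
replicate noise. The global database draws 737 stations with
covariates uniform over SST 2–32 °C, dFe 0.01–1.2 nM, P 0.01–1.5 µM
and, per taxon, log₁₀ abundance = niche truth + Gaussian noise
(SD 0.5 log₁₀ units); 18% of rows are censored to non-detect, and ~30%
of stations carry an areal rate tagged with a measurement method
(bubble/ARA rates biased low by ×0.6/×0.5). The default UCYN-B truth
is a Gaussian thermal optimum at 27.5 °C (σ = 3 °C), a saturating iron
ramp at 0.2 nM (logistic scale 0.1 nM) and a phosphate optimum at
0.1 µM (σ = 0.25 µM); response widths were chosen so the truths are
well inside what a basis-dimension-6 spline can represent, making the
noiseless-recovery property a test of the fitting machinery rather
than of basis capacity. Environmental grids are smooth analytic
latitudinal fields with a seasonal SST cycle, zonal iron structure and
two idealized rectangular continents.

What the generator does **not** emulate: spatial autocorrelation of
covariates and abundances, covariate measurement error, realistic
coastlines or circulation, inter-taxon interactions, and
depth-resolved niche structure. Passing tests therefore demonstrate
that the estimators recover known truths under the stated noise
models — not that the niche model is correctly specified for real
ocean data.

All generators draw from one seed through named, CRC-keyed substreams,
so a fixed seed regenerates byte-identical datasets and each
sub-generator is independently reproducible. Hidden truth never
appears in analysis-facing tables; it travels in sidecar structures
(`truth/` files in CLI output).

## Problem sizes and numerical choices

The recovery experiment uses 20 seeds × 600 stations (the niche-model
analyses it mirrors use a similar order of observations); Monte-Carlo
oracles use 10⁵ draws; dominance verification uses 1000 random 5×5
grids. GCV grids and coordinate passes are fixed (13 alphas, 2
passes) for determinism. Ties in dominance (shares exactly at
threshold) resolve to "none" because both thresholds are strict.
Degenerate inputs fail loudly: <2 depths for integration, non-positive
standards, undefined tracer (A_N₂ ≤ A_PN^initial), all-zero abundance
shares (returned as NaN with a flag rather than an arbitrary split).

## Known limitations

- The GAM omits spatial autocorrelation and interaction smooths; its
  p-values are conditional on the selected smoothing weights.
- Penalty-weight selection is GCV on a fixed grid; continuous
  optimization could select marginally different weights.
- Reloaded (JSON) fits interpolate effect grids instead of evaluating
  the exact basis; the two paths differ by <10⁻⁴ log₁₀ units.
- Region extraction depends on the grid resolution through
  connectivity; 8-connectivity with wrap is one reasonable
  operationalization of hand-drawn region outlines.
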