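# Methods

This package re-implements, as tested and reusable code, a multi-scale
analysis of how female Arctic caribou select summer forage and respond to
insect harassment. Because the real telemetry is access-restricted by
statute, every analysis runs against a synthetic data module that emulates
the study system's structure under a recorded ground truth; the statistical
machinery itself is general and accepts any data in the documented table
formats.

## Study structure

The season is 1 June-31 August (study days 1-92; day 1 = 1 June), split
into five behaviorally distinct periods: calving (days 1-15), post-calving
(16-24), mosquito harassment (25-45), oestrid-fly harassment (59-68), and
end of summer (77-92). The two calendar gaps (16-28 July, 8-15 August) are
herd-transit windows and belong to no period; their fixes are dropped from
all selection analyses. Calving locations are labeled but selection is not
assessed in that period: persistent snow masks most early-June forage
predictions. "Early summer" covers calving through mosquito harassment;
"late summer" covers the oestrid and end-of-summer periods.

Forage is described by three weekly 250-m gridded surfaces: aboveground
biomass (g/m^2 dry matter), digestible nitrogen concentration (DN, g/100 g
DM), and digestible energy density (DE, kJ/g DM). Forage below 1 g N/100 g
DM or 9 kJ/g DM impairs females - below those thresholds caribou cannot
compensate for quality with intake - so adequacy flags switch exactly there
(the boundary value counts as adequate; strictly below impairs). Static
habitat grids carry elevation (m), aspect class (north/east/south/west/
flat), and snowmelt date (ordinal day). Negative predicted forage values
are clamped to zero. Cell-weeks without a usable forage prediction (the
NDVI snow/cloud mask upstream) are flagged invalid; attribution drops such
rows and reports the dropped fraction per period rather than imputing.

## Insect activity indices

Mosquito (MI) and oestrid-fly (OI) activity are indexed from temperature T
(deg C) and wind speed W (m/s) on [0, 1]. The binding endpoint conditions
are: both indices equal 1 at T >= 18 with W = 0; MI = 0 for T < 6 or W > 6;
OI = 0 for T < 13 or W > 9. Between endpoints each index is a separable
product of clamped linear ramps,

    MI = clamp((T - 6)/12) * clamp(1 - W/6)
    OI = clamp((T - 13)/5) * clamp(1 - W/9),

which is this package's own interpolation: the original field-calibrated
equations are not public, only the endpoints bind, and the construction
lives behind a single function boundary so it can be swapped. At exactly
T = 6 (MI) or W = 6, the ramp value 0 applies, consistent with continuity.
Indices are attributed to points from the nearest coarse weather cell at the
containing hour; MI enters only mosquito-period models and OI only
oestrid-period models.

## Sampling designs

**Landscape scale (second-order selection).** Availability is the 100%
minimum convex polygon around all summer locations minus the ocean,
intersected with the forage prediction area. For each used location, 10
available points are drawn uniformly over prediction-area cells inside the
polygon, each carrying the used point's timestamp (so availability is
week-matched). Uniform-by-valid-cell sampling is used; the alternative
(uniform by area) is identical here because cells are congruent.

**Patch scale (fourth-order selection).** Steps are consecutive fixes 2 h
apart (tolerance +-5 min for telemetry jitter); pairs spanning gaps are
skipped and steps ending outside the prediction area are dropped. Step
lengths per period are fitted by maximum-likelihood gamma (zero lengths are
floored at half the minimum positive length first; at least 30 steps are
required). Each used step anchors a stratum of 10 available steps sharing
its start point, with lengths from the period's fitted kernel and turning
angles uniform on (-pi, pi]; endpoints landing in the ocean or off the
prediction area are redrawn up to 100 times, after which the stratum is
dropped with a logged warning.

**Covariates.** Rows take forage values from the weekly layer containing
their timestamp (day d maps to week ceil(d/7), clamped to the last layer)
and static habitat from their cell; steps are attributed at endpoints and
carry step length. Continuous covariates are z-scored over the full fitting
table (used + available pooled, per period) with the population standard
deviation, so the two-point column {0, 2} maps exactly to {-1, +1};
quadratic terms are squares of the standardized linear columns, and the
means/sds are stored in a manifest that prediction and cross-validation
reuse (new data is never re-centered on itself). Pearson correlations above
|r| = 0.7 (strictly) flag covariate pairs; flagged pairs never co-occur in a
candidate model. Base-habitat terms are fixed by design, so only pairs
involving an optional (forage or insect) term can veto a candidate.

## Estimators

**Mixed-effects logistic RSF.** Used/available (1/0) rows are modeled with
a logit link, fixed effects, and one normal random intercept per
animal-year. The marginal likelihood integrates the intercept by adaptive
Gauss-Hermite quadrature (15 nodes by default): each group's integrand is
recentered on its posterior mode and scaled by the curvature there, found
by a vectorized 1-D Newton iteration, which makes 15 nodes near-exact.
Optimization is L-BFGS-B on (beta, log sigma) with an analytic gradient
(posterior-weighted score); standard errors come from the observed
information, a central-difference Hessian of the marginal log-likelihood.
Convergence failures raise; a variance estimate at the boundary (~0) is
reported with the fit, not treated as an error. With the variance fixed at
zero the model reduces to (and is tested against) plain logistic
regression. Relative selection is exp(fixed linear predictor without
intercept or random effect) - a monotone ranking score, not a probability.

**Conditional-logistic SSF.** The conditional likelihood
prod_s exp(beta'x_used) / sum_j exp(beta'x_j) is maximized by Newton-Raphson
with step halving (convergence: max |score| < 1e-6; coefficients beyond
|beta| = 10 on standardized covariates flag separation and the fit is
returned non-converged with the offending terms listed). Naive covariance
is the inverse observed information; the robust covariance is a sandwich
whose meat sums stratum scores within animal-year clusters with the
G/(G-1) small-sample correction; confidence intervals and p-values built on
robust errors use t quantiles with G-1 degrees of freedom (the standard
few-clusters correction). Step length is a nuisance covariate in every
candidate, correcting the bias from kernel-based availability. Strata whose
used row is lost to forage masking are removed whole.

**Model selection.** Landscape candidates per period: null, base habitat
(aspect + elevation + elevation^2 + snowmelt + snowmelt^2), and base plus
every forage subset with biomass linear or linear+quadratic - 13 candidates
when nothing is flagged, 9 when the late-summer biomass-DE collinearity
rule removes their joint models. Patch candidates are the same with step
length added to the base. AIC = -2 logLik + 2k ranks the landscape fits
(k counts the random-intercept variance). Patch fits use
QIC = -2 logLik + 2 trace(Omega_naive^{-1} V_robust) (the trace form of the
quasi-likelihood independence criterion); the penalty reduces to 2k when
the sandwich equals the naive covariance and grows with within-cluster
correlation. Akaike weights are exp(-delta/2), normalized. Insect-stage
candidates add the index main effect plus every subset of index-by-forage
interaction blocks (the biomass block keeps its quadratic together) to the
period's top forage model: 1 + 2^3 = 9 candidates for a three-block model.

**Cross-validation.** 5 folds x 10 bins x 10 repeats. Folds partition
animal-years, never rows. Per fold, the model refits on the training
animal-years (with training-only standardization), scores the held-out
rows, ranks scores into 10 equal-count bins over available rows
(Boyce-style; the binning basis is available-only, a documented choice
where the design leaves it open), computes the area-adjusted used frequency
per bin, and Spearman-correlates it with bin rank (average ranks on ties).
The mean r_s averages folds then repeats.

**Movement rates.** Log step length is modeled by a Gaussian linear mixed
model with a random intercept per animal-year; the variance ratio
lambda = sigma_b^2/sigma_e^2 is profiled out, leaving a bounded 1-D
optimization. Coefficients and variance components are reported from REML;
AIC uses a maximum-likelihood refit so fixed-effect ladders are comparable
(where software defaults leave the likelihood choice ambiguous, ML-for-AIC
is the defensible convention and is the one used here). The candidate ladder per
insect period is the six models crossing {index absent, linear, quadratic}
with {ordinal-day linear, quadratic}. The harassment ratio is
exp(beta_I (z_hi - z_lo) + beta_I2 (z_hi^2 - z_lo^2)) - the fold-change of
median step length between two index values at fixed ordinal day.

## The synthetic-data generator

The generator is a stand-in for the real NDVI-driven forage surfaces and
restricted telemetry; its defaults are the study conditions and are not
tuned per experiment.

*Landscape.* A 40 x 40 grid of 250-m cells (10 x 10 km) with a west coast:
an ocean strip, a coastal-plain elevation ramp rising inland with smooth
hills plus short-wavelength relief (the relief is what gives a 250-m DEM
its mix of aspect classes), snowmelt later near the coast (noise sized so
|r(elevation, snowmelt)| stays below the 0.7 screen), and ~15% of land
cells excluded from the prediction area to emulate unsampled vegetation
types. Seasonal curves: biomass = base + peak * asymmetric Gaussian around
day 65; DN = brief early rise then exponential decay crossing 1 g/100 g DM
near day 45; DE = saturating rise to a plateau above 9 kJ/g DM. Phenology
is delayed up to 9 days toward the coast. Spatial texture is smoothed
Gaussian noise (bandwidth 3 cells; multiplicative log-normal for biomass,
additive for DN/DE), clamped at zero. Weekly masking selects exactly
round(f_w * n_cells) cells by thresholding a smooth cloud field tilted
toward the coast, with a schedule heaviest in early June (50%) falling to
4% in mid-summer and rising again toward 30% in late August - mirroring the
reported missing-value pattern (46/13/8/8/27% across periods).

*Weather.* Hourly temperature on a 3 x 3 coarse grid = seasonal cycle
(peak near mid-July) + diurnal cycle + smoothed noise, cooler toward the
coast; season-wide values span roughly -2 to 26 deg C so both insect
indices traverse [0, 1]. Wind is truncated-normal around 4 m/s.

*Telemetry.* A step-selection process at the 2-h fix rate: from each
position, 30 candidate endpoints are proposed (gamma length, uniform turn),
restricted to the prediction area, and one is chosen with probability
proportional to exp(beta_ssf' x) on generator-standardized endpoint
covariates. Default coefficients follow the early-summer patch-scale
magnitudes (biomass 0.48, biomass^2 -0.12, DN 0.42, DE 0.16, elevation
-0.49, elevation^2 0.11). Insect harassment multiplies the step-length
scale by exp(0.92 * MI) in the mosquito period (a ~2.5-fold range, the
magnitude reported for real caribou) and exp(0.15 * OI) in the oestrid
period; a log-normal per-animal speed multiplier (sd 0.25) plays the
movement model's random intercept.

*Landscape-scale point sampler.* The trajectory process realizes
landscape-scale selection only emergently, so calibration of the RSF
machinery uses a direct sampler that draws used cell-weeks jointly with
probability proportional to exp(beta_rsf' x) over prediction-area
cell-weeks. Against timestamp-matched uniform-by-cell availability this is
exactly the law the pooled use-availability logistic assumes. Default
landscape coefficients use early-summer magnitudes with deliberately
distinct values (biomass 0.90, biomass^2 -0.60, DN 0.65, DE 0.35, elevation
-0.80, elevation^2 0.20, snowmelt -0.40, snowmelt^2 0.15, plus small aspect
effects) so that rank-order recovery is well defined.

*What the generator does not emulate.* Real NDVI error structure and the
fitted forage regressions behind the true surfaces; GPS error; home-range
fidelity, memory, or directional persistence (turning angles are uniform);
inter-animal heterogeneity in selection (only intensity and speed vary);
density dependence. Passing tests therefore demonstrate that the estimators
recover the truth when the data follow the assumed designs - not that the
designs are robust to these real-world departures.

## Calibration experiments and their scales

Tests and the acceptance suite run the full chain at sizes chosen to be
informative yet tractable on one core:

- SSF recovery: 20 replicates of 50 animal-years x a full season (~670
  strata each after gap/mask filtering), pooled across analysis periods
  with period-specific kernels. Fitted coefficients are mapped to the raw
  covariate scale (the affine de-standardization, with delta-method SEs)
  and compared with the generator truth mapped the same way - the two
  standardizations (per-table vs landscape-wide) make the raw scale the
  only common currency. The criterion is +-15% or +-3 robust SE for every
  effect of magnitude >= 0.3.
- RSF recovery uses a single-week window. With timestamp-matched
  availability, between-week density differences are conditioned out of
  the likelihood, and a pooled multi-week fit without week effects targets
  a slightly different estimand (the weekly normalizer acts as an omitted
  covariate); within one week the estimand equals the truth exactly, which
  is the correct setting for calibrating the machinery. Signs of all strong
  effects and the rank ordering of |beta| are checked.
- Model selection: the generating structure (base + BM + BM^2 + DN + DE)
  must win AIC on 20 landscape replicates (10 animal-years x 150 points,
  mosquito period) and QIC on the mosquito-period strata of the 20 SSF
  replicates, in at least 80% of each.
- Cross-validation: the true landscape model on strong-selection data
  yields mean r_s >= 0.9 (field analyses of this system report 0.91-0.99);
  permuted scores stay inside |r_s| < 0.3.
- Movement: a standardized MI coefficient of 0.4 at 50 animal-years x 200
  steps is recovered within +-0.05, and the quadratic ladder is selected
  by AIC when the truth is quadratic.

## Numerical choices and degenerate inputs

Grid lookups use cell-center registration with half-open intervals (a point
on a shared edge belongs to the higher-index cell). Points off the grid or
weather extent raise attribution errors listing offending rows - never
silent drops. Aspect dummy levels absent from a fitting table, or present
in only one response class (a certain-separation column with no finite
MLE), are omitted and fold into the reference level; aspect values outside
the five known classes are an error. Gamma kernel fitting refuses zero-variance lengths;
standardization refuses zero-variance covariates; the MCP refuses collinear
point sets; strata without exactly one used and at least one available row
are rejected. Optimizer tolerances: mixed logit L-BFGS-B ftol 1e-13 /
gtol 1e-7; clogit Newton max|score| < 1e-6; LMM profile xatol 1e-10 on
log lambda, bounded to [-15, 10]. All randomness flows from
numpy SeedSequence spawns of one run seed; identical configuration and
seed reproduce every output byte-for-byte.

## Known limitations

- The insect-index interpolation between the defining endpoints is a modeling
  choice; only the endpoint lattice is authoritative.
- The multi-week pooled RSF estimand differs mildly from the generating
  coefficients whenever weekly availability shifts (see above); this is a
  property of the timestamp-matched design itself, shared with any field
  analysis, not of the implementation.
- Available steps are drawn from the kernel fitted to observed (selected)
  steps, not the latent proposal kernel; with only a linear step-length
  correction a small transfer bias remains (empirically within a few
  percent here).
- Animal-year clustering captures within-animal dependence but not the
  cross-animal dependence that arises when many animals reuse the same
  spatially correlated cells; on landscapes small relative to the
  correlation range the sandwich intervals undercover (measured directly
  in the null-selection calibration, which therefore runs at the default
  40 x 40 extent where coverage is nominal).
- QIC uses the standard trace form; other software may use variant
  penalties, so absolute QIC values are comparable only within this
  package.
- The gridded outputs are dense arrays with a YAML sidecar, not
  georeferenced rasters; there is no CRS handling.
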