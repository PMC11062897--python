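# Methods

This note documents the models implemented in `tundratrack`, the design
of the synthetic study system, the numerical choices, and what the tests
do and do not establish about real data.

## The study system being emulated

The package targets the analysis of a High-Arctic hare population tracked
with Argos collars: ~25 individuals with daily fixes over ~12 months, a
summer residency, a fall relocation of roughly 100 km with stopovers, and
a winter residency, over a polar-desert landscape of sparse vegetation,
rugged relief and scattered lakes. The real data are not required
anywhere: the synthetic module generates landscapes and trajectories with
the statistical structure the analysis assumes, plus known ground truth
(true behavioral states, true phase labels, designed selection effects).

## Synthetic landscapes

`make_landscape` builds co-registered rasters on a projected grid in
meters (default 120 × 160 km at 100-m cells):

- **Vegetation index (SAVI-like).** Three Gaussian random fields (white
  noise filtered with a Gaussian kernel whose sd is half the stated
  correlation range): a broad productivity field (range 5 km, sd
  `sqrt(sill)` = 0.063), a fine patchiness field (grain 100 m, sd 0.05),
  and a smooth amplitude field (range 2 km) that modulates the patchiness
  locally. The sum is shifted to mean 0.2 and clipped to [0, 0.6]. The
  modulated-patchiness construction is deliberate: it makes the *local
  standard deviation* of the index a real landscape property
  (patch-mosaic heterogeneity), varying smoothly at the kilometre scale,
  so that (a) buffer-sd extracted at different Argos error radii measures
  the same quantity (mean buffer sd differs by only ~17% between 250-m
  and 1500-m buffers), and (b) a behavioral response to heterogeneity is
  physically well-defined. With a single smooth field instead, buffer sd
  is dominated by the buffer radius — an artifact of coarse synthetic
  smoothness that fine-grained real imagery does not show. The moderately
  high mean (0.2) keeps clipping at zero below 2% of cells; heavier
  clipping couples buffer mean to buffer sd and confounds the two
  covariates.
- **Elevation.** Base 400 m plus a 200-m-sd field with 12-km range,
  clipped at sea level. Slope/aspect are derived with Horn's 3 × 3
  method; aspect is the downslope direction clockwise from north, nodata
  where flat.
- **Water.** Random ellipses (median radius 500 m) accumulated until 3%
  of the area is covered; water cells are nodata in the vegetation index.
- Optional NIR/Red bands are back-computed from the index so that the
  soil-adjusted vegetation index SAVI = (NIR − Red)(1 + L)/(NIR + Red + L)
  with L = 0.5 reproduces it exactly (L = 0 gives NDVI).

## Synthetic trajectories

Each animal holds a summer residency (state-1 movement tethered to a
range center within ~1.5 km), then with probability 21/25 departs between
day 70 and 100 toward a winter goal ~100 km away (±15%, bearing mostly
southward), and settles on arrival. During relocation the behavioral
state follows a two-state Markov chain; steps are gamma
(stopover mean 0.4 km/day, sd 0.4; travel mean 6 km/day, sd 3) and turns
wrapped Cauchy (concentration 0.2 vs 0.8). The default transition matrix
[[0.8, 0.2], [0.4, 0.6]] has stationary distribution (2/3, 1/3) — the
observed regime of about twice as many stopover as traveling locations —
with mean bout lengths of 5 and 2.5 days. The directional pull to the
goal enters only through the traveling state's heading (drawn around the
bearing to the goal), leaving within-state step and turn distributions
intact so HMM recovery against ground truth remains meaningful.

**Designed selection effects** (each switchable off):

- *Stopping vs vegetation heterogeneity.* During relocation the
  probability that the next day is a stopover is tilted on the logit
  scale by `effect × z`, where z is the landscape-standardized local SAVI
  sd in a 1.5-km window (the scale the error-radius buffers measure) at
  the current position. At the default effect 0.4, the realized marginal
  effect on true states at true positions is ≈ 0.4–0.5 per sd.
- *Residency site selection.* Summer range centers are drawn from
  candidate sites weighted by exp(−1 × z(elevation)); winter goals by
  exp(+1 × z(smoothed SAVI)), using a 2-km-smoothed field because a
  home-range *mean* can only respond to neighborhood-scale vegetation,
  not a single cell.

**Argos degradation.** Each retained day draws a location class and adds
isotropic bivariate normal noise with per-axis sd = radius/√2, so the RMS
radial error equals the class's nominal radius (250/500/1500 m for
classes 3/2/1; class A carries no accuracy estimate and is treated as
1500 m). 9% of days are dropped at random. `apply_argos_error` defaults
to a uniform class mix; the pipeline configuration instead uses
{3: 0.76, 2: 0.20, 1: 0.03, A: 0.01} — the distribution of the *best of
about five* attempts per 3-h daily duty cycle when each attempt's class
is uniform (P(no class 3 in 5 draws) = 0.75⁵ ≈ 0.24) — because the
simulated fix stands for the best daily fix the cleaning chain keeps.

## Cleaning and segmentation

The speed filter is a forward sweep: a fix is dropped when the
straight-line speed from the last retained fix exceeds 5 km/h, unless the
gap is under 10 min and the speed under 10 km/h. Best daily fix keeps the
smallest-error class, ties to the earliest fix.

Phase segmentation uses the 5-day centered rolling mean of net daily
displacement with a 2 km/day threshold. Because relocating animals pause
for days at stopovers, super-threshold runs separated by sub-threshold
gaps of up to `merge_gap` days (default 45 — longer than any
within-relocation pause, shorter than a residency) are merged before the
maximal run is taken; `merge_gap = 0` recovers a plain maximal-run rule.
Without merging, the detected interval covers only ~60% of true
relocation days and the missing days are ~85% stopovers, which would
selectively discard exactly the locations the stopover analysis needs.
The delegated departure/arrival rule of the original tracking study is
not published in detail; this rule is validated only against simulator
truth. Missing days inside the relocation interval are filled by linear
interpolation, flagged, and assigned class A (1500-m buffer downstream);
interpolated fixes enter the HMM likelihood as ordinary observations.

## Home ranges and the null model

The 100% a-LoCoH home range is the union of local convex hulls: each fix
roots a hull over neighbors added in order of distance while the
cumulative distance stays within `a` (default: maximum pairwise
distance). Stability uses the area-observation curve on chronological
prefixes, holding `a` at its full-data value so the curve measures data
quantity rather than growth of the heuristic. An individual is stable
when n > 50 and the area varies by less than 15% (relative to the final
area) over the last 20% of the curve. The 15% tolerance is deliberate:
under the stated Argos noise the a-LoCoH area of a genuinely resident
individual still creeps 5–15% over the last fifth of the curve (convex
hulls of noisy point clouds grow without bound), while unsettled or
drifting tracks show 30–80%; a 5% rule would reject nearly every
resident. Both `a` and the tolerance are configuration options.

Availability is the pooled seasonal 100% MCP dilated by the radius of the
circle whose area equals the mean individual MCP (override available),
clipped to the mapped extent, minus water. Random home ranges are rigid
copies — rotation uniform on [0, 2π), centroid uniform over the domain's
bounding box — accepted only when the whole polygon lies inside the
domain (covariates are extracted over whole polygons), rejection-sampled
with a per-copy cap; an individual whose range cannot be placed is
excluded and logged rather than silently shrunk.

## HSF inference

Used (observed ranges, 1) vs available (random ranges, 0) units enter a
plain binomial GLM with logit link — no random effects, since each
individual contributes one range per season. Covariates are standardized
(sample sd, pooled over used and available; configurable) and pruned
greedily in a biological priority order so no retained pair has Spearman
|ρ| > 0.7 (strict). All subsets up to `max_terms` (default 3) plus the
null and the full set are ranked by AICc = −2ℓ + 2K + 2K(K+1)/(n−K−1)
with n = number of used + available units; evidence weights are computed
over the whole fitted set. Within the ΔAICc < 2 support set, models with
any 85% Wald CI overlapping zero are flagged (AIC-based selection retains
a variable roughly when its 85% CI excludes zero), and the retained model
is the most parsimonious unflagged supported model (fewest K, then lowest
ΔAICc). Aliased subsets (the four aspect-class proportions sum to one)
and separated fits are dropped from the candidate set with a warning. A
coefficient of the fitted logit is the log relative selection strength
per 1-sd covariate change; `log_rss_curve` evaluates it against the
sample-mean profile with Wald bands.

## Movement HMM

Observations are daily step lengths (km) and turning angles; state s
emits gamma(mean μ_s, sd σ_s) steps and wrapped Cauchy
(mean θ_s, concentration ρ_s) angles, with missing components
contributing a unit factor. The likelihood is a scaled forward pass,
vectorized across individuals by NaN-padding series to a common length
(padded unit emissions leave each series' likelihood unchanged because
transition rows sum to one). Fitting maximizes the joint likelihood
numerically (L-BFGS-B) on unconstrained working scales — log for μ, σ;
logit for ρ and the transition off-diagonals; the angle mean through an
(cos, sin) pair — from 10 random starts in behaviorally plausible ranges
(stopover step mean U(0.1, 2) km, travel U(3, 15), sds U(0.1, 5),
ρ U(0, 0.95), diagonal U(0.7, 0.95)); convergence additionally requires
the two best starts to agree within 10⁻³ log-likelihood units. States are
relabelled so state 1 has the smaller step mean ("stopover"). K counts
4 emission parameters per state plus n(n−1) transition entries plus the
initial distribution (11 for two states; 10 under the stationary-initial
convention — both AICs are reported). Goodness of fit uses one-step-ahead
pseudo-residuals of step lengths (forecast CDF through the normal
quantile function) with a Kolmogorov–Smirnov summary; decoding is exact
Viterbi in log space.

On noisy observed series the fitted stopover step mean is
error-inflated (≈ 0.6–1.1 km against a true 0.4 km under the default
noise), as expected: the observation error adds ~2 × 250–1500 m of
day-to-day jitter. Decoding accuracy against ground truth is ~95%.

## Latent selection difference

One row per decoded relocation fix; the response is stopover (1) vs
traveling (0); covariates are buffer means (plus the SAVI sd) over a
circle whose radius matches the fix's error class, standardized pooled.
The model is a logistic GLMM with a normal random intercept per
individual, fitted by maximizing the adaptive Gauss–Hermite approximation
of the marginal likelihood (15 nodes; the per-group mode is found by
vectorized Newton iterations and one node recovers the Laplace
approximation). The implementation agrees with lme4's `glmer`
(nAGQ = 15) to ~10⁻³ in coefficients, random sd, and log-likelihood, and
reduces to the plain GLM as the random sd is driven to zero; boundary
fits are reported as singular. Candidate sets follow the same
AICc/support/uninformative rules as the HSF, with the SAVI × elevation
interaction admitted only alongside both main effects; K counts fixed
effects plus the random-effect variance. Odds ratios are exp(β) with
exp(β ± 1.96 SE) intervals; interaction curves report the relative
log-odds of stopping vs SAVI at 100/500/900 m elevation (converted
through the stored standardization metadata). The bootstrap ROC AUC
resamples rows with replacement *within* individuals (the grouping unit;
999 repetitions by default) and scores the fixed-effect linear predictor;
single-class resamples are redrawn and counted.

## Problem sizes and experiment designs

The recovery experiments in `tundratrack.evaluation` use: 20 tracks × 80
days for HMM recovery (5 random starts); 500 replicates at n = 600 for
HSF bias/coverage; 100 replicates at 20 groups × 100 observations for
random-sd recovery; 100 replicate track sets (21 relocating animals ×
170 days on one shared 120 × 160 km landscape) for the end-to-end
stopover-selection harness, which decodes with an HMM fitted once to
observed calibration series — as the pipeline does — rather than with the
generating kernel, whose stopover state no longer matches error-inflated
steps. The default pipeline run uses 25 individuals × 365 days at 100-m
cells. These sizes make the full suite run in minutes on one CPU while
leaving the statistical checks well-powered.

## What passing tests do and do not show

The generator reproduces the *structure* of the real study (sampling
design, error model, movement regimes, selection mechanisms) but not its
full complexity: real SAVI has seasonal dynamics, snow, and sensor
artifacts; real movement has diel structure, individual heterogeneity in
kernels, and memory; real Argos errors are heavy-tailed rather than
normal (the radii are nominal; the distribution shape is an assumption).
Parameter recovery here therefore demonstrates correctness of the
estimators under the stated model, not robustness to all real-data
violations. The headline fitted quantities of the motivating field study
(log-RSS values, its HMM AICs, its AUC, its home-range areas) depend on
the real rasters and tracking data and are not reproduced numerically;
what is reproduced is every recomputable piece of arithmetic (evidence
weights from the ranking tables, the stopover time budget) and the
qualitative structure (direction of seasonal selection effects, 2-state
superiority, ~2:1 stopover budget, AUC in the 0.55–0.65 band, summer
ranges of ~10 km²).

## Known limitations

- Zonal statistics use cell-center membership (adequate for 10–100-m
  cells against km-scale polygons; no area weighting).
- The GLMM supports a single random intercept (no random slopes or
  crossed factors), matching the analysis it implements.
- The HMM gradient is finite-difference; fits with > 2 states are out of
  scope.
- The phase-segmentation defaults are validated against simulator truth
  only; the original study's delegated rule may differ.
- `range_stability` judges an asymptote on a noisy, slowly growing
  curve; its tolerance trades resident recall against drift detection
  and is exposed in configuration.
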