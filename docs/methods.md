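# Methods

`soarlift` reimplements, on synthetic data, an analysis chain that links the
flight modes of GPS-tracked soaring birds to the fine-scale spatial
distribution of updrafts. This note records the models, their assumptions,
the numerical choices, and what the synthetic data do and do not establish.

## Uplift models

**Orographic uplift.** Horizontal wind of speed *v* striking sloped terrain
is deflected upward on windward faces. Per cell,

    w0 = v · Cα,   Cα = sin(θ) · cos(α − β)

with θ the terrain slope, β the terrain aspect (compass, downslope) and α
the meteorological wind direction-from. Cα ∈ [−1, 1]; negative values mark
leeward terrain where eddies and lee waves, not smooth deflection, dominate,
and are clamped to 0. Slope and aspect come from Horn's 3×3
finite-difference method (the algorithm behind the standard GIS Slope and
Aspect tools); border cells and cells with nodata neighbours are nodata, and
flat cells carry an undefined-aspect sentinel that maps to Cα = 0. Terrain
channelling and wind sheltering are not modelled.

**Thermal uplift.** The convective velocity scale

    w* = (g · z · H / θₚ)^(1/3)

uses a representative flight height *z* above ground (default 400 m,
recomputable as the mean height of active flight), the surface sensible heat
flux H = ρ·c_p·(Tₛ − Tₐ)/r_a from a land-surface-temperature raster, and the
potential temperature θₚ = Tₐ·(p₀/p)^k of the boundary layer. Constants
default to: ρ = 1.225 kg m⁻³, Tₐ = 288.15 K, p₀ = 1013.25 mbar,
p = 898.7457 mbar (1 km above sea level), k = 0.2854, g = 9.8 m s⁻²,
r_a = 208/v₂ₘ for a grassland surface. c_p is set to 1.0035 — the
heat-capacity figure on the kJ scale — rather than 1003.5 J kg⁻¹ K⁻¹. This
is deliberate: the uplift velocities enter downstream models only as
covariates, where any fixed rescaling is absorbed by the slope coefficient,
and the resulting w* magnitudes (roughly 0–3 m s⁻¹) are the scale on which
the association models operate. All constants are exposed and overridable.
Cells with H ≤ 0 (surface colder than air) get w* = 0, paralleling the
clamping of negative Cα; the alternative of propagating a negative
"uplift" has no physical reading for a soaring bird.

The two rasters may differ in resolution (30 m orographic vs 100 m thermal);
each is sampled independently at segment centroids by the nearest-cell rule
with half-open cell intervals [x, x+cell) — no resampling or interpolation.

## Track processing

Fixes arrive at 10-s nominal cadence. Filtering keeps the daylight window
(08:00–19:30 local, boundaries inclusive), drops missing coordinates and
exact consecutive coordinate repeats (stuck GPS readings). Continuous flight
sections end at gaps > 30 s (three missed fixes) or where ground speed stays
below 1 m s⁻¹ for ≥ 60 s (perched or walking; interior fixes of such spells
are discarded). There is no universal definition of a "continuous flight
section"; this rule is the package's own choice and both thresholds are
configurable.

Sections are cut into non-overlapping half-open 200-s windows anchored at
the first fix of each section; windows with fewer than ten fixes are
dropped. Eight parameters are computed per segment: mean altitude above
ground (AGL), first-to-last horizontal displacement and elevation change,
mean ground and vertical speed over consecutive-fix velocity vectors,
directional variance, tailwind component, and heave amplitude.

*Directional variance* is the circular variance 1 − R̄ of the velocity-vector
compass directions (R̄ = mean resultant length), bounded in [0, 1]: 0 for a
straight track, →1 for circling. The doubled convention 2(1 − R̄) used by
some circular-statistics software is available behind a flag but is not the
default — a [0, 1] scale is what the downstream clustering expects.
*Tailwind component* is the unitless cosine of the angle between the mean
velocity vector and the downwind direction (+1 downwind, −1 headwind) — a
bounded projection, not a speed in m s⁻¹; typical values are ≈0.4 for slope
soaring (partly wind-directed) and ≈0 for goal-directed glides. *Heave amplitude* is
the mean absolute deviation of all 1-Hz dorso-ventral acceleration samples
in the window about their mean, missing when fewer than ten samples are
available. When wind is supplied as a time series, each segment uses the
most recent record at or before its window midpoint.

## Flight-mode classification

Segments are clustered on (elevation change, directional variance) with
K-means (k-means++, 25 restarts, seeded). Features are z-score standardized
first: elevation change spans hundreds of metres while directional variance
lives in [0, 1], and unstandardized K-means would ignore the second axis.

The number of clusters comes from the gap statistic: for each k ≤ 10,
gap(k) = mean_b log W*_b(k) − log W(k), where W is the within-cluster
dispersion and the B reference sets are drawn uniformly over each observed
feature range; standard errors carry the √(1+1/B) factor. k is selected by
the first-SE-max rule — the smallest k whose gap lies within one standard
error of the first local maximum. Seeding is fully deterministic and
documented in the docstring so an independent reimplementation can
reproduce it draw for draw.

With three clusters, labels follow centroid geometry: lowest mean elevation
change → gliding; of the remaining two, higher directional variance →
circular soaring, lower → linear soaring; ties on elevation change break by
directional variance (the straighter cluster glides). Boundary exclusions
then remove (i) glides with elevation change above −15 m, (ii) soaring
segments with elevation change below +15 m, and (iii) 15% (round-half-up)
of the remaining soaring segments whose standardized directional variance
is closest to the midpoint between the circular and linear centroids — this
package's operationalization of "standing at the boundary" between the two
soaring modes. Exclusion never relabels.

## Association models

Non-excluded segments become observations: uplift sampled at the segment
centroid, response 1 for the soaring mode under test (circular or linear)
and 0 for gliding — glides serve as null observations of soaring because
they do not depend on uplift. Observations with orographic uplift above a
configurable threshold can be removed; such rare high-leverage points are a
documented cause of convergence trouble in this model family.

The binomial GLMM has logit link, fixed effects for thermal and orographic
uplift, and *crossed* random intercepts for bird identity and day of data
collection (day is plausibly nested in bird for a migration camp, but the
model statement names two factors symmetrically; crossing is the faithful
reading and nesting can be emulated by recoding day labels). Estimation is
maximum likelihood under the Laplace approximation, implemented here:
random effects are parametrized spherically (u = σv, v ~ N(0, I)) so the
σ = 0 boundary is regular; for candidate (σ_bird, σ_day, β) the v-mode is
found by damped Newton iterations and the Laplace objective
ℓ(η̂) − ½‖v̂‖² − ½ log det(I + SZ'WZS) is maximized by Nelder-Mead,
warm-started from a cheaper stage that profiles β jointly with v. Wald
standard errors come from the Schur complement of the random-effect block
of the joint negative Hessian; p-values are two-sided normal. The
implementation agrees with lme4's `glmer` (an independent Laplace-ML
implementation) to a few parts in 10⁴ on shared test data, and collapses
exactly to ordinary logistic regression when both variances are pinned at
zero. Complete separation and degenerate responses raise rather than
returning garbage.

Gaussian mixed models compare a flight parameter between the two soaring
modes (fixed factor: mode; same crossed intercepts; REML via statsmodels
MixedLM with variance components). AGL and ground speed are right-skewed
and positive, hence log-transformed when requested.

Goodness of fit is the marginal/conditional R² for mixed models: with
σ²_f the variance of the realized fixed-effect linear predictor over the
data (not a coefficient-only formula),

    R²_marg = σ²_f / (σ²_f + σ²_bird + σ²_day + σ²_resid)
    R²_cond = (σ²_f + σ²_bird + σ²_day) / (same denominator)

where σ²_resid is the Gaussian residual variance or π²/3 on the logit
scale. Marginal ≤ conditional and both lie in [0, 1] by construction.

## Synthetic data generator

The generator emulates the study conditions: 21 birds tracked over 3 days,
≈120 fixes per bird-day at 10-s cadence, 20-s 1-Hz accelerometer bursts
every 3 min, a 30-m DEM (Gaussian hills plus a ridge crossing the easterly
wind), a 100-m LST raster (base 305 K minus a 0.02 K m⁻¹ elevation lapse
plus correlated noise, so valleys run warmer and host stronger thermals),
and a levanter wind scenario (from 115.7° at 10.4 m s⁻¹).

Birds fly bouts of three modes; bout durations are exponential (mean 300 s,
clipped to [200, 600] s) and bouts are separated by short gaps so analysis
segments are mostly pure-mode. At each bout start the log-odds of soaring
vs gliding are β₀ + β_oro·w₀ + β_th·w* + u_bird + u_day, and of linear vs
circular soaring β₀' + β_oro·w₀ − β_th·w*; defaults β_oro = β_th = 0.8,
var(bird) = 0.5, var(day) = 0.2. Mild altitude housekeeping (forced glide
far above, forced climb far below the 400-m working band) keeps tracks
airborne. Central kinematic rates are values typical of mid-sized soaring
raptors:
climb 0.66 (circular, helix of ~30 m radius and 35-s period) and
0.61 m s⁻¹ (linear), sink 0.83 m s⁻¹, speeds 5.4/7.3/9.7 m s⁻¹. In the
campaign generator the rates vary between bouts with realistic
segment-to-segment spreads (SD ≈ 0.47/0.50/0.56 m s⁻¹ for climb/sink,
1.2/2.4/3.4 m s⁻¹ for speed), and nominally straight tracks
carry a small per-fix heading random walk (4°/2° for linear/glide).
Linear-soaring bouts head along the terrain contour in the sense nearer
downwind — slope-soarers track the windward face rather than crossing the
crest — which reproduces the high tailwind component of slope soaring and
keeps those bouts over high-w₀ cells. GPS noise is isotropic Gaussian,
1.5 m in all three axes. Heave is Gaussian with mean absolute deviation
0.15 g while soaring (flapping reference 0.30 g). A truth table records
the generating mode of every bout, making the whole chain testable by
parameter recovery.

A companion model-scale simulator draws observations directly from the
binomial GLMM (default n = 2000 segments, 20 birds, 3 days) for estimator
recovery studies where full-trajectory replication would be wasteful.

**What the synthetic data do not show.** Kinematics are geometric, not
aerodynamic: no turbulence, no boundary-layer dynamics, no wind drift
inside thermals, no flapping bouts. The LST field is a smooth lapse model,
not a land-cover mosaic. Mode choice is memoryless given position, whereas
real birds plan routes. Passing tests therefore demonstrate that the
pipeline recovers structure *of the kind the analysis assumes*, not that it
would recover it from any particular field dataset.

## Numerical choices and degenerate inputs

Seeds control every stochastic component (reference-set draws, K-means
restarts, trajectory noise); identical seeds give identical output to the
byte. The gap-statistic dispersion uses K-means inertia; the test suite
checks it against an independent pairwise-distance computation at 1e-9.
Raster nodata is NaN internally and propagates through all raster algebra.
Empty or single-class responses, unconverged fits, degenerate
(zero-variance) features, sub-3×3 rasters, points off the raster, and
non-increasing time stamps all raise typed errors early. Round-half-up is
used for the 15% exclusion count.

## Known limitations

* The first-SE-max rule is sensitive to within-mode dispersion. On pure
  200-s single-mode segments the gap statistic selects k = 3 cleanly; on
  full campaign output — where partial windows and between-bout rate
  variation smear the elevation-change axis — the gap curve can show a
  spurious early local maximum and stop at k = 1. For campaign-style
  synthetic data
  `classify_segments(..., force_k=3)` reproduces the three-mode structure
  (and the boundary exclusions then behave as designed). This sensitivity
  is a property of the method, not a bug in either implementation.
* The thermal covariate spans only ~0.8 m s⁻¹ across the synthetic scene
  (the cube root flattens heat-flux contrasts), so campaign-level fits
  estimate the thermal effect with wide intervals; the orographic effect,
  spanning several m s⁻¹, is recovered sharply.
* w* where H < 0 is a modelling choice (zero), as the source model is
  silent; any monotone alternative would only relabel cells that carry no
  usable lift anyway.
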