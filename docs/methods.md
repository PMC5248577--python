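# Methods

## The conditional two-species occupancy model

A survey consists of S site-year units (a camera station in one survey
year) observed on J daily occasions within one focal month. Each unit is
in one of four latent states — both species present, dominant A only,
subordinate B only, neither — with prior probabilities

    P(AB)      = ψ^A ψ^BA
    P(A only)  = ψ^A (1 − ψ^BA)
    P(B only)  = (1 − ψ^A) ψ^Ba
    P(neither) = (1 − ψ^A)(1 − ψ^Ba).

Conditional on the state, daily detections are independent Bernoulli
draws with no false positives: in state AB the dominant is detected with
r^A and the subordinate with r^BA (if A was detected that day) or r^Ba
(if not); in single-species states detection uses p^A or p^B. Detection
is time-constant within the month — a deliberate restriction, matching
the survey design the package targets, that lets the per-site likelihood
be computed from the four per-site counts of (1,1), (1,0), (0,1), (0,0)
occasions. The site likelihood marginalises the latent state (it never
conditions on what was observed), and unsurveyed occasions contribute a
factor of one. Sites with no surveyed occasion contribute zero to the
log-likelihood, with a warning.

All eight parameters use a logit link. A model specification assigns each
parameter a design — intercept only `(.)`, year-group factor `(y)`, a
site covariate such as `(peccary)`, or a year-by-covariate interaction
`(y*peccary)` — and may constrain groups of parameters to share one
coefficient block (e.g. `pA=rA`, `pB=rBA=rBa`, the "detection does not
depend on the other species" hypotheses). Year groups are factor
contrasts against the first year; covariates enter additively on the
logit scale.

### Fitting and uncertainty

The negative log-likelihood is minimised by L-BFGS-B with multi-start:
the first start is the zero vector (all parameters at 0.5), the rest are
drawn from U(−2, 2) on the logit scale under a fixed seed; convergence
failures keep the best point found and set `converged_ = False`. The
coefficient covariance is the inverse of a central-difference numerical
Hessian at the optimum (step 1e-4 scaled by coordinate magnitude); a
singular or non-PSD Hessian yields absent standard errors rather than a
failed fit. Derived quantities use the delta method with numerical
gradients through the full coefficient vector.

Estimates on the boundary (e.g. ψ^BA → 1 when the subordinate occurs
everywhere the dominant does) are reported at their constrained value and
flag `se_reliable_ = False`: Wald standard errors are not trustworthy
there.

### Reported quantities

Real-scale parameters are reported per year group, evaluated at the
within-group sample mean of each covariate (a reporting convention; any
covariate row can be scored with `predict_site_params`). The Species
Interaction Factor

    φ = ψ^A ψ^BA / ( ψ^A [ψ^A ψ^BA + (1 − ψ^A) ψ^Ba] )

equals the ratio of joint occupancy ψ² = ψ^A ψ^BA to the product of the
two marginal occupancies; φ is computed from the *unrounded* estimates.
Published two-decimal tables cannot generally be reproduced by plugging
their own rounded entries into this formula — e.g. a printed column
(0.28, 1.00, 0.28) gives φ = 2.08 regardless of what the source table
prints beside it — which is why the package never back-fills φ from
rounded inputs.

AICc uses the number of site-year units as the effective sample size n:

    AICc = −2ℓ + 2K + 2K(K+1)/(n − K − 1).

No consensus exists on n for occupancy models (sites, site-occasions, or
something between), so absolute AICc values from other software may
differ by a penalty term; ΔAICc ranking within one software is the
meaningful quantity. K counts free coefficients after constraints; a
model whose K exceeds n − 1 gets AICc = NaN with a warning.

## Activity patterns on the circle

### Sun time

Each photo's clock time is mapped to an angle with sunrise anchored at
π/2 and sunset at 3π/2, interpolating linearly inside the day and night
segments, so solar noon is π and the night midpoint is 0 regardless of
season. Sunrise and sunset come from the standard solar-position
equations (fractional-year Fourier series for declination and the
equation of time; zenith 90.833°), accurate to about ±2 minutes at the
mid-latitudes intended here; polar day/night raises an error. Anchors
are computed per survey year as the mean sunrise/sunset over that year's
events (dates × station coordinates): one mapping per year keeps the ±1 h
crepuscular bands at fixed angles within a year. The UTC offset defaults
to −7 (local standard time of the Sonoran study region) and is
configurable.

Double anchoring was chosen over single-anchor alternatives because it
makes both anchors season-invariant, which is what turns "±1 h around
sunrise and sunset" into fixed angular windows: 1 clock hour spans
π/(day length) radians on the day side of an anchor and π/(night length)
on the night side.

### Kernel density and Δ₁

Activity densities are von Mises kernel estimates on a 128-point equally
spaced grid. The kernel concentration follows the plug-in rule of the
circular-KDE literature: with κ̂ the maximum-likelihood von Mises
concentration of the sample (capped at 3 to stabilise small or multimodal
samples),

    ν = (3 n κ̂² I₂(2κ̂) / (4 √π I₁(κ̂)²))^(2/5),

and the concentration used is ν / adjust. The default adjust = 0.8 is
the small-sample recommendation for the Δ₁ estimator; it is exposed
everywhere. Overlap between two fitted densities is the trapezoidal
circular integral of their pointwise minimum, which is symmetric,
rotation-equivariant, exactly 1 for identical samples, and consistent
for the true min-integral as n grows (checked against numeric
integration of the generating densities at n = 10,000 within 0.02).

### Bootstrap intervals

Confidence intervals use a smoothed bootstrap: each species is resampled
from its own fitted kernel density (a data point plus von Mises kernel
noise), both densities are refitted, and Δ̂₁ recomputed; default 10,000
replicates, seeded. The interval is the percentile range **shifted down
by the bootstrap bias** (mean of the replicates minus the point
estimate). The shift matters: Δ̂₁ is biased at field sample sizes and the
smoothed bootstrap reproduces that bias a second time, so the raw
percentile interval sits systematically high — in our coverage
simulations it covered the true overlap in only ~77% of nominal-95%
intervals, versus ~90% after the shift. This is the correction the
estimator's source literature recommends; `bias_correct=False` restores
the raw percentile interval.

### Classification

A density is classified by its probability mass in three sun-time
windows: crepuscular (the ±1 h bands around both anchors), diurnal
(between the bands), nocturnal (the rest). The windows partition the
circle, so the three proportions sum to one and are interpretable as the
probability of observing the animal in each period; the label is the
largest mass. Note that heavy smoothing pushes every estimate toward the
windows' angular fractions (the uniform limit), whose largest share is
the diurnal window — weakly nocturnal species with diffuse activity can
therefore be mislabelled at small n.

## Ingestion conventions

- Species vocabulary is closed: jaguar, puma, deer, peccary, calf.
- The focal month per year is the calendar month with the most records
  of the dominant species; ties resolve to the earliest month.
- Daily collapse: one detection per species per station-day, days
  outside a station's active calendar masked for both species jointly
  (one shared survey process).
- Independence filter: greedy forward scan per station and species,
  keeping a photo iff ≥ 1 h (configurable) after the last kept photo.
  Station-level rather than survey-wide, since distinct stations sample
  distinct animals; idempotent by construction.
- Prey covariates: distinct days with ≥ 1 prey photo divided by the
  station's surveyed days in the focal month, always in [0, 1].
- Files are UTF-8 CSV with ISO-8601 datetimes; detection histories are
  written wide (`dA_1..dA_J`, `dB_1..dB_J`, "." for missing, covariates
  alongside).

## The synthetic generator

`SimDesign` defaults mirror the target survey scale: 100 stations, one
30-day month in each of four years, occupancy truth (ψ^A = 0.28,
ψ^BA = 1.0, ψ^Ba = 0.28), daily detection 0.03–0.04, prey daily presence
as Bernoulli with Beta-distributed station rates (deer common, peccary
scarce, calves intermediate), interval-shaped missingness (late
deployment), and von Mises mixture activity truths whose integrated
pairwise overlaps and day/night masses reproduce the qualitative
structure reported for arid-land jaguar/puma systems: both predators
nocturnal, prey diurnal, predator–predator overlap ≈ 0.6, jaguar–peccary
lowest, puma–calf highest among puma–prey pairs. At this detection level
parameter recovery is intentionally weak (the realistic regime);
`SimDesign.recovery()` raises detection to 0.3 at 500 sites in one year
for estimator-performance simulations. Every dataset carries its truth:
latent states, realised daily detections, generating parameters, exact
φ, and numerically integrated pairwise Δ.

What the generator does **not** emulate: animal movement and home-range
overlap between stations (sites are independent given the state),
serial correlation in daily detections, seasonal drift in activity
within a month, moon-phase effects, and camera-model differences.
Passing recovery tests therefore demonstrate correctness of the
estimators under the model's own assumptions, not robustness to their
violation in field data.

## Problem sizes used in the checks

Simulation-based checks run at sizes chosen to make their Monte-Carlo
noise small relative to the asserted tolerances: likelihood equivalence
on 1,000 random tiny instances (≤ 3 sites × 4 occasions, tolerance
1e-10); parameter recovery over 100 replicate surveys at 500 × 30
(median absolute error < 0.05; SIF within 3 delta-method SEs in ≥ 90%);
overlap consistency at n = 1,000 per species over 50 seeds (mean error
≤ 0.05); bootstrap coverage over 200 pairs at n = 100 with 500
replicates (≥ 85%); classification of the generating labels over 50
seeded draws of 120 events per species (100%).

## Known limitations

- Single-season only; no multi-season/robust design, no Bayesian
  fitting, and exactly two focal species.
- Wald/delta-method uncertainty throughout; profile intervals are not
  implemented, and SEs at boundary estimates are flagged unreliable
  rather than replaced.
- The AICc effective-sample-size convention (site-year units) makes
  absolute AICc values software-specific.
- The plug-in bandwidth assumes a roughly unimodal sample; strongly
  antipodal bimodal activity (dawn + dusk peaks) yields a near-zero mean
  resultant, hence oversmoothing.
- The 1-h independence filter is a convention, not a model of animal
  behaviour; residual autocorrelation inflates effective sample sizes in
  the bootstrap.
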