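# Methods

This note documents the models, rules and numerical choices implemented in
`pelagia`, what the synthetic-data generator does and does not emulate, and
the known limitations.

## Immersion processing and the bout-ending criterion

A logger samples the instantaneous wet/dry state every `sampling_interval`
∈ {32, 90, 100} s. State changes shorter than 90 s are absorbed into the
preceding interval (the leading run into the following one) and same-state
neighbours coalesced, repeating until every interval lasts ≥ 90 s; series
recorded at different resolutions then reflect comparable behavioural
changes. Absorption rather than deletion preserves total recorded time,
which the daily accounting identity relies on. The merge direction
(backwards) is a convention; its effect is bounded by the 90-s scale.

Pooled wet+dry interval durations are modelled as a two-process exponential
mixture, f(t) = p λ_f e^(−λ_f t) + (1−p) λ_s e^(−λ_s t), fitted by maximum
likelihood on (logit p, log λ_f, log λ_s) with L-BFGS-B, multi-start
initialization from duration percentiles (25/75, 10/90, 25/90, 50/90) and a
1e-8 log-likelihood tolerance. Pooling both states reflects the breakpoint's
role — separating rapid transitions from prolonged single-state behaviour —
and a state-specific fit is available via
`BoutIntervalModel.from_intervals(..., state=...)` for sensitivity analysis.
The bout-ending criterion (BEC) is the closed-form intersection of the
weighted component densities. A fit is flagged non-converged when the
optimizer fails, the rates are not separated (λ_f/λ_s ≤ 1.01), the mixing
proportion is degenerate, or the intersection does not lie between the two
component means; classification refuses non-converged models. Exponential
components are an assumption of the BEC method itself, not an inference;
heavier-tailed interval distributions would bias the criterion.

Bout taxonomy: dry interval ≥ BEC → sustained flight; wet interval ≥ BEC →
floating; maximal run of sub-BEC intervals → one active-foraging bout
(transitions = members − 1). An isolated single sub-BEC interval still forms
a forage bout and is flagged `isolated` so its treatment can be audited.
BECs are fitted per bird by default (individual variation in these species
is large); a pooled fit is one call on concatenated intervals.

Daily budgets assign bouts wholly inside a calendar day to that day; a bout
spanning local midnight is excluded from *both* adjacent days, its in-day
minutes reported as `excluded_min`. Proportions use the fixed 1440-min
denominator, so on fully recorded days flight + float + forage proportions +
excluded/1440 = 1 exactly. Whether the original convention excluded at the
interval or bout level is ambiguous; exclusion is done here at the bout
level and the excluded time is always reported. Consequence worth knowing:
long floating bouts frequently span midnight, so counts of >80%/>90%-float
days under this convention run lower than under conventions that split
bouts at midnight — the zero-flight-day counts are insensitive to this, the
float-threshold counts are not.

## State-space track correction

Daily light-level positions carry degree-scale error. The latent daily
position z_t follows a first-difference correlated random walk,
d_t = z_t − z_{t−1}, d_t ~ N(γ d_{t−1}, σ_p² I), with persistence γ ∈ (0,1)
(uniform prior, logit-scale Metropolis), process SD σ_p (half-normal prior,
SD 5°, log-scale Metropolis) and a diffuse N(0, 10²) first step, in a
locally Euclidean lon/lat approximation with longitudes folded to [0, 360)
(the study region straddles the antimeridian). Observations are independent
Gaussian with both coordinates' SD fixed at 3.8°, the largest published
longitude error from double-tagging; published latitude errors assume
SST-matched estimates that are not generally available, so latitudes are
treated as no better than the worst longitude. Days without a fix (equinox
window, gaps) contribute no observation term but keep their latent state.

Sampling: given (γ, σ_p) the path's full conditional is Gaussian with a
pentadiagonal precision; it is drawn exactly each iteration via banded
Cholesky. With a land mask the exact draw would ignore the constraint, so
positions instead update singly on a 3-coloring of days (a site's process
terms reach ±2 days only), each conditional draw accepted iff it lands off
land — a valid Metropolis–Hastings step because the proposal is the
unconstrained full conditional — with an occasional whole-path proposal
accepted only when entirely off land. Desk-scale defaults are 2 chains ×
10,000, burn-in 5,000, thinning 5 (2,000 retained draws);
`SSMConfig.full_settings()` gives the full 2 × 100,000 / 80,000 / 20
configuration, whose retained count (2,000) is an exact identity of the
configuration. Convergence is summarized by Gelman–Rubin R-hat for γ, σ_p
and a mid-track state, with 1.1 as the default threshold ("near 1" needs an
operational cut-off). Posterior means define the corrected track; note that
posterior-mean positions *understate* day-to-day travel during random-walk
residency (smoothing averages unresolved movement), which is visible in
overwinter daily-distance summaries.

The equinox filter removes fixes within the closed ±15-day window around
the September equinox, computed from Meeus' polynomial series (minutes-level
accuracy, far beyond the daily resolution needed).

## Phenology rules

Departure is the first day beyond 720 km from the colony — an extreme but
feasible single-day foraging range — such that none of the next W = 5 days
falls back inside and the W-day Spearman trend of colony distance is
non-decreasing; return mirrors it. The published account rests on visual
inspection; W = 5 is the explicit stand-in for "without return" /
"clear pattern" and is configurable. Overwinter onset is first located as
the first run of ≥ 3 consecutive days at ≤ 100 km/day, then refined within
±6 days by the breakpoint of a continuous two-segment linear fit to the
colony-distance series: state-space smoothing rounds the sharp
transit/residency corner and biases pure threshold rules several days late,
while the breakpoint of the distance ramp-to-plateau is unbiased when the
smoothing is symmetric. The inbound onset is found and refined the same way
walking back from return. The three phases partition [departure, return];
days since departure (DSD) is 0 on the departure day. Failure modes raise
typed errors: no day beyond 720 km (`NoMigrationError`), no slow run or
inverted phases (`PhaseDelineationError`).

## Space use

Great-circle distances use the haversine on a 6371-km sphere. The
utilization distribution projects fixes with a Lambert cylindrical
equal-area projection (standard parallel 0°, central meridian at the data's
folded-longitude midpoint) and accumulates 2-D Gaussian kernels on a grid of
squares whose area equals a 0.25° × 0.25° cell at the equator (≈ 27.8 km
side). Effort normalization weights each point by 1 / (number of distinct
birds with a fix in its cell) *before* smoothing, keeping the surface a
proper probability distribution while preventing a single prolific bird from
dominating shared cells; smoothing-then-dividing is available as a
sensitivity variant (`normalize_order="after-smoothing"`). Bandwidths follow
the Abramson square-root law: a reference bandwidth h₀ = (geometric mean of
the coordinate SDs) × n_eff^(−1/5) — deliberately tighter than the 2-D
reference rate to limit mass-spreading bias on the discrete grid — then
h_i = h₀ (f̃(x_i)/g)^(−1/2) from a pilot density, clipped to [h₀/4, 8h₀].
The exact adaptive estimator used historically for such data is not public;
Abramson's is the documented stand-in. Contours at level q are the smallest
set of cells (by descending density, ties broken by cell index) whose
cumulative density reaches q; nesting across levels holds by construction
and is asserted. On a bivariate normal sample (n = 2,000) the estimated
mass inside the true 1-σ ellipse lands within a few percent of
1 − e^(−1/2) ≈ 0.393.

## Day-to-day activity trend models

Bird-day panels carry the proportion of each day in flight / floating /
foraging, DSD, phase, species, and daily distance. Floating and foraging
are modelled directly; sustained flight, being zero-inflated, is a
two-stage hurdle — a binary model for any flight and a quasi-binomial model
for the positive proportions — with the stages specified and selected
independently (their joint weighting is not identified by the data used
here).

Each stage is a penalized-spline GAMM fitted by penalized quasi-likelihood:
logit link; quasi-binomial variance φ μ(1−μ) (φ fixed at 1 for the binary
stage); cubic B-spline smooth of DSD with basis dimension k = 10 and a
second-difference penalty; an optional by-species deviation smooth
re-expressed in the penalty's positive eigenspace, so it carries only
nonlinear shape differences and parametric species effects cannot leak into
it; phase, species and phase×species factors; a per-bird random intercept
σ_b² and exponential temporal correlation exp(−Δdsd / range) entering the
working-model covariance V_b = σ_b² J + φ W^(−1/2) C_b W^(−1/2), whitened
per bird each iteration. Smoothing parameters are selected per smooth term
by Gaussian REML on the whitened working model (REML resists the
undersmoothing into group-labelled noise that GCV showed in calibration);
σ_b² and the correlation range are method-of-moments updates from working
residuals. Wald-type F statistics use the Bayesian covariance (X'V⁻¹X +
S)⁻¹ with the term's effective degrees of freedom (floored at 1: a term
shrunk to edf ≈ 0 carries no evidence); the species main effect, a
between-bird contrast, is tested against bird-level replication
(denominator df = n_birds − 2). Backward selection drops the least
significant droppable term at α = 0.05, respecting marginality (mains stay
while their interaction remains), until all retained terms are significant;
the trace is recorded and terms are never re-added. The random intercept
and the correlation structure are never candidates for deletion. The
selection's family-wise null retention sits near the α = 0.05 budget across
the two to three species terms, so the expected species-null elimination
rate is ≈ 90%, not higher — exact calibration, not conservatism, is the
design goal.

The quasi-flightless summary counts, inside a DSD window (default 30–70),
each bird's days with no sustained flight, days entirely floating (floating
fills all non-excluded time), days floating > 80% and > 90% of the day
(strict thresholds on the 1440-min denominator), and mean daily distance,
with species-level mean ± SD.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the pipeline assumes,
with defaults at the study's scales: a Midway-like colony (177.23°W,
28.12°N); departure dates N(29 June, 16 d); ~10-day outbound and ~9-day
inbound transits at 300 km/day (lognormal daily jitter, σ = 0.15) along a
per-bird northwest-sector bearing; a 125-day overwinter isotropic random
walk with 60 km/day mean displacement; Gaussian daily observation noise
(3.8° longitude, 1.9° latitude, optionally inflated inside the equinox
window); immersion series concatenated from exponential bouts (flight 90
min dry, float 250 min wet, forage episodes of 75 min alternating ~5-min
wet/dry intervals — Table-scale values for these species) whose type is
drawn with probability ∝ daily target proportion / mean bout duration so
realized time shares track the targets; and a default day-to-day trend with
the flight minimum at DSD 50 and floating peaking in the 30–70 window.
Ground truth retained: phase boundaries, the 720-km crossing dates computed
on the noiseless track (the recovery target for detectors facing noise),
per-sample activity labels, and per-day targets.

The faster `simulate_activity_panel` draws bird-day panels directly: logit-
scale bird intercepts (SD 0.35) and AR(1) day noise (ρ = 0.5) drive a
Poisson flight-bout mechanism, so hurdle zeros arise naturally. Because the
bird intercept multiplies a *time-varying* trend, each bird carries its own
smooth deviation — deliberately harsher than the random-intercept-only
model assumes. Selection-calibration replicates therefore use the
constant-proportion configuration, which is compatible with the fitted
model; recovery replicates use the trended one.

Not emulated: raw light curves and twilight estimation; ocean drift and
habitat preference; conspecific-interaction look-alikes within immersion
series; observation-error autocorrelation (weather persistence); logger
failure. Passing recovery tests therefore demonstrates correctness of the
estimators under the assumed error structure, not robustness to every field
artefact.

## Problem sizes and numerical defaults

Recovery experiments run at 20 birds × ~165 days (tracks), 10,000 intervals
× 20 seeds (BEC), 2,000 points (UD mass), and 12 birds × 145 days × 20
replicates (trend selection); desk-scale MCMC (2 × 10,000 / 5,000 / 5) is
the default everywhere, the full-length configuration being one
constructor call away. Tolerances: mixture fit 1e-8 on log-likelihood; PQL
outer loop stops at max |Δη| < 1e-4 (≤ 12 iterations); REML grids span
λ ∈ 10^[−2, 5] (12 points per smooth term); correlation range clipped to
ρ₁ ∈ (0.02, 0.95); a 1e-8 ridge stabilizes rank-deficient designs.
Deterministic seeding throughout: every stochastic routine takes a seed or
derives independent streams from (seed, bird, purpose).

## Known limitations

PQL inference for binary responses is approximate (attenuation at small
cluster sizes); the correlation range is a moment estimate, not REML; the
process model is Euclidean in degrees, adequate at mid-latitudes but not
near the poles; the land mask slows mixing where tracks hug coastlines;
UD contours are cell unions, not smoothed isopleths; the piecewise-linear
corner refinement assumes one dominant corner within its window and can be
misled by multi-stage departures.
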