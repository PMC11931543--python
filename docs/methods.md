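# Methods

`swntpore` analyses single-ion electrokinetic transport through a long,
narrow carbon-nanotube nanopore operated as a Coulter counter: each ion
occupying the pore blocks part of the ionic current, so a recording is a
two-state signal — an open-pore baseline and a blocked level lower by the
pore-blocking current (PBC).  The package covers the full chain from
synthetic trace generation through event idealization, dwell-time
kinetics, and mobility estimation, plus the closed-form device
calculators.  This note records the models, the defaults and why they were
chosen, and what the synthetic-data tests do and do not establish.

## Transport model

An ion entering a pore of length `L` under bias `V` drifts through in

    t_drift = L^2 / (mu0 * V),

where `mu0` is its intrinsic electrophoretic mobility.  During transit it
adsorbs to the pore wall as a first-order process with rate constant
`k_ads` (s^-1) and desorbs with `k_des` (s^-1).  The generative dwell-time
model is a compound Poisson of exponentials:

    t = t_drift + sum_{i=1..N} tau_i,
    N ~ Poisson(k_ads * t_drift),   tau_i ~ Exponential(k_des).

This is the minimal model consistent with the two experimentally anchored
facts about dwell times in such pores: the mean

    <t> = t_drift * (1 + k_ads / k_des)                       (mean law)

and an exponentially decreasing long-dwell tail whose time constant is set
by desorption, `k_des = 1/tau_tail` (tail law — but see the bias caveat
below).  Inserting `v = mu0 V / L` into the mean law gives the effective
(observed) mobility under adsorption:

    mu_eff = mu0 / (1 + k_ads / k_des),

constant in pH exactly when the ratio `k_ads/k_des` is.

Dimensionless load `lambda = k_ads * t_drift` (mean number of wall visits
per transit) controls the distribution's shape: at `lambda << 1` most
transits are direct (a sharp peak at `t_drift`, sparse exponential tail);
at `lambda >~ 2` the direct peak carries little mass and the distribution
becomes a broad bulk.

## Synthetic traces (stated world)

Defaults mirror the experimental recording conditions of the device this
package models: 250 kHz sampling, Gaussian noise of 2 pA (the
post-filtering instrument noise floor), a 1.01 nm diameter x 1.1 mm long
pore, a threshold voltage below which no blockades occur, and blockade
depth linear in voltage (only monotonicity is established experimentally;
linear-through-origin is the simplest conforming choice).  Event arrivals
are homogeneous Poisson; the entry rate is experimentally unreported, so
the default (5 s^-1) is set to give tens of events in a 10 s recording —
the order observed in published traces.  Placements that would overlap, or
come closer than 100 sample periods to a neighbour or a trace edge, are
re-drawn (up to 100 attempts, then dropped): the analysis chain smooths
with a 99-point boxcar, so events closer than the smoothing window are not
"isolated events" and are outside the regime the model describes.  Events
are snapped to sample boundaries (quantization <= 1 sample period).  The
2 kHz Bessel hardware filter is not re-simulated; the noise level is
specified at the post-filter stage.  One root seed feeds separate
sub-streams for arrivals, dwells, and noise, so traces are reproducible
component-wise.

What a green synthetic test establishes: the estimators recover the
parameters of *this* generative model at the stated noise and sampling.
Real recordings additionally contain baseline drift, 1/f and interference
noise, sub-state structure, and instrument-filter correlations, none of
which are emulated; detection performance there is expected to be worse.

## Idealization

- **Boxcar filter** (default 99 points): centered moving average; at the
  edges the window shrinks to the available samples, preserving length and
  affine equivariance.
- **Levels**: all-points histogram (Freedman–Diaconis bins by default,
  with a span/50 fallback when the IQR collapses), counts lightly smoothed
  over 3 bins, modes = peaks with prominence >= 5% of the maximum and >= 4
  bins of separation.  The open level is the dominant high-current mode,
  the closed level the tallest mode below it; both are refined to sub-bin
  precision by parabolic interpolation.  More than two comparable modes
  raises a multi-state warning — on these devices that pattern is the
  signature of leak transport through the elastomer seal rather than the
  nanotube.  A unimodal histogram is an error (no blocked state).
- **Events**: maximal runs below the open/closed midpoint lasting >= 3
  samples and dipping below midpoint minus one noise-sd (hysteresis
  against shallow excursions).  Noise is the scaled median absolute
  deviation of open-state samples.  Runs touching the trace boundaries are
  censored and discarded.  When the raw (unfiltered) trace is supplied,
  boundaries are refined against raw midpoint crossings — at depth/noise
  >= 5 a raw sample sits on the wrong side of the midpoint with negligible
  probability, so this removes the filter-ramp jitter entirely — and the
  baseline is re-centred on the mean of out-of-event open-state samples
  (insensitive to event density, since events are excised; the histogram
  mode alone is quantized at the bin scale).  PBC = baseline minus the
  in-event mean.
- **QC**: a condition needs >= 50 events for inclusion; two-state purity
  is the fraction of raw samples within 4 noise-sd of either level
  (threshold 0.99).

## Dwell-time kinetics

- `t_drift` defaults to the mode of the dwell distribution, estimated by
  the Robertson–Cryer half-sample mode: it is exact on the direct-transit
  point mass produced by the generative model and consistent for smooth
  peaks, whereas a global-bandwidth KDE mode is dragged toward the
  adsorption tail.  An independently measured mobility can supply
  `t_drift` instead (avoiding circularity with mobility estimation).
- The tail fit is the shifted-exponential MLE: `tau = mean(t - u | t >
  u)`.  The initial tail start `u` is mode + 2x the IQR of the sub-peak
  mass, then deepened by fixed-point iteration `u = mode + 4*tau` while at
  least 20 tail events remain.  The factor 4 was chosen from an exact
  bias/variance computation on the compound model (below); it is
  overridable.
- `k_des = 1/tau`; `k_ads = k_des * (<t>/t_drift - 1)` (mean-law
  inversion), clamped at zero with a warning if sampling noise drives it
  negative.  Uncertainties are seeded percentile bootstraps (1000
  resamples by default), run jointly over dwells so the `k_des` error
  propagates into `k_ads`.

**Bias caveat (important).**  For the compound-Poisson model the
log-survival of the adsorbed time `s` behaves as `-k_des*s +
2*sqrt(lambda*k_des*s)`, so the tail only attains slope `-k_des`
asymptotically.  The mean-excess estimator is therefore biased high in
`tau` (low in `k_des`) by a factor that grows with `lambda` and barely
decreases at tail depths that still contain data: exact computation gives
a relative bias of about +5% at `lambda = 0.1`, +16–25% at `lambda = 0.5`,
and +40% or more at `lambda = 2.5`, at any tail start retaining >= 10 of
5000 events.  The mean-law inversion transfers the same relative error to
`k_ads`.  No tail-start rule escapes this: it is a property of the
estimator family, and any analysis using "1/(tail time constant)" on such
data — including the published analyses this package models — carries it.
An unbiased alternative (not used, to keep the estimator the conventional
one) would exploit the direct-transit fraction: `lambda = -ln(#direct/n)`,
`k_des = lambda / mean(t - t_drift)`.

## Mobility

Inverse mean dwell is linear in voltage, `1/<t> = mu V / L^2`, so `mu` is
the OLS slope times `L^2` over >= 3 voltages (unweighted by default; a
1/SE^2-weighted option exists).  The intercept is retained as a diagnostic
rather than forcing the line through the origin — threshold effects can
offset it.  With blockades at a single voltage only, `mu = L^2/(V <t>)`
with a delta-method standard error.  The threshold voltage is the smallest
grid voltage with any events (grid-resolution limited by construction).
The mobility-vs-[H+] trend is summarized by a Langmuir-type form
`mu(c) = mu_low + dmu * c/(K + c)` fit by weighted least squares —
matching the surface-charge passivation picture in which adsorbed protons
neutralize wall charge until saturation; `c95 = 19 K` marks 95% of the
plateau, and a `dmu` confidence interval containing zero flags a
pH-independent ion.

## Closed-form calculators

- Ions resident in the pore: `c * N_A * pi (d/2)^2 L` (bulk concentration
  assumed inside; `c` in mol/L converted to mol/m^3).
- Surface-charge density: `n e / (pi d L)` — lateral area only.
- Raman radial breathing mode to diameter: `d = A/omega` with
  `A = 248 cm^-1 nm` (the relation for isolated tubes on SiO2), exposed as
  a parameter.
- Proton-collision velocity gain: `100 * sqrt(m_H/m_ion)` percent — both
  partners at thermal speed, complete momentum transfer.  This reproduces
  the conventional figures for sodium (21%) and choline (10%); for the
  acetylcholine cation it gives 8.3% where 7.1% is sometimes quoted, a
  discrepancy we surface rather than reconcile (the hydrochloride mass
  would give 7.4%; no documented convention yields 7.1%).

Internal computation is full precision; reporting rounds to 2–3
significant figures.

## Numerical and degenerate-input choices

- Zero-variance dwell samples (no adsorption): the split returns the mean
  as the peak and an empty tail; kinetic inference then fails loudly with
  an insufficient-tail error rather than fabricating rates.
- Degenerate (zero-variance) tails and bootstrap resamples raise/warn.
- Negative fitted `k_ads` is clamped to zero (physical bound) with a
  warning.
- Regression slopes are declared non-physical below a relative floor of
  1e-12 (exact-zero slopes land at float noise).
- All randomness flows from explicit integer seeds; sub-stream seeds are
  derived with `SeedSequence` so stages are independently reproducible.

## Known limitations

- The tail-estimator bias above: at `lambda >~ 0.5` the reported `k_des`
  (and hence `k_ads`) understates the truth by ~15–45%.
- No multi-exponential or full-likelihood dwell fitting; no sub-state or
  hidden-Markov idealization; no baseline-drift correction beyond the
  boxcar; no modelling of proton-adsorption dynamics behind the
  saturation trend.
- Threshold voltage resolution equals the voltage grid spacing.
- Instrument-format (e.g. ABF) import is an extension point, not
  implemented; the CSV/NPZ containers defined in `swntpore.io` are the
  supported interchange formats.
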