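# Methods

This note records the models, estimators, calibrations and numerical
choices behind `motortrace`, and what the passing tests do and do not
establish about real data.

## Generative model

One construct is described by a `MotorModel`; all units are fixed
package-wide (nm, s, µm for microtubule length, events·µm⁻¹·min⁻¹ for
landing rates).

**Landing.** Motors bind each microtubule as a homogeneous Poisson process
with intensity `landing_rate_total × L_i` per minute (L_i in µm); landing
times are uniform over the observation window and positions uniform along
the segment. Each event is independently *processive* with probability
`processive_fraction`, otherwise *static*. Thinning a Poisson process is
again Poisson, so the processive landing rate is exactly
`landing_rate_total × processive_fraction` — the identity the landing-rate
recovery tests exploit.

**Motion.** A processive motor draws one instantaneous speed from a
Gaussian mixture (`velocity_components`; non-positive draws are redrawn
during trajectory simulation) and keeps it for its whole run — velocity
heterogeneity is modelled at the motor level, matching how per-motor
velocity histograms are measured. It alternates moving and paused states as
a two-state continuous-time Markov chain (`pause_entry_rate`,
`pause_exit_rate`; both default 0, so estimator-recovery fixtures are
pause-free). Detachment is either *per-distance* — at a cumulative moving
distance drawn from Exp(`run_length_mean`) — or *per-time* — at
Exp(`residency_mean`) after landing. Run length and residency cannot both
be exactly exponential once they are coupled through a random speed, so
fixtures validating the run-length estimator use per-distance mode and
fixtures validating the residency estimator use per-time mode; each
estimator is then tested against exactly the distribution it assumes.
Static binders dwell Exp(`static_dwell_mean`, default 1 s) at a fixed
position.

**Photobleaching.** Each of `n_fluorophores` (1–8) bleaches independently
as Exp(`bleach_rate`). Adsorbed-spot traces can additionally mark each
fluorophore dark from the start with probability `pre_bleached_prob`,
which makes the counted-step distribution Binomial(n, 1−q) when traces are
long enough for every active fluorophore to bleach.

**Imaging.** Frames are rendered at `frame_interval` (default 0.12 s per
frame) and `pixel_size` 160 nm/px (typical EMCCD with a 100×/1.6× optical
train); both are configurable. Each motor with ≥1 unbleached fluorophore
contributes a pixel-integrated 2-D Gaussian (σ = `psf_sigma`, default
120 nm) of total flux `photons_per_fluorophore_per_frame ×` (unbleached
count); the window kernel is renormalized so photometry is exact away from
image edges. Pixel values are Poisson(signal + background) plus Gaussian
read noise, clipped at zero and quantized to 16 bits; `noise=False`
returns the noiseless float image for identity tests. Microtubules are
rigid straight segments; gliding assays are emulated as rigid 1-D
translocation. There is no stage drift, no 3-D/astigmatic PSF, and no
fluorophore blinking.

All sampling is bit-reproducible given (config, seed); per-motor child
streams are derived with `numpy.random.SeedSequence` spawning.

## Measurement layer

Kymographs resample the movie along a segment at one-pixel spacing
(bilinear), taking the maximum over a perpendicular 3-px band. Spots are
detected per frame above background median + 5×MAD (the MAD is floored at
0.1% of the dynamic range so noiseless images keep a meaningful threshold)
and refined to sub-pixel precision by an intensity-weighted centroid over
±2 px. Detections are linked frame-to-frame by greedy nearest-neighbour
assignment within 4 px, with gap closing of one missed frame.

Event definitions follow the field's kymograph conventions: run length is
the *net* start-to-end displacement (not path length); residency is last
minus first frame time; velocity is run length / residency, so pauses are
averaged in; `velocity × residency = run_length` holds identically. Events
under five frames are discarded. An event is *motile* when its net
displacement reaches 320 nm (two pixels — below the resolution of a manual
kymograph call) and ≥80% of its frame-to-frame displacements share the net
direction or are zero. Tracks reaching the last frame are flagged
right-censored but retained. All terminations are treated as detachment;
photobleach-loss is not disambiguated.

Because short runs fall below the 320-nm threshold, the measured motile
fraction of a mixed population is `processive_fraction × P(run ≥ 320 nm)`,
not `processive_fraction` itself; the classification tests assert the
former. No left-truncation correction is applied for the five-frame filter
(its effect is visible in the end-to-end example in the README rather than
corrected), and censored events enter the fits as-is.

## Estimators

**Velocity histograms.** Counts at 20 nm/s bins are fitted by bounded
least squares with a sum of one or two Gaussians. Two-component fits are
initialized from an exact 1-D 2-means split of the raw values (ties broken
toward larger separation) and reported with means ascending; variances are
free, not shared. The s.e.m. of each mean is taken from the fit
covariance; r² is computed on the histogram counts. Degenerate histograms
(single occupied bin, or fewer occupied bins than parameters) raise rather
than fit.

**Survival curves.** Run lengths and residencies are summarized by τ from
a least-squares fit of A·exp(−x/τ) to the empirical survival curve. The
curve is evaluated at the sorted sample with the Hazen plotting position
S_i = 1 − (i − 0.5)/n; the plain 1 − i/n convention pins the largest
observation at S = 0 and biases τ low by ~3% at n = 61, which the Hazen
convention reduces to ~1%. The amplitude A is free (initialized at 1)
because a finite minimum detectable run depresses the early survival curve
in real data. The default CI95 is the Wald interval from the fit
covariance — survival points are serially correlated, so this interval is
anti-conservative and is best read as a fit diagnostic; a seeded
percentile bootstrap of the whole refit (`n_boot ≥ 200`) gives an honest
interval and is what the analysis report uses. This estimator has ~7%
sampling s.d. at n = 289 and ~13% at n = 61 (the exponential MLE — the
sample mean — is the efficiency benchmark the oracle tests compare
against).

**Landing rates.** Per microtubule, rate_i = count_i / (L_i × minutes);
the result is the mean ± s.e.m. over microtubules, with zero-event
microtubules contributing zeros. `processive_only` counts motile events
only. Construct comparisons use Welch's unequal-variance t-test with
Welch–Satterthwaite degrees of freedom.

**Motile fraction.** Motile / total with a Wilson 95% interval.

**Photobleaching.** The ROI anchored at a picked pixel p spans rows/cols
[p−1, p+2] (the "4×4 centred" block, taking p as upper-left-of-centre; the
convention is stated because even-sized centred blocks are ambiguous) and
the background block spans [p−4, p+5] minus the ROI (84 px). The ROI is
not re-centred per frame (adsorbed motors are immobile). Aggregates are
traces whose initial intensity (mean of the first five corrected frames)
exceeds the population median + 5× plain MAD. Step counting is greedy
binary segmentation of the corrected trace: change points are added where
they most reduce within-segment squared error while the reduction exceeds
a Schwarz-type penalty 2σ̂²·log n (σ̂ from the scaled MAD of first
differences — zero for noiseless traces, where any true reduction is
accepted), capped at 8 change points. Downward level transitions of at
least `min_step` count as steps; by default `min_step` is half the median
detected drop, a scale-free unit-step estimate that is robust across laser
and gain settings but can suppress a unit step when most detected drops
are simultaneous multi-fluorophore drops — a rare pattern for 1–4
fluorophores. The greedy segmentation is validated in the test suite
against an exhaustive dynamic-programming optimum on ≤32-frame traces.

## Calibration of the packaged configurations

The packaged configs encode each construct's fitted motility parameters as
generative truth, so the pipeline should recover them at the published
sample sizes. Velocity spreads are derived from the published precision:
for single-Gaussian constructs the generative s.d. is s.e.m.×√n (483:
7.7×√346 ≈ 143.2; 483LZ: 3.6×√774 ≈ 100.2; 754: 2.4×√289 ≈ 40.8 nm/s).
For the full-length two-population mixture the published s.e.m. is per
component, so component s.d. = s.e.m.×√(weight×n) with slow/fast weights
0.75/0.25 (the slow majority is reported only qualitatively; the weights
are a modelling choice): slow 12.7, fast 42.1 nm/s at n = 61. The gliding
spread (25 nm/s) and the non-measured landing parameters of the 483/483LZ/
K560 configs are plausible placeholders, flagged in the config comments
and never used for recovery claims. 2mNeon dimers carry 4 fluorophores,
the full-length mNeon dimer 2.

## Problem sizes and statistical design of the checks

Recovery checks run at the published sample sizes (n = 61–774 events,
98–100 microtubules, 10-minute landing windows). Because several of those
sizes are small, single-seed estimates carry 7–20% sampling noise; the
acceptance script therefore reports medians over ensembles of replicate
seeds (25 for velocity fits, 200 for survival fits and the fold-change, 50
for landing rates and the mixture fit), which estimates what the estimator
recovers under the stated conditions rather than one draw's noise. The
test suite asserts both the ensemble median (within 2–3%) and the spread
(the per-seed error stays within 10–15% for the expected fraction of
seeds). The double-Gaussian fast-component mean is the noisiest quantity:
at n = 61 its fit s.d. is ≈31 nm/s, an irreducible property of fitting six
parameters to ~15 fast-population events.

## Known limitations

- The simulator's idealizations (rigid microtubules, constant per-motor
  speed, no blinking or drift, Poisson+Gaussian noise only) mean passing
  tests certify the estimators and the pipeline plumbing, not robustness
  to optical artefacts real recordings contain.
- Tracking is nearest-neighbour with 1-frame gap closing; it degrades when
  concurrent occupancy per microtubule approaches one motor per 4 px, and
  crossing tracks at similar speeds can swap identities.
- The survival fit's Wald CI underestimates; use the bootstrap CI for
  inference.
- Mixture-model order is user-chosen (1 vs 2 components), not selected by
  information criterion.
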