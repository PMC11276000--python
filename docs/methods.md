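# Methods

condkit quantifies the physical aging of multi-component biomolecular
condensates that host a clustering-prone RNA: how intra-condensate RNA
clusters grow, how the surrounding medium stiffens from a viscoelastic fluid
to an arrested solid, how component mobility drops, and where in
cofactor/temperature space condensation becomes irreversible.  Every
analysis stage is paired with a synthetic generator carrying ground truth,
so the package validates itself by parameter recovery rather than by
comparison with undeposited raw data.

## Tracer-bead models and trajectory simulation

Bead motion in a condensate is modelled per material class:

* **Newtonian liquid** — free 2D diffusion with per-axis increment variance
  `2 D dt`, `D = kB T / (6 π η R)` (Stokes–Einstein).  Defaults: `T = 298 K`
  (room-temperature experiments), `R = 0.1 µm` (200 nm tracer beads), so
  `η = 35.2 Pa·s` gives `D = 6.20e-5 µm²/s`.
* **Kelvin–Voigt solid** — a stationary mean-reverting (Ornstein–Uhlenbeck)
  process per axis with stationary SD `σ_c` (the corral size) and
  correlation time `τ_r`, discretized exactly
  (`x' = φ x + N(0, σ_c²(1−φ²))`, `φ = exp(−dt/τ_r)`).  The ensemble MSD
  plateaus at `4 σ_c²`.
* **Maxwell-type viscoelastic fluid** — the sum of an independent confined
  term and a free-diffusion term at the terminal viscosity (a Jeffreys-type
  construction).  Its MSD is `4 D τ + 4 σ_c² (1 − e^{−τ/τ_r})`: sub-linear
  through the crossover, linear at long lags.  This reproduces the observed
  MSD shapes without committing to a specific constitutive model.
* **Arrested** — static positions; only localization noise is recorded.

Localization noise (default 20 nm SD) is added i.i.d. per frame and adds a
constant `4 σ_loc²` ("static error") to every MSD lag.  Drift accumulates
per frame, common to all particles.

The acquisition interval is a free design parameter (it is not a property
of the medium).  The recovery studies use `dt = 2 s` over 300 frames per
bead: by a power argument, the fitted-window displacement `4 D τ_max` must
exceed the 1.6e-3 µm² static floor even at `η = 500 Pa·s`, which requires
lag windows of ~100 s.  The classification suite instead uses
`dt = 0.1 s` × 4000 frames so that both the sub-linear crossover
(τ_r = 0.3 s) and the terminal regime of the Maxwell medium fall inside
one profile.

## MSD estimation, drift correction, tracking

The per-trajectory time-averaged MSD over all start points is computed
either by direct differencing (short tracks) or an FFT identity (long
tracks); both give the same estimator and are cross-checked against a
brute-force double loop.  The ensemble profile is the unweighted mean of
per-trajectory time averages (a pair-count-weighted mode is available).
Lags run to 25% of the track length to bound estimator variance.

Drift is removed by subtracting the cumulative per-frame ensemble-median
displacement; with a single particle this removes all motion and warns.
Localization uses intensity-weighted centroids around local maxima (merging
duplicates within half the expected diameter); linking solves a per-frame
assignment problem (Hungarian algorithm on squared displacement, gated at
`max_disp`) with gap closing over a configurable memory.

## Rheological classification and terminal viscosity

The log-log slope α of the MSD is the diagnostic: α ≈ 1 everywhere →
Newtonian; sub-linear short-lag slope with a diffusive long-lag regime →
viscoelastic (Maxwell-type) fluid; α ≈ 0 at long lags with a plateau above
the static floor → Kelvin–Voigt solid; MSD everywhere at the floor →
arrested.  Default windows are the first and last decade of lags; default
thresholds 0.8 (fluid) and 0.2 (solid) — chosen here, since the study being
emulated classifies by inspection.

Because the static floor flattens log-log slopes (dominating entirely at
high viscosity), classification subtracts a floor calibrated from arrested
control beads when one is configured; the arrested test itself
(`everywhere ≤ 1.5 × floor`) uses the uncorrected profile.  Terminal
viscosity is `kB T / (6 π R D)` with `D` from an ordinary least-squares
slope of MSD vs lag over the terminal window (slope is invariant to any
constant offset); it is only reported when the window's log-log slope lies
in [0.8, 1.2], otherwise a `TerminalRegimeError` points to classification.

## Spatial autocorrelation (SAC) cluster sizing

The mask-restricted, mean-subtracted autocovariance is computed by FFT and
normalized at every lag by the mask's own autocorrelation (the number of
contributing pixel pairs), which removes the edge bias of finite
condensates; the map is normalized to 1 at zero lag and radially averaged
over one-pixel annuli (each bin carries its exact pair-weighted mean
radius).  The estimator is verified against an O(N²) direct summation.

Cluster size convention: the lag at which the radial correlation decays to
1/e of its structural amplitude, interpolated linearly between bins; for an
isolated Gaussian cluster of width σ (autocorrelation `exp(−r²/4σ²)`) this
is 2σ.  Two refinements make the convention noise-robust:

* White detector noise contributes only to the zero-lag spike, so the
  correlation remaining at one pixel measures the fraction of variance in
  genuine structure.  If that fraction is ≤ 0.05 the image is structure-free
  and the size is reported at the one-pixel floor (`at_floor`).
* Otherwise the 1/e reference is the structural amplitude extrapolated to
  zero lag by a Gaussian-form fit (log-correlation linear in lag²) over the
  leading bins with correlation ≥ 0.3 of the one-pixel value.  For
  well-resolved, low-noise structure the reference is ≈ 1 and the plain
  zero-lag convention is recovered.

Sizes ≤ 1.5 pixels are flagged `at_floor`: the image cannot resolve
structure below its pixel scale, which is exactly the behaviour of
cluster-free condensates.  Absolute sizes therefore depend on this
convention; only floor behaviour and relative trends are comparable across
conventions.

Line-profile pairs are normalized per channel by offsetting to zero minimum
and dividing by the maximum; Pearson r of the normalized profiles measures
co-localization (negative r = demixing).  The cluster RNA fraction
thresholds within-condensate pixels at `median + 3 σ_MAD` (robust statistics
so clusters do not inflate their own threshold) and ratios
baseline-subtracted cluster intensity to background-subtracted condensate
intensity.

## FRAP

Double normalization is the default: background subtraction, division by a
prebleach-normalized reference channel (cancels acquisition photobleaching),
and scaling to a prebleach mean of 1; a single normalization fallback is
flagged.  Recovery is fitted to `I(t) = I0 + A (1 − e^{−t/τ})` with guesses
taken from the curve; `mobile = A / (1 − I0)`, `t½ = τ ln 2`.  When the
window is shorter than 3τ the asymptotic amplitude is unconstrained (it is
degenerate on flat traces), so the fit is flagged `short_span` and the
mobile fraction falls back to the recovery actually observed at window end.
Diffusion-model FRAP (spot-size dependence) is out of scope.

## Temperature ramps and the state diagram

A cloud point (LCPT) is the temperature of the first sustained crossing of
`baseline + 5 sd` on the heating leg: traces are lightly smoothed
(3-sample window), crossings must persist for 3 samples (isolated 5σ noise
excursions are rejected), the threshold has a floor at 25% of the dynamic
range (on noiseless traces the bare rule triggers in the numerical tail of
the transition), and the crossing temperature is interpolated between the
bracketing samples.  Ramps span 2–80 °C in 0.5 °C steps by default.

Reversibility compares the end-of-cooling signal to the heating baseline:
irreversible iff it stays elevated by more than `tol` (exactly `tol` counts
as reversible).  Conditions with clusters present at the lowest temperature
are annotated `pre_percolated` rather than inferred.  The state diagram
over a Mg²⁺ grid places the percolation boundary midway between the highest
non-percolated and lowest percolated condition and reports the reversible
window; non-monotone classification sequences are flagged, not rejected.

Droplet-fusion force traces are fitted to `F∞ + ΔF e^{−t/τ}`; the reported
relaxation time is normalized by the arithmetic-mean droplet diameter
(ms/µm).  Fits with τ above a third of the trace span are flagged
unconverged with no normalized value.

## Synthetic scenarios and what passing does not show

The image generator renders a uniform condensate disk plus Gaussian
clusters that grow (size and amplitude) under a saturating-exponential
aging law, convolves with a Gaussian PSF, and adds Poisson (default) or
Gaussian noise; anti-correlated scaffold channels are depleted where
clusters are bright, emulating a core–shell architecture.  The pipeline's
`wt` scenario couples growing clusters to a stiffening medium
(35 → 90 → 250 Pa·s Maxwell, then Kelvin–Voigt, then arrested) and a
falling RNA mobile fraction; `mut` holds everything constant at ~21.5 Pa·s
with no clusters.

The generators emulate idealized versions of the real observables: isolated
Gaussian clusters (not fractal aggregates), single condensates per frame,
white noise, single-exponential recoveries/relaxations, sharp sigmoidal
cloud points.  Passing the recovery suite shows the estimators are
unbiased and correctly implemented under these conditions; it does not
validate them against irregular cluster morphologies, anisotropic media,
multi-exponential kinetics, or the undeposited raw data of any particular
experiment, and exact numerical agreement with published cluster sizes is
not claimed (the size convention is declared, not inferred).

## Numerical choices

Floats are written to CSV at 17 significant digits and parsed with
round-trip precision, so file round-trips are exact.  All randomness flows
through `numpy.random.default_rng(seed)`; identical seeds give
bit-identical outputs.  Recovery studies at stochastic stages report
medians (viscosity, cluster size) or means over ~20 seeds (FRAP, fusion),
with study sizes chosen so each stage runs in seconds to a few minutes on
one CPU: 100 beads × 300 frames per viscosity level, 50 seeds per class ×
30 beads × 4000 frames for classification, 5 noise realizations per
cluster-size σ, 50 seeds per cloud-point temperature.
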