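# Methods

This note documents the models fitted by each analysis stage, the defaults
chosen where the underlying experimental protocol leaves a choice open, what
the synthetic-data generators do and do not emulate, and the numerical
decisions that affect results.

## FRET arithmetic (`photophysics`)

All stages share the *apparent* FRET efficiency

    E = I_A / (I_A + I_D)

computed from background-corrected donor (DiI) and acceptor (DiD)
intensities.  No gamma-factor, spectral-leakage or direct-excitation
correction is applied anywhere in the package — the quantity of interest is
a relative compaction readout, not an absolute distance, and the
uncorrected ratio is what the single-vesicle histograms are built from.  A
correction hook is exposed (`fret_efficiency(..., correction=...)`) and
defaults to the identity.

Efficiency and mean dye separation interconvert through the Förster
relation `E = R0^6 / (R0^6 + R^6)` with `R0 = 5.3 nm` for DiI–DiD.  The
inversion `R = R0 ((1-E)/E)^(1/6)` is exact; round-trip identity holds to
1e-12 relative over E in (0.01, 0.99).  E = 0.40 maps to 5.67 nm (5.7 to
one decimal); E = 0.60 maps to 4.95 nm.  Note that quoting peak positions
rounded to two decimals and converting *the rounded value* can differ in
the first decimal from converting the unrounded fit mean (0.615 → 4.90 nm
vs 0.60 → 4.95 nm); the package always converts the unrounded fitted mean.

## Ensemble spectra (`ensemble_spectra`)

A titration series is one emission spectrum per crowder concentration
(532 nm excitation).  Band intensities are trapezoidal integrals on the
native wavelength grid — no resampling — of the baseline-subtracted
spectrum, clipped at zero.

Open choices and their defaults:

- **Integration bands**: donor 545–610 nm, acceptor 650–750 nm.  These
  cover the DiI and DiD emission bands and respect the 640 nm long-pass
  dichroic used for imaging.  Both are parameters of every entry point.
- **Baseline**: either a measured blank spectrum, a constant, or (default)
  the median intensity over 750–780 nm, a region where neither dye emits
  appreciably.  Subtracting a spectrum from itself produces a flagged row
  (zero band signal), never a NaN that could poison the trend fit.
- **Trend fit**: the concentration dependence of E (or R) is summarised by
  an ordinary least-squares quadratic — a heuristic smoother for a
  monotone saturating titration, not a binding model.  It refuses fewer
  than 3 points.

## Lifetime fitting (`tcspc`)

The decay histogram is modelled as a multi-exponential
`I(t) = sum_i a_i exp(-t/tau_i)` convolved with the measured IRF plus a
constant offset.  At an 80 MHz repetition rate the window is 12.5 ns, so a
2–4 ns component does not complete between pulses; the model therefore
wraps the exponential over the repetition period (each component becomes
`exp(-t/tau) / (1 - exp(-T/tau))`) and the convolution is circular.
Wrap-around is always on.

Numerical design:

- **Objective**: weighted least squares with Neyman weights
  `1/max(counts, 1)` per bin — the standard weighting for TCSPC data at
  ~1e4 peak counts, stable in low-count tails.  Poisson MLE fitting is out
  of scope.
- **Variable projection**: the optimiser searches only over
  log-lifetimes and the IRF timing shift; amplitudes and offset are
  solved at each iterate by non-negative least squares.  This halves the
  nonlinear dimension, guarantees nonnegative amplitudes/offset, and makes
  each fit fast enough to bootstrap densely.
- **Sub-bin IRF shift**: circular linear interpolation, bounded to
  ±5 bins.  The discrete model has an inherent half-bin lag alignment
  relative to the continuous convolution; the shift parameter absorbs it.
- **Fit window**: from the point where the rising edge crosses 1% of the
  peak to the end of the window (configurable).  Bins before the rise are
  dominated by background and the previous-pulse tail.
- **Initialisation**: a crude intensity-weighted lifetime from the
  post-peak tail, spread geometrically across components.
- **Degenerate models**: lifetimes closer than 5% relative are merged
  (amplitudes summed) and the fit re-run with one fewer component;
  likewise a component whose amplitude collapses to numerically zero is
  dropped.  The reported fit is always the reduced model, with lifetimes
  sorted ascending.  Component count is otherwise user-specified (1–4);
  there is no automatic model selection.

The summary statistic is the amplitude-weighted lifetime
`tau_av = sum(a_i tau_i) / sum(a_i)`, which always lies between the
extreme component lifetimes.

**Bootstrap intervals.**  Uncertainty is assessed by a parametric
bootstrap: every bin is Poisson-resampled around the fitted model and
refitted (warm-started from the original fit).  The default 95% interval
is the symmetric bootstrap standard-error interval
(estimate ± 1.96·sd of replicates).  Raw 2.5/97.5 percentile intervals are
available (`interval="percentile"`) but are slightly anti-conservative
here: the replicate distribution of the lifetimes is mildly left-skewed
while the least-squares estimator carries a small negative bias, and in
repeated simulations at the default acquisition conditions percentile
intervals covered the truth ~85% of the time versus ~90–93% for the
symmetric interval.  More than 20% replicate fit failures raises an
instability error rather than returning a misleading interval.

## Dynamic light scattering (`dls`)

Correlograms are fitted to the single-exponential model

    G(tau) = A [1 + B exp(-2 D q^2 tau)],    q = 4 pi n / lambda0 * sin(theta/2)

with positivity constraints (B capped at 1.2).  No cumulant expansion or
regularised inversion is attempted: the model is monodisperse by design
and distribution width comes from repeated measurements.  Internally the
fit uses a dimensionless decay rate (rate × median lag) so that all three
parameters share a common scale; D in m²/s differs from A by ~12 orders of
magnitude and would otherwise stall the optimiser.  Initialisation: A from
the tail mean, B from the intercept, D from a log-linear fit of the early
decay.  A flat curve raises a degenerate-fit error.

`d_H = k_B T / (3 pi eta D)` converts to a hydrodynamic diameter.
Instrument defaults are a 633 nm backscatter correlator (theta = 178°,
n = 1.33); the environment defaults to water at 25 °C (T = 298.15 K,
eta = 8.9e-4 Pa·s).  All four are configuration fields on the correlogram,
since the acquisition protocol does not pin them down.

`size_distribution_stats` summarises externally measured diameter tables
(electron-microscopy sizing): a fixed-width histogram (default 25 nm bins)
plus a log-normal maximum-likelihood fit, reporting the fitted density
mode and FWHM (found by root-finding on the fitted density).  A degenerate
all-equal sample returns that value with zero FWHM.

## Single-vesicle imaging (`single_vesicle_imaging`)

The movie is a dual-view stack: donor and acceptor half-images side by
side.  Pipeline decisions:

- **Registration** is translation-only, estimated by sub-pixel phase
  cross-correlation of the time-averaged channels, and the acceptor stack
  is resampled onto the donor grid by linear interpolation.  A dual-view
  splitter at camera scale is well approximated by a translation; affine
  registration is left as an extension.  Featureless channels raise a
  registration error carrying the identity transform.
- **Detection** runs on the sum of both registered time-averaged channels
  so that high-FRET vesicles (dim in the donor channel) and low-FRET
  vesicles (dim in the acceptor channel) are found equally.  The image is
  band-passed with a difference of Gaussians at the PSF scale, local
  maxima above median + k·MAD (k = 5) are kept with a minimum-separation
  constraint, and centroids are refined to sub-pixel precision.
- **Traces**: per frame and channel, integrated counts in a 3 px circular
  aperture minus the median of a 5–7 px annulus times the aperture area.
  Spots whose annulus leaves the image are dropped and recorded.
- **Per-vesicle efficiency**: one E per vesicle from the trace means over
  a configurable frame range (default: all frames; no photobleaching
  truncation, since vesicles carry many fluorophores and the illumination
  regime is deliberately weak).
- **Histograms** use fixed 0.01-wide bins on [0, 1].  A single Gaussian is
  fitted to the binned counts (initialised at the argmax bin); the fitted
  mean converts to the mean dye separation ⟨d⟩.  The fit is withheld if
  fewer than 10 vesicles are available or the relative fit error exceeds
  a threshold (default 0.6).
- **Condition comparison**: with fitted before/after/wash histograms and a
  peak-shift threshold (default 0.03), the verdict is *irreversible* if
  the peak moved and stayed moved after washing, *reversible* if it moved
  and returned, *no effect* otherwise.  The mean total intensity per
  vesicle (I_D + I_A) is compared across conditions; a >20% change flags
  possible vesicle loss or disruption, since a pure conformational change
  conserves total emission.

## Synthetic data (`synthetic_data`)

The generators produce every input modality with serialised ground truth;
identical seeds give bit-identical outputs.

- **Spectra**: skew-normal donor/acceptor line shapes (peaks near 565 and
  670 nm, red tails) with band areas in ratio (1−E):E, a constant
  baseline, and optional Gaussian noise.  The shapes are templates chosen
  to be essentially fully contained in the default integration bands;
  dye-to-dye spectral crosstalk is deliberately not modelled.
- **Decays**: Gaussian IRF (default FWHM 0.2 ns, centred at 1.5 ns in a
  12.5 ns window of 250 bins), wrapped-convolution model scaled so the
  noiseless maximum equals the acquisition stopping criterion of 1e4
  counts, constant background of 2 counts/bin, independent Poisson draw
  per bin.  Default components 0.6/0.5 ns + 0.4/2.0 ns.
- **Correlograms**: 100 log-spaced lags spanning 0.01–10 decay times,
  exact single-exponential model (A = 1, B = 0.9) plus additive Gaussian
  noise.
- **Movies**: vesicle count Poisson with mean density × area (default
  195 per 25 × 50 µm field, 0.11 µm pixels), uniform positions with
  minimum-separation rejection, log-normal per-vesicle brightness
  (median 1500 photons/frame, sigma 0.4 — chosen so intensity histograms
  are visibly log-normal), split (1−E):E between channels, Gaussian PSF
  (sigma 1 px), a fixed true inter-channel shift (default (1.3, −0.6) px),
  per-pixel Poisson shot noise and a camera model (offset 100, read noise
  sd 2, unity gain — appropriate for low-power TIRF imaging).  The
  efficiency spec is either a constant or a per-vesicle normal
  distribution; population dispersion is a free parameter rather than a
  mechanistic dye-copy-number model.  Geometry and brightness come from a
  random stream independent of the efficiency spec, so the same seed
  reproduces the same vesicle field at any E — per-vesicle total
  brightness is independent of E by construction, which is what makes the
  total-intensity intactness check meaningful.

Not emulated: photobleaching, blinking, within-trace FRET dynamics,
vesicle diffusion (tethered vesicles are immobile), detector
nonlinearity, and spectral crosstalk.  Passing tests therefore demonstrate
correctness of the estimators under the stated statistical model, not
robustness to these additional real-data effects.

## Problem sizes used in the test suite and acceptance script

Recovery statistics are computed at sizes chosen to make the Monte-Carlo
medians stable while keeping a full run inexpensive: 50 decay seeds with
100 bootstrap replicates each in the test suite (20 seeds / 80 replicates
in the acceptance script); 20 correlogram seeds per vesicle size (10 in
the script); two 3-movie imaging scenarios at 500 frames and ~195 vesicles
each; 1e4 diameter samples for the size-distribution round trip.

## Known limitations

- Translation-only channel registration; no drift correction over frames.
- Single-Gaussian histogram fits cannot represent bimodal vesicle
  populations; the fit-quality threshold withholds ⟨d⟩ in that case.
- The DLS stage is strictly monodisperse; polydispersity appears only as
  residual misfit.
- Bootstrap intervals quantify photon-counting uncertainty around the
  fitted model, not model misspecification (e.g. a true lifetime
  distribution rather than two discrete components).
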