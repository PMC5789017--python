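# Methods

## Imaging and noise model

A camera pixel records `ADU = gain * Poisson(mu) + offset + read noise`,
where `mu` is the expected photo-electron count (emitter signal plus
background) and the read noise is Gaussian with per-pixel variance
`readvar * gain^2` in ADU (so `readvar` is expressed in e-²).  Correction
inverts gain and offset, `d = (ADU - offset) / gain`, leaving the standard
sCMOS statistics: a corrected pixel has mean `mu` and variance
`mu + readvar`.  Corrected frames are kept as floats and never clipped at
zero — read noise legitimately undershoots the offset, and clipping would
bias the maximum-likelihood fits.

In a multi-camera configuration the emission is split across P planes with
fixed transmission fractions t_p summing to 1 (0.5/0.5 biplane, 0.25 per
camera quadplane, dichroic fractions for spectral imaging), and each camera
is focused at its own axial offset.  Default offsets follow the plane
spacings of the instrument classes the package targets: 600 nm (biplane),
500 nm (quadplane), 100 nm (spectral).

## PSF models

Two PSF families share one contract — `evaluate(x, y, z, window)` returns the
expected *fraction* of the emitter's photons in each pixel of a window:

* **Pixel-integrated Gaussian** with an optional defocus curve
  `sigma(z) = sigma0 * sqrt(1 + (z/d)^2)`.  Defaults: `sigma0 = 130 nm`,
  pixel `a = 108 nm`.  The defocus depth `d = 300 nm` acts as an effective
  Rayleigh range of the detection PSF; for a high-NA oil objective the
  measured spot width roughly doubles within 500–600 nm of defocus, which
  this value reproduces (`sigma(520 nm) ≈ 2 sigma0`).  A Gaussian that merely
  widens with defocus remains more informative at large defocus than a real
  aberrated PSF; consequences are noted under *Limitations*.
* **Tri-cubic B-spline PSF** built from an averaged bead z-stack, one lateral
  knot per pixel and one axial knot per scan step (50 nm default).  The
  B-spline prefilter makes the spline interpolate every stack sample exactly;
  evaluation and the x/y/z derivatives are analytic in the coefficients
  (finite differences interact badly with knot boundaries, and the Fisher
  bounds and fitter both require smooth derivatives).  Negative spline
  ringing is clamped to 1e-9 of the peak at evaluation so fitted means stay
  positive.  Stacks are normalized so the sharpest slice sums to 1.

Per-plane splines are stored in *defocus* coordinates relative to each
camera's own focal plane.  `calibrate_spline_psfs` handles the bookkeeping
for a stage scan: frames at the same stage z are averaged, beads closer than
24 px to a neighbour or not visible on every camera are discarded, each bead
patch is background-subtracted (median of the window's border ring),
sub-pixel aligned by a Gaussian MLE fit of its sharpest slice and a cubic
interpolation shift, averaged, and splined with
`z_min = first stage position - focal offset`.

## Detection

The significance map correlates the corrected frame with a zero-mean Gaussian
matched filter (template sigma 1.2 px by default) and divides by the
propagated noise scale `sqrt(corr(max(local mean, 0) + readvar, template^2))`,
giving a map calibrated in standard deviations (its standard deviation on
background-only frames is 1 by construction).  Candidates are local maxima
above the threshold — 8 sigma for biplane, 6 sigma for quadplane data —
with closer maxima than `min_separation = 3 px` suppressed in favour of the
more significant one (ties to the smaller row, then column).  Raising the
threshold can only remove candidates, never add them, because a suppressing
maximum is always at least as significant as the one it suppresses.

## Maximum-likelihood fitting

Each corrected pixel is modelled as `(d + readvar) ~ Poisson(mu + readvar)`,
the standard variance-stabilized sCMOS likelihood; the objective is
`sum (d+v) ln(mu+v) - (mu+v)`.  Optimization is Fisher-scoring Newton with
Levenberg damping: steps that would lower the likelihood are rejected and the
damping increased, so the objective is non-decreasing across accepted steps.
Convergence requires the largest scaled parameter step to fall below 1e-4
(positions and widths scaled by 1 px, z by one pixel-size in nm, signals and
backgrounds relatively); the iteration cap is 100 and non-converged fits are
flagged `failed`, never dropped.

* **Single plane**: theta = (x, y, N, b, sigma), pixel-integrated Gaussian;
  initial values from the border-median background, background-subtracted
  centroid and window sum.  sigma is reported in nm.
* **Multiplane**: a joint fit over all planes with shared position.  In the
  default `shared` mode theta = (x, y, z, N, b_1..b_P) with the plane split
  fixed at the geometry's transmissions; in `per_plane` mode each plane's
  signal is free (theta = (x, y, z, N_1..N_P, b_1..b_P)), which is what
  spectral data need since the split itself encodes the dye.  Candidate
  seeds are pooled across planes (detections mapped to the reference frame
  through each camera's affine transform, merged within 3 px), z is
  initialized by normalized correlation against the spline's axial slices,
  and positions are optimized in the reference frame with the affine linear
  part entering the chain rule.  A fit whose z ends pinned against the
  calibrated spline range is flagged `failed` with no silent clamping.

## Cramer-Rao bounds

`mortensen_crb` evaluates the closed-form 2D MLE bound
`var(x) = (sigma_a^2/N) / F`, `F = -∫_0^1 t ln t/(t+tau) dt`,
`tau = 2 pi sigma_a^2 b / (N a^2)`, `sigma_a^2 = sigma^2 + a^2/12`, by
adaptive quadrature at relative tolerance 1e-8; at b = 0 it reduces to
`sigma_a/sqrt(N)` exactly.  `fisher_crb` builds the Fisher matrix
`I_ij = sum_planes sum_pixels (dmu/dtheta_i)(dmu/dtheta_j)/(mu + readvar)`
over a finite window (15 px default; at sigma/a ≈ 1.2 the outside
contribution is negligible) and reports `sqrt(diag(I^-1))`.  For purely 2D
models the z row is dropped and sigma_z reported as NaN; a z-capable model
with vanishing axial derivative raises an error naming the null direction.
The EMCCD excess-noise equivalence halves both N and b, since background
photons traverse the same gain register as signal photons.

The quadplane-vs-biplane photon cost is computed by root-finding the
multiplier m with `CRB_quad(m N) = CRB_biplane(N)` in the lateral bound at
the mid-plane z.  With the Gaussian-defocus model this gives ≈1.6 rather
than the ≈2 expected when only the two nearest planes contribute: the
defocused Gaussian decays too gracefully, so the two far planes (750 nm
defocus) still carry ~10–15% of the lateral information.  The value is
insensitive to the defocus depth (1.58–1.62 over d = 250–400 nm); it is a
property of the PSF family, not a tuning choice.

## Spectral classification

Per-localization channel signals (from `per_plane` multiplane fits) are
normalized to unit-sum 4-vectors; all-zero or negative-channel vectors are
flagged rejected rather than raised, since dim localizations produce them
routinely.  Two classifiers: (i) the first moment `sum_i i v_i` with cuts at
midpoints between per-dye training medians; (ii) seeded k-means (k-means++
init, clusters ordered by first moment for reproducibility) with
nearest-mean assignment and *global* fractional rejection — the worst
`floor(f n)` assignments by distance to their mean are discarded (f = 0.20
default), ties keeping the lower index.  Cross-talk is the row-normalized
confusion matrix over non-rejected localizations.

## Synthetic data

The generator emulates exactly the model above: Poisson photon statistics on
`t_p N PSF_p + b`, per-pixel gain/offset, Gaussian read noise added in ADU,
rounding to non-negative integers.  Bead z-scans step a stage grid with
constant bead brightness; spectral draws multinomially thin one Poisson
photon budget through the dye's channel fractions (the physically consistent
model of one emission stream through sequential dichroics).  Blinking is
caller-supplied on-frame sets — no photoswitching kinetics; no aberration
model beyond defocus (the 0.79 first-order spherical-aberration rescale is
applied downstream, as in practice); dye signatures are user-supplied and
not claimed to match any real dye.  Passing tests therefore demonstrate
correctness of the estimators under the stated noise model, not robustness
to aberrated PSFs, sample drift during calibration, or real dye photophysics.

## Postprocessing

Bead tracks seed from frame-0 localizations (seeds never updated, matching
the fixed-seed rule), capture radius 2 px, nearer localization wins a
contested frame with the frame flagged ambiguous.  Tracks missing more than
10% of frames — strictly more, so 10/100 passes and 11/100 fails — are
discarded, on both cameras when paired.  Precision statistics use the
unbiased (n−1) standard deviation and require ≥10 frames.  Drift correction
renders 1000-frame segments into 20 nm histograms (defaults chosen for
100 Hz-class acquisitions: long enough for correlation SNR, short enough to
track thermal drift), cross-correlates against the first segment with
quadratic sub-bin peak interpolation, interpolates offsets linearly between
segment centres, and subtracts; sparse segments (<100 localizations) are
interpolated from neighbours with a warning.  Lateral-only and 3D modes are
both provided.  `rescale_z` multiplies z by 0.79.

## Problem sizes in the validation suite

The quantitative end-to-end checks use 5000 single-plane fits (N = 1000,
b = 10) against the Mortensen bound and 700 full-pipeline biplane fits
(600 nm offset, N = 3640, b = 30/plane, 32x32 px frames) against the Fisher
bound — sizes at which the sampling error of a standard-deviation estimate
(~1/sqrt(2n)) is 1–3%, comfortably inside the 10%/15% acceptance bands.

## Known limitations

No multi-emitter fitting: overlapping-window fits are flagged, not
deconvolved.  No GPU path.  The Gaussian-defocus generator understates how
fast real PSFs lose information with defocus (see the photon-cost section).
Drift correction assumes a structured, temporally stationary sample;
featureless or sparse segments degrade it gracefully but visibly.
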