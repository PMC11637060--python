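# Methods

`echosos` is a simulation-driven toolkit for pixel-wise speed-of-sound (SoS)
estimation from plane-wave ultrasound RF data and for SoS-aware time-reversal
reconstruction of photoacoustic (PA) images. This note documents the models,
the numerical choices, and what the synthetic experiments do and do not show.

## Physical model

Linear acoustics in 2-D with heterogeneous sound speed c(x) and mass density
rho0(x), written as the first-order system

    du/dt   = -(1/rho0) grad p
    drho/dt = -rho0 div u
    p       = c^2 (rho + absorption terms)

This pair is exactly equivalent to the variable-density wave equation
d2p/dt2 = c^2 rho0 div((1/rho0) grad p), so sub-resolution density
perturbations scatter the field and produce speckle, while the SoS field
controls travel times and refraction — the separation the SoS-regression
problem relies on.

### Solver

k-space pseudospectral time domain (PSTD): spectral spatial derivatives on
half-cell staggered grids with the exact k-space temporal correction
sinc(c_ref |k| dt / 2), split-field quartic PML on all four sides
(10 points, absorption strength 2 c_ref/dx), and fractional-Laplacian
power-law absorption.

Numerical choices that matter:

* **Time step.** dt is locked to integer submultiples of the 20 MHz RF clock
  (dt = 50 ns / k) with k chosen so the CFL number is <= 0.3 against the
  maximum SoS. Decimation to the 128 x 1024 RF frame is then exact.
* **Absorption/dispersion.** The power-law exponent is y = 1.01 (the
  fractional-Laplacian operator is well posed away from y = 1). With the raw
  zero-frequency reference, the Kramers-Kronig dispersion companion of a
  near-1 exponent shifts the in-band phase velocity by several percent
  (tan(pi y / 2) ~ -64 at y = 1.01). The dispersion operator is therefore
  re-referenced to the transmit band center, k_ref = 2 pi f_c / c_ref, making
  the stated SoS the phase velocity at f_c; travel-time oracles then hold to
  a fraction of an RF sample. Absorption magnitude (0.5 dB/(MHz cm),
  soft-tissue average) is unaffected.
* **Initial-pressure release.** p0 is smoothed with a frequency-domain
  Blackman window (suppresses spectral ringing), rho is initialized to
  p0/(2c^2) per split component, and the first velocity half-step uses dt/2
  to pair the release with the staggered velocity grid.
* **Time reversal** enforces the recorded (reversed) pressures as Dirichlet
  values on the sensor line each step and reads the final interior field.
  Reversal runs lossless: re-amplifying through an absorbing medium is
  ill-posed and the desk-scale media are only weakly attenuating.

### Probe and grids

A 128-element linear array (0.3 mm pitch, 38.4 mm aperture, 7 MHz center
frequency) occupies one grid edge just outside the PML. The full-scale
grids — 1536^2 at 0.025 mm for pulse-echo simulation (11 grid points per
element + 1 kerf) and 788 x 768 at 0.05 mm for PA reconstruction (5 points
per element + 1 kerf, RF resampled 128 x 1024 -> 640 x 4096) — are
supported directly. Tests and the acceptance script run reduced grids
(128^2 - 384^2 over the same 38.4 mm extent) with the transmit frequency
scaled to keep >= 3 grid points per minimum wavelength (e.g. 1.46 MHz at
0.3 mm); every per-element quantity scales with the pitch-to-dx ratio.
These problem sizes keep a complete validation pass within CPU minutes while
exercising the identical code paths.

## Digital phantoms

Training phantoms: homogeneous background with SoS ~ U[1400, 1600] m/s and
1-5 elliptical inclusions, each 1-7 % faster than the background and
hyperechoic. Geometry is uniform: long semi-axis up to 38.4 mm, short up to
19.2 mm, any orientation. Later-listed structures overwrite earlier ones on
overlap (a deterministic rule is required; this is the simplest).

Echogenicity: hyperechoic contrast raises the SoS by 7-11 % of the
background at ~10 % (Bernoulli 0.1) of the grid points inside the inclusion.
Speckle: scatterers at 3 per wavelength^2 perturb the mass density
fractionally with amplitudes ~ U[-0.03, 0.03]. Density, not SoS, carries the
speckle so the regression label stays the clean bulk-SoS field; this is the
standard separation in pulse-echo speckle simulation. Hypoechoic inclusions
(evaluation pattern 3) scale interior scatterer amplitudes by U[0.1, 0.5].

Evaluation patterns are drawn from geometry families absent from training:
(1) two layers split by a sine-deformed boundary (amplitude U[1, 4] mm,
1-2 periods), (2) straight isoechoic layers, (3) homogeneous background with
hypoechoic ellipses. SoS ranges reuse the training bounds. Layer SoS may be
below as well as above the background. The 40-per-pattern batch protocol is
supported by seeding.

Labels are 384 x 384 at 0.1 mm: exact 4 x 4 block means of the 1536^2
bulk-SoS rasterization (desk grids below 384 are replicated upward). All
randomness flows from one top-level seed through named substreams
(geometry / sos / echogenicity / scatterers / noise).

## RF conditioning

The acquisition chain mirrors the clinical system: time gain compensation of
0.5 dB/MHz/cm at 1540 m/s (two-way depth mapping c t / 2, at the 7 MHz
center frequency), anti-aliased decimation to 20 MHz / 1024 samples, system
noise (transmit-interference bursts confined to the first 50 samples; the
shipped bank is synthetic — band-limited Gaussian-windowed bursts — and real
banks are loadable), white thermal noise at a per-channel SNR drawn from
U[40, 80] dB (the noise floor 40-80 dB below the channel signal power; a
literal signal-to-noise of -80..-40 dB would make every frame pure noise),
zeroing of the first 50 samples (electrical crosstalk), and per-channel
standardization to mean 0 / std 1. Stage order is configurable and logged;
the default applies noise before blanking and normalization, as in
acquisition.

## The SoS regression network

A fully convolutional encoder-decoder maps one conditioned 128 x 1024 frame
to a 384 x 384 SoS map (0.1 mm pixels). Implemented in NumPy with explicit
backpropagation (offset-loop convolutions, batch normalization, LeakyReLU
0.1, 2x2 max pooling, nearest-neighbour upsampling, separable bilinear
resize); float32 throughout, Xavier initialization, seed-deterministic.

Encoder: six stages with anisotropic kernels whose time-axis width narrows
from 15 toward 3; the stated endpoints and the decrease-by-2 rule cannot
both hold over six layers, so the realized widths are 15, 13, 11, 9, 7, 3.
Strides contract the time axis faster than the channel axis
((2,4), (1,2), (2,2), then three unit-stride stages with 2x2 max pooling),
taking (128, 1024) to (8, 16). Decoder: six stages with kernels widening
3 -> 11; the first four are x2 upsampling + conv + BN, the fifth is conv +
bilinear resize to 384 x 384, the sixth a 3x3 conv + BN, then a final 1x1
conv. Encoder stages 4/3/2 are concatenated onto decoder stages 3/4/5 — the
unique shape-consistent reading of the stated skip wiring. The "strided"
decoder convolutions are realized as upsample + conv (same operator family
as transposed convolution, without checkerboard artifacts).

The network regresses on the normalized scale s = (SoS - 1500)/100 with a
zero-initialized output bias, so an untrained model predicts 1500 m/s
everywhere and reported RMSE is always in m/s. Reference training uses MSE
loss and SGD (mini-batch 10, lr 1e-4) with a 0.9 per-phantom train/valid
split and best-validation checkpointing. The trainer optionally applies a
step learning-rate schedule and Polyak (exponential moving average, decay
0.98) weight averaging; with momentum SGD on small validation sets the
averaged weights turn a noisy validation plateau into a monotone descent,
so the retained checkpoint comes from the settled late epochs. The desk
profile (thin channels 4-8, 200 phantoms on the 128^2 solver grid, lr 0.02
with momentum 0.9 on the normalized scale, 22 epochs annealed to 0.006 for
the last 6, EMA on) exercises the same code; the full-scale 6000-sample
configuration is supported but not run by the test suite, and its reported
convergence is not a claim of this package.

Transfer learning: a residual head (3x3 conv -> LeakyReLU -> zero-initialized
3x3 conv) is attached on the output map; the augmented model initially
reproduces the base exactly, the base is frozen (bit-identical after
fine-tuning), and the head trains with an epoch cap of 20 plus a
validation-plateau stop. The domain-shifted fixture emulates a different
probe response by convolving each channel with a short random FIR kernel and
adding excess noise — a synthetic stand-in for real acquisitions.

## Reconstruction and baselines

`parecon.reconstruct` composes the stated pipeline: blank the first 150 of
1024 samples, resample RF to the sensor grid (640 x 4096 at full scale),
bilinearly interpolate the 384^2 SoS map onto the reconstruction grid, and
run Dirichlet time reversal. Display normalization is max-abs to [0, 1];
negative lobes are kept until then. The SoS source (constant / autofocus /
dl / ground_truth) is recorded on the image.

Autofocus baseline: exhaustive sweep of a global SoS (default 5 m/s step),
scoring each reconstruction with normalized intensity power
sum(I^4)/(sum(I^2))^2 (Brenner gradient available); ties break toward
1540 m/s. The sweep table is kept as a diagnostic.

Metrics: RMSE in m/s over structure masks (scalar estimators broadcast);
single-window SSIM with region-level statistics (C1 = 1e-4, C2 = 9e-4 at
dynamic range L = 1) — a deliberate choice over the 11x11 sliding window,
since the evaluation is per-structure/ROI; lateral FWHM with linear
half-max interpolation; SNR = 20 log10(mu/sigma) with the 0.35 intensity
threshold separating signal from background. Point-source SSIM uses 2 mm
square ROIs centered on the known sources; an option mirrors the exclusion
of very deep low-SNR sources (off by default).

## What the synthetic studies show — and what they do not

The validation studies (see `echosos.studies` and `scripts/acceptance.py`)
establish: sub-sample travel-time accuracy of the solver; round-trip
refocusing through heterogeneous media; the ray-predicted displacement under
wrong-SoS reconstruction; autofocus recovery on homogeneous media and its
layered-medium failure mode; closed-form correctness of all metrics; that a
network trained end to end on 200 simulated acquisitions beats the
constant-1540 prior (~70.2 m/s RMSE against U[1400, 1600] backgrounds) and
recovers homogeneous backgrounds; and that true-SoS time reversal improves
point-source SSIM/FWHM over the constant assumption on layered media.

They do not show clinical performance: the generator has no out-of-plane
signal, no element-to-element response variation, no anatomical texture, and
the desk profile runs at reduced frequency and grid resolution, so absolute
RMSE numbers are not comparable to full-scale training campaigns or to real
probes. The transfer-learning study demonstrates the mechanics (frozen base,
improving head) on a synthetic shift, not sim-to-real closure.

## Known limitations

2-D only; no nonlinearity, shear waves, or element bandwidth beyond the tone
burst; evaluation-phantom SSIM against the correct-SoS reconstruction is
trivial for the ground-truth arm (the initial pressure is used as reference
for point-source phantoms instead); the NumPy network is CPU-bound and not
intended for the full 6000-sample campaign; autofocus uses image-domain
sharpness only (no channel-coherence variant).
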