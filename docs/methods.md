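# Methods

## The reconstruction problem

A light micrograph is a blurred, photon-noisy rendering of the underlying
object.  With a linear, shift-invariant optical system the acquisition is

    I = phi( h * y + b )

where `y` is the object, `h` the point-spread function (PSF), `b` a constant
background and `phi` Poisson sampling of the expected photon counts.  The
package restores `y` from `I` with a conditioned denoising diffusion model
whose training loss and sampler both carry a *physics-informed* term derived
from this forward model, so that reconstructions are pulled toward images
that actually explain the measurement instead of merely looking plausible.

## Optical forward model

The pupil function over the transverse frequency plane is
`Q(m) = A(m) exp(i phi(m))` with `A` a top-hat of radius `NA/lambda` and
`phi` an optional aberration phase (zero by default: an ideal system; a user
supplied phase field is accepted, but no Zernike parameterisation is
provided).  The coherent amplitude PSF is the inverse Fourier transform of
`Q`, propagated to defocus planes with the angular-spectrum factor
`exp(2*pi*i*kz*z)` where `kz = sqrt((n/lambda)^2 - |k_perp|^2)` lies on the
Ewald cap.  The incoherent widefield PSF is `h = |u_ex|^2 |u_em|^2`; with
equal wavelengths its focal-plane profile is the Airy intensity
`[2 J1(v)/v]^4`, which the tests verify against the analytic form (first
zero at `0.61 lambda / NA`).

The optical transfer function is computed as the autocorrelation of the
pupil via FFT and is validated against an O(N^4) double-loop autocorrelation
on small grids.

**Pinhole interpretation.**  A confocal pinhole of radius R is modelled as a
field stop: the binary disk `T = 1_{x^2+y^2 <= R^2}` multiplies the emission
amplitude in the image plane, plane by plane, before the modulus square
(`h = |T u_em|^2 |u_ex|^2`).  Equivalently, the disk's transform is convolved
with the emission pupil in k-space.  This choice makes the two physical
limits exact: a pinhole wider than the field of view reproduces the
widefield PSF identically, and a small pinhole (~0.25 Airy units) strictly
tightens the lateral FWHM, with the L2 distance to the widefield PSF
decreasing monotonically in R.  A disk *convolved with the amplitude in real
space* would invert both limits and was therefore rejected.

Conventions chosen where several are defensible: PSFs are normalised to unit
sum over the simulated volume (so the convolution operator preserves flux);
the centre pixel is `(nz//2, ny//2, nx//2)`; the pinhole mask uses hard
pixel-centre rasterisation with sub-pixel radii clamped to one pixel; for
2-D data the focal-plane slice of the PSF, renormalised, is the convolution
kernel.  Wavelengths are stored in nanometres and all other lengths in
micrometres.  The synthetic-microscope refractive index defaults to 1.33
(water immersion).

## Acquisition operator

`A` is periodic (circular) convolution with the unit-sum kernel, implemented
by FFT.  Periodic boundaries make `A` exactly linear, make the adjoint the
correlation with the same kernel, and preserve the image mean; the adjoint
identity `<Ay, x> = <y, A^T x>` is tested to 1e-8 on random pairs.
`acquire` draws `x = Poisson(s (A y + b)) / s` with photon scale `s`
(expected photons per unit intensity), giving a per-pixel Fano factor of 1
in photon units.  Camera read noise, EMCCD gain and spatially varying PSFs
are out of scope.  A periodic Richardson-Lucy deconvolver (flux-preserving
multiplicative updates) is included as the classical baseline.

Diffusion operates on intensities affinely mapped from [0, 1] to [-1, 1];
because the kernel is unit-sum and boundaries are periodic, `A` commutes
with this affine map, so guidance can act directly in diffusion units.

## Diffusion core

Forward noising uses the standard variance-preserving chain with a linear
beta schedule (default `1e-4..0.02` at T = 1000; the desk-scale smoke
configuration uses T = 100 with `1e-3..0.12`, chosen so that
`gamma_T ~ 2e-3`, i.e. y_T is essentially pure noise; a squared-cosine
schedule is also available).  The per-step sampling variance `sigma_t^2` is
`beta_t` by default, with the posterior variance `beta~_t` selectable.
The exact posterior `q(y_{t-1}|y_t, y_0)` is verified against brute-force
numerical Bayes on a one-pixel problem.  The denoiser predicts the injected
noise from `(y_t, x, gamma_t)`: the observation is channel-concatenated and
the *continuous* signal level `gamma_t` — not the integer step index — is
the time conditioning, embedded sinusoidally.  No noise is added at the
final step t = 1.

## Physics-informed guidance

The reverse transition mean is shifted by `sigma_t^2 g` with
`g ~= A^T(x - xi - A y_t)/xi^2` under the Gaussian surrogate
`n ~ N(xi, xi I)` of the Poisson noise.  During training on synthetic data
the noiseless measurement `x~ = A y_0` replaces `x - xi`, and `g` is
annealed to the norm `eta sqrt(gamma_t)` (default `eta = 10`; an ablation
sweep across `{1, 5, 10, 25, 50}` is exposed through the CLI).  Because the
annealing renormalises `g`, constant prefactors such as `1/xi^2` are
irrelevant whenever guidance is active, so `xi` only matters if a literal
unannealed gradient is requested.  The training target is
`eps + sigma_t^2 g` with the simplification constant C = 1; no learning
signal flows through `g` (it is evaluated, not differentiated), which is the
point of the construction — the alternative of evaluating the measurement
model at the posterior-mean estimate of y_0 would couple the guidance to the
network's own prediction and is deliberately not implemented.

An optional L1 or L2 regulariser with weight `lambda_t` (constant by
default, optionally scaled by `sqrt(gamma_t)`) joins the data term *inside*
the annealed gradient as a descent direction,
`raw = A^T(x~ - A y_t) - grad(lambda_t R(y_t))`; adding the regulariser
subgradient with a positive sign would ascend R, so the sign follows the
objective `||A y - x~||^2 + lambda R(y)` rather than the loosest reading of
the additive formulation.  Guidance is applied at every reverse step.

With `eta = 0` and no regulariser, the physics-informed loss and sampler are
bit-identical (same seeds) to the conditioned-DDPM baseline — the baseline
is the strict special case, which the tests check exactly.  At inference the
guidance target is the observed (noisy) image; the PSF must be supplied
(learning the forward operator implicitly is not attempted).

## Denoiser

An encoder-decoder with skip connections: per level two 3x3 convolutions
with instance normalisation (also in the decoder) and SiLU, average-pool
downsampling, bilinear upsampling in the decoder, and a per-block bias
projected from the gamma embedding (dimension 64).  Default 3 levels and 32
base channels, no attention — deliberately small so the whole pipeline
trains on one CPU core; the exact widths of the original architecture are
not public and no attempt is made to match them.  The network runs on a
compact in-package reverse-mode autodiff over numpy (conv2d via im2col,
Adam optimiser); its gradients are verified against central finite
differences, and the bilinear upsampler against its adjoint identity.

## Synthetic data

Random microscopes are sampled per instrument: NA uniform in (0.4, 1.0),
excitation wavelength in (320, 400) nm, emission in (450, 550) nm, pinhole
radius uniform in (0.1, 1000) um (radii beyond the field of view act as
widefield), refractive index fixed at 1.33, focal plane centred.  Phantoms
(bars, points, disks, filaments, a Shepp-Logan-like head) stand in for
natural-image and fluorescence corpora so nothing needs downloading; they
carry construction metadata (point coordinates, bar geometry, filament
count) for downstream scoring.  Photon budgets default to a
50 / 500 / 5000 expected-peak-photon grid spanning low- to high-light
conditions.  Train and test splits use disjoint phantom seeds *and*
independently drawn PSF banks.

What the phantoms do not emulate: natural-image statistics, textured
backgrounds, out-of-focus haze from 3-D structure, camera noise beyond the
Poisson term.  Passing the end-to-end tests therefore demonstrates that the
machinery (forward model, objective, guided sampler) works and that guidance
helps under these controlled conditions, not that the configured network
rivals full-scale training on real micrographs.

## Metrics

PSNR (`20 log10 MAX - 10 log10 MSE`, MAX defaulting to the ground-truth
peak; identical images report +inf), NRMSE (RMSE over the ground-truth
range) and MS-SSIM (five dyadic scales, equal per-scale exponents with the
canonical weights 0.0448/0.2856/0.3001/0.2363/0.1333, 11x11 Gaussian window
with sigma 1.5, K1 = 0.01, K2 = 0.03).  Images too small for five halvings
fall back to fewer scales with renormalised weights and a warning; metrics
are computed on [0, 1]-scaled intensities.  The per-scale SSIM is
cross-checked against scikit-image's single-scale implementation.

## Desk-scale study configuration

The end-to-end checks train the default 3-level/32-channel network on
200 synthetic pairs of 32x32 phantoms (photon budget 500), T = 100,
batch 4, Adam at 2e-3, ~2,000 training steps (the test suite trims this to
1,500), and restore held-out test observations with 8 guided samples each
(eta = 10), reporting the mean restoration, the pixel-wise
standard-deviation map (the model's uncertainty estimate) and PSNR against
the degraded inputs.  A single-pair overfit run (~400 steps) is used to
verify optimisation health.  These sizes are the package's smoke-test
defaults; serious use should scale all of them up.

At this scale the restoration quality is genuinely stochastic: the test
microscopes are drawn anew per seed, and a draw dominated by low-NA (heavily
blurring) PSFs poses a much harder inverse problem, so the PSNR gain over
the degraded inputs varies by several dB between seeds while individual
samples remain visibly noisy (pixel-wise spread ~0.3); the sample mean is
the usable estimate.  More training steps and more samples per restoration
tighten both, at proportional cost.

## Known limitations

- Scalar (non-vectorial, unpolarised) pupil treatment; no Gibson-Lanni
  immersion-mismatch aberrations; no STED/SIM PSF models.
- Periodic convolution wraps structure near the border; pad images whose
  content touches the edge.
- The numpy network trains orders of magnitude slower than a GPU
  implementation; the defaults are sized accordingly.
- MS-SSIM on 32x32 images uses fewer than five scales by necessity.
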