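# Methods

## The measurement problem

In spectral-domain OCT a reflector at optical depth *z* produces a spectral
fringe cos(2*kz*) across the detector (wavenumber *k* = 2π/λ). Fourier
transforming the spectrum over a uniform *k* grid yields an A-scan whose
peak positions are *optical* depths — geometric depth times the group
refractive index *n_G* of the tissue. A layer's geometric thickness is the
peak separation times the axial pixel pitch divided by *n_G*; we use
*n_G* = 1.387 for corneal tissue in the near infrared.

When the beam meets the corneal interfaces along their normal vector, the
specular interface reflections are by far the strongest image features and
refraction does not displace deeper signal, so segmentation reduces to
tracing three bright, nearly flat lines: air(–tear film)–epithelium,
epithelium–Bowman's, Bowman's–stroma. The epithelial thickness reported by
this pipeline runs from the anterior surface to the epithelium–Bowman's
boundary and therefore *includes the tear film*: the Fresnel reflection at
the air–tear interface is much stronger than the diffuse tear–epithelium
signal, so the anterior surface is the only reliably segmentable anterior
boundary. A tear-film-resolved mode is deliberately not offered.

## Synthetic captures

The simulator is the package's source of test data and defines the
conditions the pipeline is validated under.

**Phantom.** Per lateral column: anterior surface depth (quadratic sag,
default 5 µm centre-to-edge, plus a small random walk), epithelium
(default 50 µm geometric), Bowman's layer (default 16.6 µm), optional tear
film and contact lens. Interface roughness is a spatially correlated
zero-mean texture (Gaussian noise smoothed over ~2 columns, sample SD
rescaled exactly), so the column mean equals the nominal thickness and the
texture is trackable by a bounded-step path — uncorrelated per-column
noise would be indistinguishable from measurement noise. The default
Bowman's roughness of 1.0 µm makes measured profile SDs fall in the 1–2.5
µm band observed on real corneas. Stromal speckle is the coherent sum of
discrete scatterers (default 300 over the stack; amplitude ≲ 1/3 of the
weakest interface), keeping ground truth exact rather than statistical.

**Acquisition.** A capture is 50 frames over 0.125 s (frame period 2.5 ms,
integration 500 µs as metadata). The spectrum is sampled *uniformly in
wavelength* over 700–1000 nm — as a grating spectrograph does — so k-space
resampling downstream is a genuine operation. Per column and frame:

    I(λ) = E(λ)·[1 + Σᵢ 2√rᵢ cos(2 k zᵢ + φ(k))]

with *E* a Gaussian envelope in *k* (FWHM 0.6 of the spanned range), *rᵢ*
power reflectivities (surface 4·10⁻⁴, epithelium–Bowman's 10⁻⁴,
Bowman's–stroma 5·10⁻⁵), φ a residual dispersion phase modelled as a cubic
polynomial in (k − k₀) (zero by default; a quadratic coefficient of ~0.85
µm² gives a visibly broadened PSF for dispersion tests). The spectrum is
blurred along the detector by a Gaussian of FWHM 2.0 px (spectrograph
resolution), Poisson-sampled at 10⁴ photoelectrons at the envelope peak,
and a static spurious-fringe image (2% of reference, at 35% of the alias
depth) is added to every frame. Frame-to-frame axial motion is Gaussian
with SD 3.5 µm (~3 px); each frame washes out with probability 0.06 (the
median observed discard rate for trainee operators), modelled as fringe
contrast collapsing to 10⁻³ of nominal while the reference level remains.
Reflectors beyond the Nyquist depth π/(2·max Δk) raise an error rather
than alias silently.

**What the simulator does not emulate:** lateral eye motion, polarization,
confocal (lateral) PSF effects, camera read noise or fixed-conversion
non-linearity, multiple scattering, and real speckle statistics. Passing
tests therefore demonstrate correctness of the *algorithms* under the
stated noise model, not clinical performance.

## Reconstruction choices

- **k-resampling** by cubic spline (endpoints clamped); sideband artifacts
  stay below the phantom noise floor (verified against a dense-DFT oracle).
- **Spectral shaping**: the window is *compensating* — weights =
  (Gaussian target)/(measured envelope), zeroed where the envelope falls
  below 5% of peak. The target's bandwidth is set from the requested axial
  resolution via FWHM_k = 4·ln 2/FWHM_z, so the windowed spectrum — not
  the window itself — has the shape that yields the configured PSF. A
  plain Gaussian multiplier would narrow against the envelope and miss the
  target width by ~10%.
- **Dispersion correction** multiplies exp(−iφ̂) on the resampled grid; in
  tests φ̂ is built from the simulator's known polynomial, standing in for
  the glass-interface calibration of a real instrument. Without NDC the
  spectrum is real and the transform depth-symmetric; only the positive
  half is kept.
- **DC suppression** is by blank subtraction only; no extra high-pass.
- **dB convention**: images are amplitudes, so dB = 20·log₁₀(amplitude);
  the log is display-only and never enters averaging or segmentation.
- **Roll-off**: Monte-Carlo SNR of an ideal reflector (oversampled fringe,
  box-averaged per pixel, Gaussian-blurred, Poisson-sampled, FFT) against
  the closed-form amplitude MTF sinc(πf)·exp(−π²w²f²/(4 ln 2)) at fringe
  frequency f = z/(2·z_max) cycles/px. Depths are snapped to FFT bins: an
  off-bin fringe in an unwindowed transform measures spectral leakage, not
  roll-off.

## Frame averaging choices

- Stage order is fixed: fixed-pattern removal → washout rejection →
  reference selection → alignment → linear mean. The median image is taken
  *before* averaging because averaging would smear the static artifact
  into the mean.
- Washout defaults: threshold 10× the stack mean amplitude, minimum count
  1% of the correlation-ROI pixel count (nominally an 81-row full-width
  band). A median-based background level is degenerate here: after
  clamping the median-subtracted stack at zero, about half the background
  is exactly zero. Both thresholds are exposed in the API and CLI.
- Registration is integer-pixel by design (the axial pitch of ~1.17
  optical µm is ~half the PSF width; sub-pixel gains would be marginal).
  ROI columns are summed into one axial profile before the 1D normalised
  cross-correlation — summation maximises profile SNR. Lags are bounded by
  the ROI depth and additionally require ≥ max(8, len/4) px of overlap,
  since near-total lags correlate a handful of samples and produce
  spurious |r| ≈ 1.
- Shifted frames are zero-filled and excluded from the mean at invalid
  rows (per-pixel valid-count normalisation), so image edges are unbiased.

## Segmentation choices

- Energy: cost = 1 − min-max-normalised amplitude, after a 2×2 median and
  before a 2×2 top-hat. Both even-sized filters anchor their footprint at
  the top-left pixel with bottom/right edge replication — a fixed,
  documented convention. The 2×2 "median" is the *upper* median (third of
  four order statistics): a lone hot pixel still vanishes, but a
  one-pixel-wide bright interface line survives, which the lower median or
  the averaged median would erase or halve.
- The path search is free-endpoint dynamic programming, one node per
  column, |Δdepth| ≤ 2 px/column by default (corneal interfaces at normal
  incidence are nearly flat; the exhaustive oracle in the tests validates
  the DP for any bound). Equal-cost ties resolve to the lexicographically
  smallest depth sequence via backward-DP greedy reconstruction.
- Three sequential searches with a ±3 px exclusion band around each found
  path; results are sorted by mean depth and asserted strictly
  non-crossing. Manual correction is supported by passing a blocking mask
  and re-running — the interactive step itself is out of scope.
- Thickness bias: both 2×2 filters shift all three paths up-left by the
  same sub-pixel amount, which cancels in the path *differences*; on
  noise-free phantoms segmentation is exact to ±1 px, and on 20 noisy
  captures the mean Bowman's bias is below 0.1 µm.

## Statistics

Sample (n−1) standard deviations throughout. The 95% population range is
mean ± 2 SD under an assumed normal distribution. Repeatability is the SD
of per-capture mean thicknesses (single subject), or the mean over
subjects of within-subject SDs. The literature meta-summary averages
published means (a range-only study contributes its midpoint) and averages
per-study bounds (mean ± 2 SD, or the printed range); the packaged table's
"this work" row is excluded from the consensus by default, since the
consensus is the external reference the new measurement is compared
against. The paraxial refraction correction Z_r = n·Z_a (phase index
1.376 in the visible) converts apparent thicknesses from focus-ranged
confocal instruments, whose depth scale omits surface refraction, to true
geometric thickness; it is the exact inverse of the OCT group-index
division when n equals n_G.

## Problem sizes in the tests

The test and validation captures use 64 lateral columns and 768 spectral
pixels while keeping the full 50-frame capture structure; the axial pitch
(~1.165 optical µm/px) depends only on the spanned wavenumber range and is
unchanged from a full-width configuration, so segmentation and thickness
arithmetic operate at the realistic scale. The graph-search oracle
enumerates all monotone paths on instances up to 8×8; the roll-off
Monte-Carlo uses 50 noise draws per depth.

## Known limitations

- Washout detection is threshold-based; a frame with partial contrast loss
  passes QC and slightly dilutes the average.
- Integer registration leaves up to half a pixel of residual jitter in the
  average, broadening interfaces by a small, thickness-neutral amount.
- The simulator's coherent discrete scatterers underestimate the density
  of real stromal speckle; segmentation robustness to dense speckle is
  only partially exercised.
- Absolute sensitivity (dB) of a real instrument depends on optics the
  simulator does not model; only relative/ordering SNR statements are
  meaningful here.
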