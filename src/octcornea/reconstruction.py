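"""SD-OCT reconstruction: blank subtraction, k-resampling, spectral shaping,
numerical dispersion correction (NDC), FFT, and system characterisation.

The chain turns raw spectrograph frames into linear-amplitude B-scans.  The
axial axis of the result is *optical* depth (geometric depth times the group
index n_G); conversion to geometric µm happens in :mod:`octcornea.thickness`.
The image presented to a viewer is ``20·log10`` of the linear amplitude (dB);
all averaging and segmentation operate on the linear amplitude itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter1d

from .synthetic import RawCapture, unambiguous_depth_um

__all__ = [
    "SpectralCalibration",
    "ShapingWindow",
    "DispersionCorrection",
    "BScanStack",
    "subtract_blank",
    "resample_to_k",
    "design_window",
    "apply_window",
    "apply_ndc",
    "reconstruct",
    "reconstruct_capture",
    "to_db",
    "measure_psf_fwhm",
    "measure_snr",
    "ndc_degradation",
    "rolloff_curve",
    "RolloffResult",
]


# ---------------------------------------------------------------------------
# Calibration and resampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectralCalibration:
    """Wavelength-per-pixel calibration and the uniform-k resampling grid.

    ``k_per_pixel`` is 2π/λ in rad/µm (monotone decreasing for an ascending
    wavelength axis); ``resample_grid`` is a uniform ascending k grid
    spanning the measured range with the same number of points.
    """

    wavelength_nm: np.ndarray
    k_per_pixel: np.ndarray = field(init=False)
    resample_grid: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength_nm, dtype=float)
        d = np.diff(wl)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("calibration wavelengths must be strictly monotone")
        k = 2 * np.pi / (wl * 1e-3)  # rad/µm
        object.__setattr__(self, "k_per_pixel", k)
        grid = np.linspace(k.min(), k.max(), k.size)
        object.__setattr__(self, "resample_grid", grid)

    @property
    def dk(self) -> float:
        return float(self.resample_grid[1] - self.resample_grid[0])

    @property
    def axial_pitch_um(self) -> float:
        """Optical depth per reconstructed pixel (µm)."""
        return np.pi / (self.resample_grid.size * self.dk)


def subtract_blank(raw: RawCapture) -> np.ndarray:
    """Subtract the averaged reference-only (blank) image from every frame.

    Removes the reference spectrum DC term; the residual is fringes plus the
    fixed pattern plus noise, and may be negative.
    """
    frames = np.asarray(raw.frames, dtype=np.float64)
    if raw.blank.shape != frames.shape[-2:]:
        raise ValueError("blank shape does not match frame shape")
    return frames - raw.blank


def resample_to_k(stack: np.ndarray, calibration: SpectralCalibration) -> np.ndarray:
    """Cubic-spline interpolation of spectra onto the uniform-k grid.

    ``stack`` has the spectral axis last (any leading shape).  Endpoint
    values outside the measured k range are clamped to the edge values;
    since the grid spans exactly the measured range, only round-off can
    land outside.
    """
    stack = np.asarray(stack, dtype=np.float64)
    if stack.shape[-1] != calibration.k_per_pixel.size:
        raise ValueError("spectral axis length does not match calibration")
    k = calibration.k_per_pixel
    order = np.argsort(k)
    spline = CubicSpline(k[order], stack[..., order], axis=-1, extrapolate=False)
    grid = np.clip(calibration.resample_grid, k.min(), k.max())
    return spline(grid)


# ---------------------------------------------------------------------------
# Spectral shaping and dispersion correction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShapingWindow:
    """Digital spectral shaping window over the resampled pixels.

    ``weights`` multiply the resampled spectrum; ``target`` is the nominal
    spectral shape the weighted source envelope realises.  Max weight is
    normalised to 1.
    """

    weights: np.ndarray
    target: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(w)) or np.any(w < 0):
            raise ValueError("window weights must be finite and non-negative")
        m = w.max()
        if m > 0:
            object.__setattr__(self, "weights", w / m)
            object.__setattr__(self, "target", np.asarray(self.target, dtype=float))


def design_window(
    envelope_k: np.ndarray,
    calibration: SpectralCalibration,
    axial_resolution_um: float = 2.4,
    floor: float = 0.05,
) -> ShapingWindow:
    """Design a shaping window that realises a Gaussian target spectrum.

    The target is Gaussian in k with bandwidth set so the amplitude PSF has
    FWHM ``axial_resolution_um`` (optical µm): FWHM_k = 4·ln2 / FWHM_z.
    Weights are target/envelope, zeroed where the measured source envelope
    falls below ``floor`` of its peak (no noise amplification in the tails).
    """
    grid = calibration.resample_grid
    kc = 0.5 * (grid[0] + grid[-1])
    fwhm_k = 4 * np.log(2) / axial_resolution_um
    target = np.exp(-4 * np.log(2) * ((grid - kc) / fwhm_k) ** 2)
    env = np.asarray(envelope_k, dtype=float)
    env = env / env.max()
    weights = np.where(env > floor, target / np.maximum(env, floor), 0.0)
    return ShapingWindow(weights=weights, target=target)


@dataclass(frozen=True)
class DispersionCorrection:
    """Unit-magnitude complex phase multiplied onto the resampled spectrum."""

    phase: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.phase, dtype=complex)
        if not np.allclose(np.abs(p), 1.0, atol=1e-9):
            raise ValueError("dispersion correction must have unit magnitude everywhere")
        object.__setattr__(self, "phase", p)

    @classmethod
    def from_polynomial(
        cls, coeffs: tuple[float, ...], calibration: SpectralCalibration
    ) -> "DispersionCorrection":
        """Correction cancelling a residual phase polynomial in (k − k_centre)."""
        grid = calibration.resample_grid
        kc = 0.5 * (grid[0] + grid[-1])
        phi = np.polynomial.polynomial.polyval(grid - kc, coeffs)
        return cls(phase=np.exp(-1j * phi))


def apply_window(stack: np.ndarray, window: ShapingWindow) -> np.ndarray:
    """Multiply the shaping window onto the spectral axis."""
    if stack.shape[-1] != window.weights.size:
        raise ValueError("window length does not match spectral axis")
    return stack * window.weights


def apply_ndc(stack: np.ndarray, ndc: DispersionCorrection) -> np.ndarray:
    """Multiply the complex NDC array onto the spectral axis (complex out)."""
    if stack.shape[-1] != ndc.phase.size:
        raise ValueError("NDC length does not match spectral axis")
    return stack.astype(complex) * ndc.phase


# ---------------------------------------------------------------------------
# FFT reconstruction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BScanStack:
    """Linear-amplitude B-scan frames with their axial scale.

    ``frames`` is [n_frames, n_columns, n_depth]; ``axial_pitch`` is the
    optical depth per pixel (n_G·µm); ``depth_range`` the total imaged
    optical depth.
    """

    frames: np.ndarray
    axial_pitch: float
    depth_range: float

    def __post_init__(self) -> None:
        if np.any(self.frames < 0):
            raise ValueError("amplitudes must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_depth(self) -> int:
        return self.frames.shape[-1]

    def image(self, frame: int = 0) -> np.ndarray:
        """A single frame as a [depth, columns] image (depth increases downward)."""
        return self.frames[frame].T


def reconstruct(stack: np.ndarray, calibration: SpectralCalibration) -> BScanStack:
    """FFT along the spectral axis; keep the positive-depth half, linear amplitude.

    Input must be on the uniform-k grid (real before NDC, complex after).
    A real input yields a depth-symmetric ("folded") transform; only the
    positive half is stored.  Depth pixel m corresponds to optical depth
    m·axial_pitch with axial_pitch = π/(N·dk).
    """
    stack = np.asarray(stack)
    n = stack.shape[-1]
    if n % 2:
        raise ValueError("spectral axis must have even length")
    if n != calibration.resample_grid.size:
        raise ValueError("stack length does not match calibration grid")
    spec = np.fft.fft(stack, axis=-1)
    amp = np.abs(spec[..., : n // 2]) * (2.0 / n)
    pitch = calibration.axial_pitch_um
    while amp.ndim < 3:  # promote single spectra / single frames to a stack
        amp = amp[np.newaxis]
    return BScanStack(frames=amp, axial_pitch=pitch, depth_range=pitch * (n // 2))


def to_db(amplitude: np.ndarray, floor: float = 1e-12) -> np.ndarray:
    """Display transform: 20·log10 of the linear amplitude (dB)."""
    return 20 * np.log10(np.maximum(amplitude, floor))


def reconstruct_capture(
    raw: RawCapture,
    axial_resolution_um: float = 2.4,
    ndc: bool = False,
) -> BScanStack:
    """Full chain: blank subtraction → k-resampling → shaping → (NDC) → FFT.

    When ``ndc`` is true the correction is built from the capture's known
    residual dispersion polynomial, standing in for the pre-measured
    glass-interface calibration of a real instrument.
    """
    cal = SpectralCalibration(wavelength_nm=raw.wavelengths_nm)
    resid = subtract_blank(raw)
    uk = resample_to_k(resid, cal)
    env_k = resample_to_k(raw.config.envelope(), cal)
    window = design_window(env_k, cal, axial_resolution_um)
    shaped = apply_window(uk, window)
    if ndc:
        corr = DispersionCorrection.from_polynomial(raw.config.dispersion_phase, cal)
        shaped = apply_ndc(shaped, corr)
    return reconstruct(shaped, cal)


# ---------------------------------------------------------------------------
# Characterisation: PSF width, SNR, sensitivity roll-off
# ---------------------------------------------------------------------------

def measure_psf_fwhm(image: np.ndarray, axial_pitch: float, column: int) -> float:
    """FWHM (optical µm) of the dominant peak in one A-scan, by linear
    interpolation of the half-maximum crossings of the amplitude profile."""
    profile = np.asarray(image, dtype=float)[:, column]
    peak = int(np.argmax(profile))
    pv = profile[peak]
    noise = np.median(profile)
    if pv <= 0 or pv < 5 * max(noise, 1e-30):
        raise ValueError("no dominant peak above the noise in this column")
    half = pv / 2

    def cross(idx_range):
        prev = peak
        for i in idx_range:
            if profile[i] < half:
                # linear interpolation between i and prev
                frac = (profile[prev] - half) / (profile[prev] - profile[i])
                return prev + (i - prev) * frac
            prev = i
        raise ValueError("half-maximum crossing not found inside the image")

    left = cross(range(peak - 1, -1, -1))
    right = cross(range(peak + 1, profile.size))
    return float((right - left) * axial_pitch)


def measure_snr(
    image: np.ndarray,
    signal_roi: tuple[slice, slice],
    noise_roi: tuple[slice, slice],
) -> float:
    """SNR in dB: 20·log10(peak signal amplitude / noise-ROI amplitude SD).

    ROIs are (depth slice, column slice) into a [depth, columns] image and
    must not overlap.
    """
    img = np.asarray(image, dtype=float)
    mask_s = np.zeros(img.shape, dtype=bool)
    mask_n = np.zeros(img.shape, dtype=bool)
    mask_s[signal_roi] = True
    mask_n[noise_roi] = True
    if not mask_s.any() or not mask_n.any():
        raise ValueError("empty ROI")
    if (mask_s & mask_n).any():
        raise ValueError("signal and noise ROIs must be disjoint")
    peak = img[mask_s].max()
    sd = img[mask_n].std()
    if sd <= 0:
        raise ValueError("noise ROI has zero variance")
    return float(20 * np.log10(peak / sd))


def ndc_degradation(fwhm_without: float, fwhm_with: float) -> float:
    """Fractional axial-resolution degradation without dispersion correction,
    as a percentage rounded to the nearest whole percent."""
    if fwhm_with <= 0:
        raise ValueError("corrected FWHM must be positive")
    return round((fwhm_without - fwhm_with) / fwhm_with * 100)


@dataclass(frozen=True)
class RolloffResult:
    """Monte-Carlo and closed-form sensitivity roll-off versus depth."""

    depths_um: np.ndarray
    snr_db: np.ndarray  # Monte-Carlo mean SNR at each depth
    model_db: np.ndarray  # closed-form roll-off, 0 dB at z = 0

    @property
    def snr_rel_db(self) -> np.ndarray:
        """Monte-Carlo roll-off relative to the shallowest depth."""
        return self.snr_db - self.snr_db[0]


def _rolloff_model_db(
    depths: np.ndarray, z_max: float, resolution_px: float, pixel_integration: bool
) -> np.ndarray:
    """Closed-form amplitude roll-off in dB: sinc (pixel integration) times
    Gaussian (spectrograph resolution) MTFs at the fringe frequency."""
    f = 0.5 * depths / z_max  # cycles per spectral pixel
    mtf = np.exp(-(np.pi**2) * resolution_px**2 * f**2 / (4 * np.log(2)))
    if pixel_integration:
        mtf = mtf * np.sinc(f)
    return 20 * np.log10(mtf)


def rolloff_curve(
    resolution_px: float,
    depths: np.ndarray,
    n_pixels: int = 512,
    shot_noise_scale: float = 1e4,
    n_repeats: int = 50,
    pixel_integration: bool = True,
    oversample: int = 16,
    seed: int = 0,
) -> RolloffResult:
    """Monte-Carlo sensitivity roll-off for a single ideal reflector.

    For each depth a unit-contrast fringe on a flat envelope is synthesised
    on an ``oversample``-times finer grid, box-averaged over each detector
    pixel (pixel integration), blurred by a Gaussian of FWHM
    ``resolution_px``, Poisson-sampled, reconstructed by FFT, and the SNR
    (peak amplitude over background amplitude SD) measured; the mean over
    ``n_repeats`` noise draws is reported together with the closed-form
    sinc²×Gaussian roll-off for cross-checking.
    """
    if resolution_px < 0:
        raise ValueError("resolution_px must be non-negative")
    depths = np.asarray(depths, dtype=float)
    z_max = n_pixels / 2  # work in units where axial pitch = 1 px
    if np.any(depths >= z_max):
        raise ValueError(
            f"depth beyond the unambiguous range ({z_max:.0f} px): fringe would alias"
        )
    rng = np.random.default_rng(seed)
    fine = (np.arange(n_pixels * oversample) + 0.5) / oversample - 0.5
    contrast = 0.4
    # snap to reconstruction bins: an off-bin fringe spreads sidelobes over
    # the whole un-windowed spectrum and measures leakage, not roll-off
    depths = np.round(depths * 2 * z_max / n_pixels) * n_pixels / (2 * z_max)
    snr = np.empty(depths.size)
    for i, z in enumerate(depths):
        f = 0.5 * z / z_max  # cycles/px
        fringe = 1 + contrast * np.cos(2 * np.pi * f * fine)
        if pixel_integration:
            spectrum = fringe.reshape(n_pixels, oversample).mean(axis=1)
        else:
            spectrum = fringe[oversample // 2 :: oversample]
        if resolution_px > 0:
            spectrum = gaussian_filter1d(
                spectrum, resolution_px / (2 * np.sqrt(2 * np.log(2))), mode="wrap"
            )
        expected = spectrum * shot_noise_scale
        vals = np.empty(n_repeats)
        peak_bin = int(round(f * n_pixels))
        bins = np.arange(n_pixels // 2)
        bg_mask = (np.abs(bins - peak_bin) > 10) & (bins >= 5) & (bins < n_pixels // 2 - 5)
        lo, hi = max(0, peak_bin - 3), min(n_pixels // 2, peak_bin + 4)
        for r in range(n_repeats):
            noisy = rng.poisson(np.broadcast_to(expected, expected.shape)).astype(float)
            amp = np.abs(np.fft.fft(noisy - expected.mean()))[: n_pixels // 2]
            peak = amp[lo:hi].max()
            vals[r] = 20 * np.log10(peak / amp[bg_mask].std())
        snr[i] = vals.mean()
    model = _rolloff_model_db(depths, z_max, resolution_px, pixel_integration)
    return RolloffResult(depths_um=depths, snr_db=snr, model_db=model - model[0])
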