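"""Synthetic line-field SD-OCT cornea captures with exact ground truth.

The simulator produces raw spectral interferograms of a layered cornea
phantom as a grating spectrograph would record them: sampled uniformly in
wavelength, blurred by the finite spectrograph resolution, Poisson shot
noise, a static fixed-pattern fringe, inter-frame axial motion, and the
occasional washed-out (motion-blurred) frame.  Every downstream stage of
the pipeline is validated against the phantom's known interface depths.

Depths are expressed as *optical* path length in micrometres (the product
of geometric depth and the group refractive index ``n_G``); geometric
layer thicknesses are converted to optical separations internally.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "DEFAULT_N_G",
    "PhantomParams",
    "ContactLens",
    "CorneaPhantom",
    "AcquisitionConfig",
    "RawCapture",
    "make_phantom",
    "simulate_capture",
    "unambiguous_depth_um",
    "write_capture",
    "read_capture",
]

#: Group refractive index of corneal tissue in the near infrared.
DEFAULT_N_G = 1.387


# ---------------------------------------------------------------------------
# Phantom geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContactLens:
    """Optional contact lens sitting above the tear film.

    Depths are optical µm of the front and back surface; reflectivities are
    power reflectivities of the two interfaces.
    """

    front_depth_um: float
    back_depth_um: float
    front_reflectivity: float = 2e-4
    back_reflectivity: float = 2e-4

    def __post_init__(self) -> None:
        if not self.front_depth_um < self.back_depth_um:
            raise ValueError("contact lens front surface must lie above its back surface")


@dataclass(frozen=True)
class PhantomParams:
    """Parameters of the layered cornea phantom.

    Thicknesses are *geometric* µm; depth of the anterior surface is optical
    µm.  ``surface_sag_um`` is the centre-to-edge quadratic sag of the
    anterior surface (the cornea imaged at the normal-incidence orientation
    is nearly flat over the short line field).  ``*_roughness_um`` are
    per-column Gaussian perturbations of the layer thicknesses.
    """

    n_columns: int = 512
    surface_depth_um: float = 100.0
    surface_sag_um: float = 5.0
    epi_thickness_um: float = 50.0
    bowman_thickness_um: float = 16.6
    tear_film_um: float = 0.0
    epi_roughness_um: float = 0.5
    bowman_roughness_um: float = 1.0
    tear_roughness_um: float = 0.0
    # power reflectivities of the specular interfaces, anterior to posterior
    surface_reflectivity: float = 4e-4
    epi_bowman_reflectivity: float = 1e-4
    bowman_stroma_reflectivity: float = 5e-5
    # discrete stromal scatterers (keratocytes / lamella interfaces)
    n_scatterers: int = 300
    scatterer_amplitude: float = 2e-3
    stroma_extent_um: float = 120.0
    contact_lens: ContactLens | None = None
    n_g: float = DEFAULT_N_G


@dataclass(frozen=True)
class CorneaPhantom:
    """Ground-truth cornea geometry per lateral column.

    ``surface_depth`` is the optical depth of the air–tear/epithelium
    interface; ``epi_thickness``/``bowman_thickness``/``tear_film_thickness``
    are geometric µm per column.  ``interface_reflectivities`` maps interface
    names to power reflectivities.  ``stromal_scatterers`` is an array of
    (column, optical depth µm, amplitude reflectivity) rows.
    """

    lateral_positions: np.ndarray
    surface_depth: np.ndarray
    epi_thickness: np.ndarray
    bowman_thickness: np.ndarray
    tear_film_thickness: np.ndarray
    interface_reflectivities: dict[str, float]
    stromal_scatterers: np.ndarray
    contact_lens: ContactLens | None = None
    n_g: float = DEFAULT_N_G

    def __post_init__(self) -> None:
        if self.n_g <= 1:
            raise ValueError("group refractive index must exceed 1")
        for name in ("epi_thickness", "bowman_thickness", "tear_film_thickness"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_columns(self) -> int:
        return self.lateral_positions.size

    def interface_depths(self) -> dict[str, np.ndarray]:
        """Optical depths (µm) of the three corneal interfaces per column.

        The tear film is merged with the epithelium: the anterior surface is
        the air–tear-film interface and the next resolved boundary is
        epithelium–Bowman's, so the "epithelium" layer of the pipeline is
        epithelium plus tear film by construction.
        """
        z0 = self.surface_depth
        z1 = z0 + (self.tear_film_thickness + self.epi_thickness) * self.n_g
        z2 = z1 + self.bowman_thickness * self.n_g
        return {"surface": z0, "epi_bowman": z1, "bowman_stroma": z2}

    def max_depth_um(self, stroma_extent_um: float = 0.0) -> float:
        z2 = self.interface_depths()["bowman_stroma"]
        zmax = float(np.max(z2)) + stroma_extent_um
        if self.stromal_scatterers.size:
            zmax = max(zmax, float(self.stromal_scatterers[:, 1].max()))
        return zmax


def make_phantom(params: PhantomParams = PhantomParams(), seed: int = 0) -> CorneaPhantom:
    """Generate a cornea phantom with smoothly varying interfaces.

    The anterior surface is a quadratic sag plus per-column roughness; layer
    thicknesses are their nominal values plus independent per-column
    Gaussian roughness (clipped at zero).  With all roughness set to zero
    the phantom is exactly flat/constant, which downstream tests exploit.
    """
    for name in ("epi_thickness_um", "bowman_thickness_um", "tear_film_um"):
        if getattr(params, name) < 0:
            raise ValueError(f"{name} must be non-negative")
    if params.n_columns < 1:
        raise ValueError("need at least one lateral column")
    rng = np.random.default_rng(seed)
    cols = np.arange(params.n_columns)
    x = (cols - (params.n_columns - 1) / 2) / max(params.n_columns / 2, 1)
    surface = params.surface_depth_um + params.surface_sag_um * x**2
    surface = surface + 0.2 * rng.standard_normal(params.n_columns).cumsum() / np.sqrt(
        np.arange(1, params.n_columns + 1)
    )

    def rough(mean: float, sd: float) -> np.ndarray:
        # spatially correlated zero-mean texture (correlation length a few
        # columns, as for a real interface), sample SD exactly `sd`, so the
        # column mean equals the nominal thickness
        t = np.full(params.n_columns, float(mean))
        if sd > 0 and params.n_columns > 3:
            from scipy.ndimage import gaussian_filter1d

            x = gaussian_filter1d(rng.standard_normal(params.n_columns), 2.0, mode="wrap")
            x = x - x.mean()
            if x.std() > 0:
                t = t + sd * x / x.std()
        return np.clip(t, 0.0, None)

    epi = rough(params.epi_thickness_um, params.epi_roughness_um)
    bowman = rough(params.bowman_thickness_um, params.bowman_roughness_um)
    tear = rough(params.tear_film_um, params.tear_roughness_um)

    z2 = surface + (tear + epi + bowman) * params.n_g
    if params.n_scatterers > 0:
        sc_col = rng.integers(0, params.n_columns, params.n_scatterers)
        sc_z = z2[sc_col] + rng.uniform(2.0, params.stroma_extent_um, params.n_scatterers)
        sc_a = params.scatterer_amplitude * rng.uniform(0.3, 1.0, params.n_scatterers)
        scatterers = np.column_stack([sc_col, sc_z, sc_a])
    else:
        scatterers = np.empty((0, 3))

    return CorneaPhantom(
        lateral_positions=cols,
        surface_depth=surface,
        epi_thickness=epi,
        bowman_thickness=bowman,
        tear_film_thickness=tear,
        interface_reflectivities={
            "surface": params.surface_reflectivity,
            "epi_bowman": params.epi_bowman_reflectivity,
            "bowman_stroma": params.bowman_stroma_reflectivity,
        },
        stromal_scatterers=scatterers,
        contact_lens=params.contact_lens,
        n_g=params.n_g,
    )


# ---------------------------------------------------------------------------
# Acquisition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AcquisitionConfig:
    """Camera / spectrograph settings for one capture.

    A capture is 50 consecutive frames spanning 0.125 s.  The spectrum is
    sampled uniformly in *wavelength* (a grating spectrograph), so the
    reconstruction genuinely has to resample to uniform wavenumber.
    ``spectrograph_resolution_px`` is the FWHM of the Gaussian spectral
    blur in detector pixels; ``shot_noise_scale`` is the photoelectron
    count at the reference (envelope peak) level.  ``axial_jitter_sd`` is
    the standard deviation of the frame-to-frame axial motion, in optical
    µm.  ``dispersion_phase`` are polynomial coefficients (c0, c1, c2, c3)
    of the residual phase in powers of (k − k_centre), k in rad/µm.
    """

    n_spectral_pixels: int = 2048
    wavelength_range_nm: tuple[float, float] = (700.0, 1000.0)
    n_columns: int = 512
    n_frames: int = 50
    frame_period_s: float = 0.0025
    integration_time_s: float = 500e-6  # metadata only
    spectrograph_resolution_px: float = 2.0
    shot_noise_scale: float = 1e4
    fixed_pattern_amplitude: float = 0.02
    axial_jitter_sd: float = 3.5
    washout_probability: float = 0.06
    washout_residual_contrast: float = 1e-3
    dispersion_phase: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0)
    envelope_fwhm_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.wavelength_range_nm
        if not lo < hi:
            raise ValueError("wavelength range must be (min, max) with min < max")
        if not 0.0 <= self.washout_probability <= 1.0:
            raise ValueError("washout_probability must be in [0, 1]")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")

    @property
    def wavelengths_nm(self) -> np.ndarray:
        lo, hi = self.wavelength_range_nm
        return np.linspace(lo, hi, self.n_spectral_pixels)

    @property
    def k_rad_per_um(self) -> np.ndarray:
        """Wavenumber per detector pixel, rad/µm (decreasing with pixel)."""
        return 2 * np.pi / (self.wavelengths_nm * 1e-3)

    def envelope(self) -> np.ndarray:
        """Source spectral envelope on the detector, peak normalised to 1.

        Gaussian in wavenumber, FWHM ``envelope_fwhm_fraction`` of the total
        spanned wavenumber range.
        """
        k = self.k_rad_per_um
        kc = 0.5 * (k.max() + k.min())
        fwhm = self.envelope_fwhm_fraction * (k.max() - k.min())
        return np.exp(-4 * np.log(2) * ((k - kc) / fwhm) ** 2)


def unambiguous_depth_um(config: AcquisitionConfig) -> float:
    """Maximum optical depth before the fringe aliases (Nyquist), µm.

    The limiting sampling interval is the largest wavenumber step across the
    wavelength-uniform grid.
    """
    k = np.sort(config.k_rad_per_um)
    dk_max = float(np.max(np.diff(k)))
    return np.pi / (2 * dk_max)


@dataclass(frozen=True)
class CaptureTruth:
    """Everything the simulator knows that the pipeline must recover."""

    phantom: CorneaPhantom
    axial_shifts_um: np.ndarray  # per-frame axial offset, optical µm
    washed_out: np.ndarray  # boolean per frame
    fixed_pattern: np.ndarray  # [n_columns, n_spectral_pixels]


@dataclass(frozen=True)
class RawCapture:
    """Raw spectral frames plus calibration, blank, and ground truth.

    ``frames`` is [n_frames, n_columns, n_spectral_pixels] of non-negative
    photoelectron counts; ``blank`` is the averaged reference-only image.
    """

    frames: np.ndarray
    wavelengths_nm: np.ndarray
    blank: np.ndarray
    config: AcquisitionConfig
    truth: CaptureTruth

    def __post_init__(self) -> None:
        if np.any(self.frames < 0):
            raise ValueError("raw counts must be non-negative")
        if self.blank.shape != self.frames.shape[1:]:
            raise ValueError("blank must match the per-frame (columns, pixels) shape")


def _column_depths(phantom: CorneaPhantom) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Per-column reflector optical depths and amplitude reflectivities."""
    ifaces = phantom.interface_depths()
    refl = phantom.interface_reflectivities
    n = phantom.n_columns
    depths: list[list[float]] = [[] for _ in range(n)]
    amps: list[list[float]] = [[] for _ in range(n)]
    for name in ("surface", "epi_bowman", "bowman_stroma"):
        a = np.sqrt(refl[name])
        for c in range(n):
            depths[c].append(float(ifaces[name][c]))
            amps[c].append(a)
    if phantom.contact_lens is not None:
        cl = phantom.contact_lens
        for c in range(n):
            depths[c].extend([cl.front_depth_um, cl.back_depth_um])
            amps[c].extend([np.sqrt(cl.front_reflectivity), np.sqrt(cl.back_reflectivity)])
    for col, z, a in phantom.stromal_scatterers:
        depths[int(col)].append(float(z))
        amps[int(col)].append(float(a))
    return [np.asarray(d) for d in depths], [np.asarray(a) for a in amps]


def simulate_capture(phantom: CorneaPhantom, config: AcquisitionConfig) -> RawCapture:
    """Simulate one raw LF-SD-OCT capture of a cornea phantom.

    For every column and frame the spectrum is

        I(λ) = E(λ) · [1 + Σᵢ 2√rᵢ cos(2 k zᵢ + φ(k))]

    sampled at the detector wavelengths (k = 2π/λ), blurred along the
    spectral axis by a Gaussian of FWHM ``spectrograph_resolution_px``,
    Poisson-sampled at ``shot_noise_scale`` photoelectrons, plus a static
    fixed-pattern fringe image.  ``zᵢ`` includes the per-frame axial jitter;
    washed-out frames keep the reference level but lose fringe contrast.
    Bit-reproducible for a fixed ``config.seed``.
    """
    if phantom.n_columns != config.n_columns:
        raise ValueError(
            f"phantom has {phantom.n_columns} columns but config expects {config.n_columns}"
        )
    z_alias = unambiguous_depth_um(config)
    jitter_margin = 5 * config.axial_jitter_sd
    z_needed = phantom.max_depth_um() + jitter_margin
    if z_needed >= z_alias:
        raise ValueError(
            f"reflector at optical depth {z_needed:.1f} µm exceeds the unambiguous "
            f"depth range ({z_alias:.1f} µm): the fringe would alias"
        )

    rng = np.random.default_rng(config.seed)
    k = config.k_rad_per_um
    kc = 0.5 * (k.max() + k.min())
    env = config.envelope()
    phase_disp = np.polynomial.polynomial.polyval(k - kc, config.dispersion_phase)

    shifts = rng.normal(0.0, config.axial_jitter_sd, config.n_frames)
    washed = rng.random(config.n_frames) < config.washout_probability

    # shot_noise_scale == 0 means a noiseless capture in unit reference level
    intensity_scale = config.shot_noise_scale if config.shot_noise_scale > 0 else 1.0

    # static spurious fringe (e.g. internal reflection), non-negative by design
    z_fp = 0.35 * z_alias
    fixed_pattern = (
        config.fixed_pattern_amplitude
        * intensity_scale
        * env
        * (1 + np.cos(2 * k * z_fp))
        / 2
    )
    fixed_pattern = np.broadcast_to(fixed_pattern, (config.n_columns, config.n_spectral_pixels)).copy()

    depths, amps = _column_depths(phantom)
    # Quadrature sums at zero jitter: a frame shifted by δ multiplies the
    # per-reflector phases by a common e^{i·2δk}, so
    #   Σᵢ 2aᵢcos(θᵢ + 2δk) = cos(2δk)·C − sin(2δk)·S
    # with C, S the zero-jitter cosine/sine sums — one O(C·N) pass per frame.
    c_sum = np.empty((config.n_columns, config.n_spectral_pixels))
    s_sum = np.empty_like(c_sum)
    for c in range(config.n_columns):
        theta = 2 * np.outer(depths[c], k) + phase_disp
        w = 2 * amps[c][:, None]
        c_sum[c] = (w * np.cos(theta)).sum(axis=0)
        s_sum[c] = (w * np.sin(theta)).sum(axis=0)

    frames = np.empty(
        (config.n_frames, config.n_columns, config.n_spectral_pixels), dtype=np.float32
    )
    from scipy.ndimage import gaussian_filter1d

    sigma_px = config.spectrograph_resolution_px / (2 * np.sqrt(2 * np.log(2)))
    for f in range(config.n_frames):
        contrast = config.washout_residual_contrast if washed[f] else 1.0
        psi = 2 * shifts[f] * k
        fringe = np.cos(psi) * c_sum - np.sin(psi) * s_sum
        spectra = env * (1 + contrast * fringe)
        if sigma_px > 0:
            spectra = gaussian_filter1d(spectra, sigma_px, axis=1, mode="nearest")
        expected = np.clip(spectra * intensity_scale, 0.0, None)
        noisy = rng.poisson(expected).astype(np.float64) if config.shot_noise_scale > 0 else expected
        frames[f] = noisy + fixed_pattern

    blank = (env * intensity_scale) * np.ones((config.n_columns, 1))
    return RawCapture(
        frames=frames,
        wavelengths_nm=config.wavelengths_nm,
        blank=blank,
        config=config,
        truth=CaptureTruth(
            phantom=phantom,
            axial_shifts_um=shifts,
            washed_out=washed,
            fixed_pattern=fixed_pattern,
        ),
    )


# ---------------------------------------------------------------------------
# On-disk interchange: multi-page TIFF + JSON sidecar
# ---------------------------------------------------------------------------

def write_capture(capture: RawCapture, out_dir: str | Path) -> Path:
    """Write a capture as 16-bit multi-page TIFF plus a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scale = float(capture.frames.max()) or 1.0
    q = np.clip(capture.frames / scale * 65535.0, 0, 65535).astype(np.uint16)
    tifffile.imwrite(out / "frames.tiff", q, photometric="minisblack")
    qb = np.clip(capture.blank / scale * 65535.0, 0, 65535).astype(np.uint16)
    tifffile.imwrite(out / "blank.tiff", qb, photometric="minisblack")
    phantom = capture.truth.phantom
    sidecar = {
        "wavelengths_nm": capture.wavelengths_nm.tolist(),
        "intensity_scale": scale,
        "config": dataclasses.asdict(capture.config),
        "truth": {
            "axial_shifts_um": capture.truth.axial_shifts_um.tolist(),
            "washed_out": capture.truth.washed_out.astype(bool).tolist(),
            "phantom": {
                "surface_depth": phantom.surface_depth.tolist(),
                "epi_thickness": phantom.epi_thickness.tolist(),
                "bowman_thickness": phantom.bowman_thickness.tolist(),
                "tear_film_thickness": phantom.tear_film_thickness.tolist(),
                "interface_reflectivities": phantom.interface_reflectivities,
                "n_g": phantom.n_g,
            },
        },
    }
    (out / "capture.json").write_text(json.dumps(sidecar))
    return out


def read_capture(in_dir: str | Path) -> RawCapture:
    """Read a capture written by :func:`write_capture` (truth partially restored)."""
    src = Path(in_dir)
    meta = json.loads((src / "capture.json").read_text())
    scale = meta["intensity_scale"]
    frames = tifffile.imread(src / "frames.tiff").astype(np.float64) * scale / 65535.0
    blank = tifffile.imread(src / "blank.tiff").astype(np.float64) * scale / 65535.0
    cfg_d = meta["config"]
    cfg_d["wavelength_range_nm"] = tuple(cfg_d["wavelength_range_nm"])
    cfg_d["dispersion_phase"] = tuple(cfg_d["dispersion_phase"])
    config = AcquisitionConfig(**cfg_d)
    ph = meta["truth"]["phantom"]
    n_cols = len(ph["surface_depth"])
    phantom = CorneaPhantom(
        lateral_positions=np.arange(n_cols),
        surface_depth=np.asarray(ph["surface_depth"]),
        epi_thickness=np.asarray(ph["epi_thickness"]),
        bowman_thickness=np.asarray(ph["bowman_thickness"]),
        tear_film_thickness=np.asarray(ph["tear_film_thickness"]),
        interface_reflectivities=ph["interface_reflectivities"],
        stromal_scatterers=np.empty((0, 3)),
        n_g=ph["n_g"],
    )
    truth = CaptureTruth(
        phantom=phantom,
        axial_shifts_um=np.asarray(meta["truth"]["axial_shifts_um"]),
        washed_out=np.asarray(meta["truth"]["washed_out"], dtype=bool),
        fixed_pattern=np.zeros_like(blank),
    )
    return RawCapture(
        frames=frames, wavelengths_nm=np.asarray(meta["wavelengths_nm"]),
        blank=blank, config=config, truth=truth,
    )
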