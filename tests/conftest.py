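"""Shared fixtures: a small but fully featured phantom capture.

The acquisition keeps the study's 50-frame capture structure but uses a
short line field (64 columns) and 768 spectral pixels so the full pipeline
runs in seconds; the axial pixel pitch (~1.165 optical µm) is unchanged
because it depends only on the spanned wavenumber range.
"""

import numpy as np
import pytest

import octcornea as oc

N_PIXELS = 768
N_COLUMNS = 64


def small_phantom_params(**overrides) -> oc.PhantomParams:
    base = dict(
        n_columns=N_COLUMNS,
        surface_depth_um=60.0,
        stroma_extent_um=60.0,
        n_scatterers=60,
    )
    base.update(overrides)
    return oc.PhantomParams(**base)


def small_config(**overrides) -> oc.AcquisitionConfig:
    base = dict(n_spectral_pixels=N_PIXELS, n_columns=N_COLUMNS, n_frames=50)
    base.update(overrides)
    return oc.AcquisitionConfig(**base)


def noiseless_config(**overrides) -> oc.AcquisitionConfig:
    base = dict(
        shot_noise_scale=0.0,
        spectrograph_resolution_px=0.0,
        fixed_pattern_amplitude=0.0,
        axial_jitter_sd=0.0,
        washout_probability=0.0,
        n_frames=3,
    )
    base.update(overrides)
    return small_config(**base)


def single_reflector_params(depth_um: float = 100.0, **overrides) -> oc.PhantomParams:
    """A phantom degenerate to (almost) one reflector at a given depth."""
    base = dict(
        n_columns=4,
        surface_depth_um=depth_um,
        surface_sag_um=0.0,
        epi_thickness_um=0.01,
        bowman_thickness_um=0.01,
        epi_roughness_um=0.0,
        bowman_roughness_um=0.0,
        epi_bowman_reflectivity=0.0,
        bowman_stroma_reflectivity=0.0,
        n_scatterers=0,
        stroma_extent_um=0.0,
    )
    base.update(overrides)
    return oc.PhantomParams(**base)


@pytest.fixture(scope="session")
def capture() -> oc.RawCapture:
    phantom = oc.make_phantom(small_phantom_params(), seed=1)
    return oc.simulate_capture(phantom, small_config(seed=2))


@pytest.fixture(scope="session")
def measurement(capture) -> oc.CaptureMeasurement:
    return oc.measure_capture(capture)


@pytest.fixture(scope="session")
def bscan_stack(capture) -> oc.BScanStack:
    return oc.reconstruct_capture(capture)
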