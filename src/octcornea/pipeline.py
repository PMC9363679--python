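"""End-to-end convenience chain: raw capture → thickness profiles.

Runs the stages in their canonical order — reconstruction, fixed-pattern
removal, washout rejection, reference selection, axial alignment, linear
averaging, 2×2 median smoothing, amplitude energy, three-path graph
search, thickness conversion — with the package defaults at every stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import averaging, reconstruction, segmentation, thickness
from .synthetic import RawCapture

__all__ = ["CaptureMeasurement", "measure_capture"]


@dataclass(frozen=True)
class CaptureMeasurement:
    """Everything produced from one capture."""

    bscans: reconstruction.BScanStack
    averaged: averaging.AveragedBScan
    result: segmentation.SegmentationResult
    epithelium: thickness.ThicknessProfile
    bowman: thickness.ThicknessProfile


def measure_capture(
    raw: RawCapture,
    axial_resolution_um: float = 2.4,
    ndc: bool = False,
    roi: averaging.CorrelationROI | None = None,
    min_pixel_value: float | None = None,
    min_pixel_count: int | None = None,
    max_step: int = 2,
    exclusion_halfwidth: int = 3,
    trim_columns: int = 2,
) -> CaptureMeasurement:
    """Measure epithelial and Bowman's layer thickness from a raw capture.

    ``trim_columns`` drops the outermost columns from the thickness
    profiles, where the 2×2 filters replicate edges.
    """
    stack = reconstruction.reconstruct_capture(raw, axial_resolution_um, ndc=ndc)
    stack = averaging.remove_fixed_pattern(stack)
    qc = averaging.washout_filter(stack, min_pixel_value, min_pixel_count)
    if not qc.accepted:
        raise ValueError("all frames rejected as washed out")
    if roi is None:
        roi = averaging.auto_roi(stack)
    qc = averaging.estimate_shifts(stack, qc, roi)
    avg = averaging.align_and_average(stack, qc)
    smoothed = segmentation.preprocess(avg.image)
    energy = segmentation.build_energy(smoothed)
    result = segmentation.find_three_paths(
        energy, max_step=max_step, exclusion_halfwidth=exclusion_halfwidth
    )
    epi, bow = thickness.paths_to_thickness(
        result, avg.axial_pitch, raw.truth.phantom.n_g
    )
    if trim_columns > 0 and epi.thickness_um.size > 2 * trim_columns:
        sl = slice(trim_columns, -trim_columns)
        epi = thickness.ThicknessProfile(
            columns=epi.columns[sl], thickness_um=epi.thickness_um[sl],
            layer=epi.layer, n_g=epi.n_g,
        )
        bow = thickness.ThicknessProfile(
            columns=bow.columns[sl], thickness_um=bow.thickness_um[sl],
            layer=bow.layer, n_g=bow.n_g,
        )
    return CaptureMeasurement(
        bscans=stack, averaged=avg, result=result, epithelium=epi, bowman=bow
    )
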