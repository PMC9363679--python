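"""Correlated frame averaging: fixed-pattern removal, washout rejection,
reference-frame selection, 1D axial alignment, linear-amplitude averaging.

The chain runs strictly in this order on reconstructed linear-amplitude
frames; the log (dB) transform is display-only and never precedes the mean.
Axial registration is integer-pixel (nearest pixel) on purpose: the corneal
interfaces are the strongest features and inter-frame motion is purely
axial in this geometry, so a 1D correlation of depth profiles suffices.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .reconstruction import BScanStack

__all__ = [
    "CorrelationROI",
    "QCReport",
    "AveragedBScan",
    "remove_fixed_pattern",
    "default_washout_thresholds",
    "washout_filter",
    "select_reference",
    "estimate_axial_shift",
    "estimate_shifts",
    "align_and_average",
    "auto_roi",
]


@dataclass(frozen=True)
class CorrelationROI:
    """Column/depth window (pixels) covering the strongest desired features.

    On the instrument this area is selected by the operator; here it is a
    parameter (see :func:`auto_roi` for an automatic stand-in).
    """

    col_start: int
    col_stop: int
    depth_start: int
    depth_stop: int

    def __post_init__(self) -> None:
        if self.col_stop <= self.col_start or self.depth_stop <= self.depth_start:
            raise ValueError("ROI must be non-empty")
        if min(self.col_start, self.depth_start) < 0:
            raise ValueError("ROI must lie inside the image")

    def validate(self, n_columns: int, n_depth: int) -> None:
        if self.col_stop > n_columns or self.depth_stop > n_depth:
            raise ValueError("ROI exceeds image bounds")


@dataclass(frozen=True)
class QCReport:
    """Which frames survived quality control and how they were aligned."""

    accepted: list[int]
    discarded: list[int]
    shifts: dict[int, int]  # accepted frame -> integer axial correction (px)
    reference_frame: int | None
    min_pixel_value: float
    min_pixel_count: int


@dataclass(frozen=True)
class AveragedBScan:
    """Mean of aligned linear-amplitude frames, as a [depth, columns] image."""

    image: np.ndarray
    axial_pitch: float
    qc: QCReport


def remove_fixed_pattern(stack: BScanStack) -> BScanStack:
    """Subtract the per-pixel median image across frames; clamp at zero.

    The median over ≥3 frames estimates any frame-invariant artifact
    (spurious fringes, residual DC) while the moving sample, displaced by
    jitter between frames, largely drops out.
    """
    if stack.n_frames < 3:
        raise ValueError("fixed-pattern estimation needs at least 3 frames")
    median = np.median(stack.frames, axis=0)
    cleaned = np.clip(stack.frames - median, 0.0, None)
    return replace(stack, frames=cleaned)


def default_washout_thresholds(
    stack: BScanStack, roi: CorrelationROI | None = None
) -> tuple[float, int]:
    """(min_pixel_value, min_pixel_count) defaults.

    After fixed-pattern removal about half the background clamps to zero,
    so the stack *median* is degenerate as a background level; the mean
    amplitude is the robust analogue.  Interface reflections sit far above
    10× the mean while residual noise in a washed-out frame stays below
    it.  The pixel-count floor is 1% of the correlation ROI (the feature
    band); when no ROI is given a nominal 81-row full-width band is
    assumed.
    """
    min_val = 10.0 * float(stack.frames.mean())
    if roi is None:
        n_cols = stack.frames.shape[1]
        roi_pixels = n_cols * min(81, stack.n_depth)
    else:
        roi_pixels = (roi.col_stop - roi.col_start) * (roi.depth_stop - roi.depth_start)
    min_count = max(1, int(0.01 * roi_pixels))
    return min_val, min_count


def washout_filter(
    stack: BScanStack,
    min_pixel_value: float | None = None,
    min_pixel_count: int | None = None,
) -> QCReport:
    """Discard frames whose super-threshold pixel count is below the minimum.

    A washed-out frame (motion during integration) loses its fringe
    contrast, so almost no pixel rises above the background threshold.
    """
    if min_pixel_value is None or min_pixel_count is None:
        dv, dc = default_washout_thresholds(stack)
        min_pixel_value = dv if min_pixel_value is None else min_pixel_value
        min_pixel_count = dc if min_pixel_count is None else min_pixel_count
    if min_pixel_value < 0 or min_pixel_count < 0:
        raise ValueError("thresholds must be non-negative")
    counts = (stack.frames > min_pixel_value).reshape(stack.n_frames, -1).sum(axis=1)
    accepted = [i for i in range(stack.n_frames) if counts[i] >= min_pixel_count]
    discarded = [i for i in range(stack.n_frames) if counts[i] < min_pixel_count]
    return QCReport(
        accepted=accepted,
        discarded=discarded,
        shifts={},
        reference_frame=None,
        min_pixel_value=float(min_pixel_value),
        min_pixel_count=int(min_pixel_count),
    )


def select_reference(stack: BScanStack, qc: QCReport) -> int:
    """Accepted frame with the highest super-threshold pixel count (ties →
    lowest frame index)."""
    if not qc.accepted:
        raise ValueError("no accepted frames to choose a reference from")
    counts = (stack.frames > qc.min_pixel_value).reshape(stack.n_frames, -1).sum(axis=1)
    best = max(qc.accepted, key=lambda i: (counts[i], -i))
    return int(best)


def estimate_axial_shift(
    frame: np.ndarray, reference: np.ndarray, roi: CorrelationROI
) -> int:
    """Integer axial correction aligning ``frame`` to ``reference``.

    Within the ROI, columns are summed into 1D axial profiles and the lag
    maximising the normalised cross-correlation is found over ±(ROI depth).
    The returned value is the shift to *apply* to the frame: a frame
    displaced downward by +7 px yields −7.

    ``frame``/``reference`` are [columns, depth] frames of a stack.
    """
    n_cols, n_depth = frame.shape
    roi.validate(n_cols, n_depth)
    sl = (slice(roi.col_start, roi.col_stop), slice(roi.depth_start, roi.depth_stop))
    prof_f = frame[sl].sum(axis=0).astype(float)
    prof_r = reference[sl].sum(axis=0).astype(float)
    prof_f = prof_f - prof_f.mean()
    prof_r = prof_r - prof_r.mean()
    if prof_f.std() == 0 or prof_r.std() == 0:
        raise ValueError("flat (zero-variance) profile: cannot correlate")
    # bounded by the ROI depth, but demand enough overlap for the
    # normalised correlation to be meaningful
    min_overlap = max(8, prof_f.size // 4)
    max_lag = prof_f.size - min_overlap
    best_lag, best_val = 0, -np.inf
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            a, b = prof_f[lag:], prof_r[: prof_r.size - lag]
        else:
            a, b = prof_f[:lag], prof_r[-lag:]
        if a.size < min_overlap or a.std() == 0 or b.std() == 0:
            continue
        val = float(np.corrcoef(a, b)[0, 1])
        if val > best_val + 1e-12 or (abs(val - best_val) <= 1e-12 and abs(lag) < abs(best_lag)):
            best_lag, best_val = lag, val
    # profile displaced by +d matches reference when slid up by d → correction −d
    return -best_lag


def _shift_frame(frame: np.ndarray, shift: int) -> tuple[np.ndarray, np.ndarray]:
    """Shift along the depth axis by an integer, zero-filling; also return a
    validity mask so zero-filled rows are excluded from the mean."""
    out = np.zeros_like(frame)
    valid = np.zeros_like(frame, dtype=bool)
    n = frame.shape[-1]
    if shift >= n or -shift >= n:
        return out, valid
    if shift >= 0:
        out[:, shift:] = frame[:, : n - shift]
        valid[:, shift:] = True
    else:
        out[:, :shift] = frame[:, -shift:]
        valid[:, :shift] = True
    return out, valid


def estimate_shifts(stack: BScanStack, qc: QCReport, roi: CorrelationROI) -> QCReport:
    """Fill in the QC report with per-frame corrections against the reference."""
    ref_idx = select_reference(stack, qc)
    ref = stack.frames[ref_idx]
    shifts = {}
    for i in qc.accepted:
        shifts[i] = 0 if i == ref_idx else estimate_axial_shift(stack.frames[i], ref, roi)
    return replace(qc, shifts=shifts, reference_frame=ref_idx)


def align_and_average(stack: BScanStack, qc: QCReport) -> AveragedBScan:
    """Shift each accepted frame by its integer correction and take the
    per-pixel mean of linear amplitudes.

    Rows that a shift moved out of the image are zero-filled and excluded
    from the mean at those rows (per-pixel valid-count normalisation), so
    edges are not biased toward zero.
    """
    if not qc.accepted:
        raise ValueError("no accepted frames to average")
    if qc.reference_frame is None:
        raise ValueError("shifts not estimated yet (run estimate_shifts)")
    acc = np.zeros_like(stack.frames[0], dtype=np.float64)
    count = np.zeros_like(acc)
    for i in qc.accepted:
        shifted, valid = _shift_frame(stack.frames[i], qc.shifts.get(i, 0))
        acc += shifted
        count += valid
    mean = np.divide(acc, count, out=np.zeros_like(acc), where=count > 0)
    return AveragedBScan(image=mean.T, axial_pitch=stack.axial_pitch, qc=qc)


def auto_roi(stack: BScanStack, depth_halfwidth: int = 40) -> CorrelationROI:
    """Automatic stand-in for the operator-selected correlation window:
    full lateral width, a depth band centred on the brightest image row
    (the specular anterior-surface reflection)."""
    mean_img = stack.frames.mean(axis=0)  # [columns, depth]
    row = int(np.argmax(mean_img.sum(axis=0)))
    lo = max(0, row - depth_halfwidth)
    hi = min(stack.n_depth, row + depth_halfwidth + 1)
    return CorrelationROI(0, mean_img.shape[0], lo, hi)
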