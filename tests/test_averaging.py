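"""Fixed-pattern removal, washout QC, axial alignment and averaging."""

import numpy as np
import pytest

import octcornea as oc
from octcornea import averaging
from octcornea.reconstruction import BScanStack

from conftest import small_config, small_phantom_params


def _stack(frames, pitch=1.0):
    frames = np.asarray(frames, dtype=float)
    return BScanStack(frames=frames, axial_pitch=pitch, depth_range=pitch * frames.shape[-1])


class TestRemoveFixedPattern:
    def test_identical_frames_become_zero(self):
        frame = np.random.default_rng(0).random((8, 16))
        stack = _stack(np.stack([frame] * 5))
        out = oc.remove_fixed_pattern(stack)
        assert np.all(out.frames == 0)

    def test_fewer_than_three_frames_rejected(self):
        with pytest.raises(ValueError, match="3 frames"):
            oc.remove_fixed_pattern(_stack(np.ones((2, 8, 16))))

    def test_static_artifact_suppressed_20db(self, capture, bscan_stack):
        """The fixed-pattern line is attenuated by ≥ 20 dB while the moving
        sample survives the median subtraction."""
        from octcornea.synthetic import unambiguous_depth_um

        z_fp = 0.35 * unambiguous_depth_um(capture.config)
        row = round(z_fp / bscan_stack.axial_pitch)
        cleaned = oc.remove_fixed_pattern(bscan_stack)
        before = bscan_stack.frames[:, :, row - 1 : row + 2].mean()
        after = cleaned.frames[:, :, row - 1 : row + 2].mean()
        assert 20 * np.log10(before / max(after, 1e-12)) >= 20

    def test_moving_features_preserved(self):
        rng = np.random.default_rng(1)
        frames = np.zeros((6, 4, 50))
        for f in range(6):
            frames[f, :, 10 + 3 * f] = 100.0  # feature moving between frames
        frames += rng.random(frames.shape)
        out = oc.remove_fixed_pattern(_stack(frames))
        for f in range(6):
            assert out.frames[f, :, 10 + 3 * f].min() > 50


class TestWashoutFilter:
    def test_all_zero_frame_discarded(self):
        frames = np.ones((5, 4, 20))
        frames[2] = 0.0
        qc = oc.washout_filter(_stack(frames), min_pixel_value=0.5, min_pixel_count=3)
        assert qc.discarded == [2]
        assert sorted(qc.accepted + qc.discarded) == list(range(5))

    def test_forced_washout_discards_every_frame(self):
        phantom = oc.make_phantom(small_phantom_params(), seed=1)
        raw = oc.simulate_capture(
            phantom, small_config(washout_probability=1.0, n_frames=10, seed=4)
        )
        stack = oc.remove_fixed_pattern(oc.reconstruct_capture(raw))
        qc = oc.washout_filter(stack)
        assert len(qc.discarded) == 10

    def test_injected_washout_frames_exactly_identified(self, capture, bscan_stack):
        cleaned = oc.remove_fixed_pattern(bscan_stack)
        qc = oc.washout_filter(cleaned)
        truth = sorted(np.flatnonzero(capture.truth.washed_out).tolist())
        assert sorted(qc.discarded) == truth

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            oc.washout_filter(_stack(np.ones((3, 4, 8))), -1.0, 5)


class TestSelectReference:
    def test_double_contrast_frame_wins(self):
        frames = np.zeros((4, 4, 20))
        frames[:, :, 5] = 1.0
        frames[2, :, 6] = 1.0  # twice the super-threshold pixels
        qc = oc.washout_filter(_stack(frames), 0.5, 1)
        assert oc.select_reference(_stack(frames), qc) == 2

    def test_tie_goes_to_lowest_index(self):
        frames = np.ones((5, 4, 20))
        qc = oc.washout_filter(_stack(frames), 0.5, 1)
        assert oc.select_reference(_stack(frames), qc) == 0

    def test_matches_bruteforce_count(self, capture, bscan_stack):
        cleaned = oc.remove_fixed_pattern(bscan_stack)
        qc = oc.washout_filter(cleaned)
        ref = oc.select_reference(cleaned, qc)
        counts = [
            (cleaned.frames[i] > qc.min_pixel_value).sum() for i in range(cleaned.n_frames)
        ]
        best = max(
            (c for c in qc.accepted), key=lambda i: (counts[i], -i)
        )
        assert ref == best

    def test_no_accepted_frames_rejected(self):
        frames = np.zeros((3, 4, 8))
        qc = oc.washout_filter(_stack(frames), 0.5, 1)
        with pytest.raises(ValueError, match="no accepted"):
            oc.select_reference(_stack(frames), qc)


def _peaky_frame(n_cols=8, n_depth=120, rows=(40, 60, 75), seed=0):
    rng = np.random.default_rng(seed)
    frame = 0.05 * rng.random((n_cols, n_depth))
    for r in rows:
        frame[:, r] = 1.0
        frame[:, r - 1] = frame[:, r + 1] = 0.5
    return frame


class TestEstimateAxialShift:
    def test_constructed_shift_recovered_with_opposite_sign(self):
        ref = _peaky_frame()
        shifted = np.roll(ref, 7, axis=1)  # features moved down by +7
        roi = averaging.CorrelationROI(0, 8, 20, 100)
        assert oc.estimate_axial_shift(shifted, ref, roi) == -7

    def test_identical_frames_give_zero(self):
        ref = _peaky_frame()
        roi = averaging.CorrelationROI(0, 8, 20, 100)
        assert oc.estimate_axial_shift(ref, ref, roi) == 0

    def test_flat_profile_rejected(self):
        flat = np.ones((8, 120))
        roi = averaging.CorrelationROI(0, 8, 20, 100)
        with pytest.raises(ValueError, match="flat"):
            oc.estimate_axial_shift(flat, flat, roi)

    def test_shift_equivariance(self):
        """Displacing the frame by an extra c pixels changes the estimated
        correction by −c."""
        ref = _peaky_frame()
        roi = averaging.CorrelationROI(0, 8, 20, 100)
        base = oc.estimate_axial_shift(np.roll(ref, 3, axis=1), ref, roi)
        moved = oc.estimate_axial_shift(np.roll(ref, 3 + 5, axis=1), ref, roi)
        assert moved == base - 5

    def test_jittered_capture_shifts_recovered(self, capture, measurement):
        """≥ 95% of accepted frames recover the injected axial jitter to the
        nearest pixel."""
        qc = measurement.averaged.qc
        pitch = measurement.averaged.axial_pitch
        ref = qc.reference_frame
        truth = np.round(
            (capture.truth.axial_shifts_um[ref] - capture.truth.axial_shifts_um) / pitch
        ).astype(int)
        hits = [qc.shifts[i] == truth[i] for i in qc.accepted]
        assert np.mean(hits) >= 0.95

    def test_roi_outside_image_rejected(self):
        ref = _peaky_frame()
        with pytest.raises(ValueError, match="bounds"):
            oc.estimate_axial_shift(ref, ref, averaging.CorrelationROI(0, 8, 20, 500))


class TestAlignAndAverage:
    def _qc(self, n, shifts=None, ref=0):
        return averaging.QCReport(
            accepted=list(range(n)), discarded=[],
            shifts=shifts or {i: 0 for i in range(n)},
            reference_frame=ref, min_pixel_value=0.0, min_pixel_count=0,
        )

    def test_identical_frames_average_to_frame(self):
        frame = np.random.default_rng(2).random((6, 40))
        stack = _stack(np.stack([frame] * 7))
        avg = oc.align_and_average(stack, self._qc(7))
        np.testing.assert_allclose(avg.image, frame.T, atol=1e-12)

    def test_idempotent_on_identical_frames(self):
        frame = np.random.default_rng(3).random((6, 40))
        avg1 = oc.align_and_average(_stack(np.stack([frame] * 5)), self._qc(5))
        avg2 = oc.align_and_average(_stack(np.stack([avg1.image.T] * 5)), self._qc(5))
        np.testing.assert_allclose(avg2.image, avg1.image, atol=1e-12)

    def test_shifted_frames_realigned(self):
        frame = _peaky_frame()
        frames = np.stack([np.roll(frame, s, axis=1) for s in (0, 4, -3)])
        qc = self._qc(3, shifts={0: 0, 1: -4, 2: 3})
        avg = oc.align_and_average(_stack(frames), qc)
        interior = slice(10, 110)
        np.testing.assert_allclose(avg.image[interior], frame.T[interior], atol=1e-12)

    def test_background_snr_grows_like_sqrt_n(self):
        """Averaging N noisy frames improves the background-limited SNR by
        √N (within 20% at N = 50)."""
        rng = np.random.default_rng(4)
        n = 50
        signal = np.zeros((8, 200))
        signal[:, 100] = 10.0
        frames = signal + np.abs(rng.standard_normal((n, 8, 200)))
        stack = _stack(frames)
        avg = oc.align_and_average(stack, self._qc(n))
        roi_sig = (slice(95, 106), slice(0, 8))
        roi_noise = (slice(10, 80), slice(0, 8))
        snr_single = oc.measure_snr(stack.frames[0].T, roi_sig, roi_noise)
        snr_avg = oc.measure_snr(avg.image, roi_sig, roi_noise)
        gain = 10 ** ((snr_avg - snr_single) / 20)
        assert gain == pytest.approx(np.sqrt(n), rel=0.20)

    def test_average_contrast_exceeds_single_frame(self, measurement):
        """Correlated averaging raises interface contrast above a single frame."""
        stack = measurement.bscans
        surf_row = int(measurement.result.surface.depth_index.mean())
        roi_sig = (slice(surf_row - 3, surf_row + 4), slice(4, 60))
        roi_noise = (slice(surf_row + 40, surf_row + 48), slice(4, 60))
        i = measurement.averaged.qc.accepted[0]
        snr_single = oc.measure_snr(stack.frames[i].T, roi_sig, roi_noise)
        snr_avg = oc.measure_snr(measurement.averaged.image, roi_sig, roi_noise)
        assert snr_avg > snr_single + 3

    def test_no_accepted_frames_rejected(self):
        qc = averaging.QCReport(
            accepted=[], discarded=[0], shifts={}, reference_frame=None,
            min_pixel_value=0.0, min_pixel_count=0,
        )
        with pytest.raises(ValueError, match="no accepted"):
            oc.align_and_average(_stack(np.ones((1, 4, 8))), qc)
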