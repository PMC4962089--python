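import numpy as np
import pytest
from skimage.draw import disk, ellipse

from rupturekit import (
    FrameStack,
    SegmentationParams,
    detect_nuclei,
    measure_regions,
    normalize_intensity,
    smooth_spatiotemporal,
)


def _single_channel_stack(frames, frame_interval=2.0):
    data = np.asarray(frames, dtype=float)[:, None]
    return FrameStack(data, frame_interval=frame_interval,
                      channel_roles={"reporter": 0})


class TestNormalizeIntensity:
    def test_recovers_per_frame_gains(self, small_scene):
        _, stack, _ = small_scene
        gains = np.linspace(1.0, 0.6, stack.n_frames)
        drifted = stack.with_data(stack.data * gains[:, None, None, None])
        restored = normalize_intensity(drifted)
        reference = normalize_intensity(stack)
        # one global factor per frame: relative structure must be identical
        assert np.allclose(restored.data, reference.data, rtol=1e-7)

    def test_constant_stack_unchanged(self):
        stack = _single_channel_stack(np.full((3, 32, 32), 7.0))
        out = normalize_intensity(stack)
        assert np.allclose(out.data, stack.data)

    def test_all_zero_frame_error_names_frame(self):
        frames = np.full((3, 16, 16), 5.0)
        frames[1] = 0.0
        with pytest.raises(ValueError, match="frame 1"):
            normalize_intensity(_single_channel_stack(frames))

    def test_channels_normalized_independently(self, small_scene):
        _, stack, _ = small_scene
        both = normalize_intensity(stack)
        solo = normalize_intensity(
            FrameStack(stack.data[:, 1:2], frame_interval=stack.frame_interval,
                       channel_roles={"reporter": 0})
        )
        assert np.allclose(both.data[:, 1], solo.data[:, 0])


class TestSmoothing:
    def test_zero_sigmas_identity(self, small_scene):
        _, stack, _ = small_scene
        out = smooth_spatiotemporal(stack, 0.0, 0.0)
        assert np.array_equal(out.data, stack.data)

    def test_constant_stack_preserved(self):
        stack = _single_channel_stack(np.full((4, 32, 32), 3.0))
        out = smooth_spatiotemporal(stack, 2.0, 4.0)
        assert np.allclose(out.data, 3.0)

    def test_impulse_response_matches_sampled_gaussian(self):
        frames = np.zeros((2, 65, 65))
        frames[:, 32, 32] = 1.0
        sigma = 3.0
        out = smooth_spatiotemporal(_single_channel_stack(frames), sigma, 0.0)
        yy, xx = np.mgrid[0:65, 0:65] - 32.0
        kernel = np.exp(-(yy**2 + xx**2) / (2 * sigma**2))
        kernel /= kernel.sum()
        assert np.allclose(out.data[0, 0], kernel, atol=1e-6)

    def test_temporal_cap_enforced(self, small_scene):
        _, stack, _ = small_scene
        with pytest.raises(ValueError, match="10"):
            smooth_spatiotemporal(stack, 1.0, 10.5)


class TestDetectNuclei:
    def test_blank_noise_frame_yields_no_detections(self):
        rng = np.random.default_rng(0)
        frames = 100.0 + rng.normal(0, 10, size=(3, 256, 256))
        stack = _single_channel_stack(np.clip(frames, 0, None))
        _, det = detect_nuclei(stack, "reporter")
        assert len(det) == 0

    def test_separated_disks_all_found_with_subpixel_centroids(self, small_scene):
        spec, stack, truth = small_scene
        labelmap, det = detect_nuclei(normalize_intensity(stack))
        truth_c = truth.centroids
        for f in (0, 20, 39):
            sub = det[det["frame"] == f]
            tc = truth_c[truth_c["frame"] == f]
            assert len(sub) == spec.n_nuclei
            d = np.hypot(
                sub["y"].to_numpy()[:, None] - tc["y"].to_numpy()[None, :],
                sub["x"].to_numpy()[:, None] - tc["x"].to_numpy()[None, :],
            )
            assert d.min(axis=1).max() <= 1.0

    def test_conditional_watershed_splits_touching_pair(self):
        img = np.full((2, 220, 220), 100.0)
        for cy, cx in ((150, 80), (150, 120)):  # overlapping by a narrow neck
            rr, cc = disk((cy, cx), 22)
            img[:, rr, cc] = 1000.0
        rr, cc = disk((50, 50), 16)  # lone reference nucleus for median area
        img[:, rr, cc] = 1000.0
        stack = _single_channel_stack(img)
        params = SegmentationParams(log_sigma=12.0, min_area=300)
        _, det = detect_nuclei(stack, "reporter", params)
        assert len(det[det["frame"] == 0]) == 3
        params_off = SegmentationParams(
            log_sigma=12.0, min_area=300, watershed_enabled=False
        )
        _, det_off = detect_nuclei(stack, "reporter", params_off)
        assert len(det_off[det_off["frame"] == 0]) == 2

    def test_min_area_monotonicity(self, small_scene):
        """Raising min-area never increases the detection count."""
        _, stack, _ = small_scene
        counts = []
        for min_area in (50, 150, 400, 800):
            _, det = detect_nuclei(
                normalize_intensity(stack),
                params=SegmentationParams(min_area=min_area),
            )
            counts.append(len(det))
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestMeasureRegions:
    @staticmethod
    def _measure_mask(mask):
        lm = np.zeros((2,) + mask.shape, dtype=np.uint16)
        lm[:, mask] = 1
        stack = FrameStack(
            np.ones((2, 1) + mask.shape), channel_roles={"reporter": 0}
        )
        return measure_regions(lm, stack).iloc[0]

    def test_disk_circularity_near_one(self):
        mask = np.zeros((128, 128), dtype=bool)
        rr, cc = disk((64, 64), 50)
        mask[rr, cc] = True
        row = self._measure_mask(mask)
        assert 0.95 <= row["circularity"] <= 1.02

    def test_square_circularity_near_pi_over_4(self):
        mask = np.zeros((100, 100), dtype=bool)
        mask[20:80, 20:80] = True
        row = self._measure_mask(mask)
        assert row["circularity"] == pytest.approx(np.pi / 4, abs=0.05)

    def test_ellipse_matches_ramanujan_oracle(self):
        mask = np.zeros((220, 220), dtype=bool)
        rr, cc = ellipse(110, 110, 40, 80)
        mask[rr, cc] = True
        a, b = 2.0, 1.0
        h = ((a - b) / (a + b)) ** 2
        perim = np.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h)))
        expected = 4 * np.pi * (np.pi * a * b) / perim**2
        row = self._measure_mask(mask)
        assert row["circularity"] == pytest.approx(expected, abs=0.01)

    def test_mean_intensities_per_channel(self, disk_stack):
        mask = disk_stack.data[0, 0] > 500
        lm = np.zeros((2, 128, 128), dtype=np.uint16)
        lm[:, mask] = 1
        det = measure_regions(lm, disk_stack)
        assert det["mean_ref"].iloc[0] == pytest.approx(1000.0)
        assert det["mean_rep"].iloc[0] == pytest.approx(1000.0)
        assert {"mean_ch0", "mean_ch1"} <= set(det.columns)

    def test_misaligned_labelmap_rejected(self, disk_stack):
        with pytest.raises(ValueError):
            measure_regions(np.zeros((3, 64, 64), dtype=np.uint16), disk_stack)
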