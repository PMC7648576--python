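"""Segmentation, ring morphology and corrected-intensity measurement."""

import numpy as np
import pytest

from asympart import (SceneParams, SegmentationConfig, background_ring,
                      generate_scene, measure_objects, render_channels,
                      segment_budneck, segment_nuclei, segment_reporter_nuclei)
from asympart.imagegen import background_surface
from asympart.segmentation import LabelMask, dilate

from conftest import brute_dilate, greedy_match


def label_mask(labels: np.ndarray) -> LabelMask:
    return LabelMask(labels=labels.astype(np.int32), channel_role="marker")


class TestSegmentNuclei:
    def test_constant_image_yields_no_objects(self):
        mask = segment_nuclei(np.full((64, 64), 7.0))
        assert mask.n_objects == 0

    def test_single_bright_disc_perfect_contrast(self):
        img = np.zeros((64, 64))
        rr, cc = np.mgrid[0:64, 0:64]
        disc = (rr - 30) ** 2 + (cc - 30) ** 2 <= 16
        img[disc] = 100.0
        mask = segment_nuclei(img)
        assert mask.n_objects == 1
        np.testing.assert_array_equal(mask.labels > 0, disc)

    def test_non_2d_input_rejected(self):
        with pytest.raises(ValueError, match="2-D"):
            segment_nuclei(np.zeros((4, 4, 4)))

    def test_recovery_on_default_scene(self, default_scene):
        scene, channels = default_scene
        mask = segment_nuclei(channels["marker"])
        truth = scene.truth_table()
        rings = background_ring(mask)
        measures = measure_objects(mask, rings, {"marker": channels["marker"]})
        found = np.array([m.centroid for m in measures])
        matches = greedy_match(truth[["row", "col"]].to_numpy(float), found,
                               max_distance=1.0)
        recall = len(matches) / len(truth)
        precision = len(matches) / max(len(found), 1)
        assert recall >= 0.95
        assert precision >= 0.95

    def test_border_objects_flagged(self):
        img = np.zeros((32, 32))
        img[0:4, 10:14] = 50.0   # touches top border
        img[15:19, 15:19] = 50.0
        mask = segment_nuclei(img, SegmentationConfig(min_area=1))
        assert mask.n_objects == 2
        assert len(mask.border_objects) == 1


class TestReporterSegmentation:
    def test_reporter_free_scene_yields_no_objects(self):
        params = SceneParams(n_cells=5, category_mixture=(0.0, 0.0, 0.0, 1.0),
                             stage_counts={"telophase": 5, "s_phase": 0, "g1": 0},
                             shot_noise=False, read_noise_sd=0.0)
        scene = generate_scene(params, seed=1)
        channels = render_channels(scene)
        assert segment_reporter_nuclei(channels["reporter"]).n_objects == 0

    def test_asymmetric_scene_detects_daughters_only(self):
        params = SceneParams(n_cells=6, category_mixture=(1.0, 0.0, 0.0, 0.0),
                             stage_counts={"telophase": 6, "s_phase": 0, "g1": 0},
                             shot_noise=False, read_noise_sd=0.0, amplitude_cv=0.0)
        scene = generate_scene(params, seed=2)
        channels = render_channels(scene)
        mask = segment_reporter_nuclei(channels["reporter"])
        assert mask.n_objects == 6
        daughters = np.array([c.daughter_center for c in scene.cells], dtype=float)
        measures = measure_objects(mask, background_ring(mask),
                                   {"reporter": channels["reporter"]})
        found = np.array([m.centroid for m in measures])
        assert len(greedy_match(daughters, found, max_distance=1.5)) == 6
        assert "caveat" in mask.notes

    def test_same_input_gives_same_mask_as_marker_mode(self, default_scene):
        _scene, channels = default_scene
        a = segment_nuclei(channels["marker"])
        b = segment_reporter_nuclei(channels["marker"])
        np.testing.assert_array_equal(a.labels, b.labels)


class TestBackgroundRing:
    def test_single_pixel_object_analytic_ring(self):
        labels = np.zeros((32, 32), dtype=np.int32)
        labels[15, 15] = 1
        rings = background_ring(label_mask(labels), inner_steps=2, outer_steps=4)
        # dilations of one pixel are 5x5 and 9x9 squares: 81 - 25 = 56 pixels
        assert rings[1].sum() == 56

    def test_corner_object_ring_clipped(self):
        labels = np.zeros((32, 32), dtype=np.int32)
        labels[0, 0] = 1
        labels[15, 15] = 2
        rings = background_ring(label_mask(labels))
        assert rings[1].sum() < rings[2].sum()

    def test_matches_bruteforce_for_two_close_nuclei(self):
        labels = np.zeros((32, 32), dtype=np.int32)
        labels[10:13, 8:11] = 1
        labels[10:13, 15:18] = 2   # 6 px apart: rings interact
        mask = label_mask(labels)
        rings = background_ring(mask, 2, 4)
        any_inner = brute_dilate(labels > 0, 2)
        for k in (1, 2):
            expected = brute_dilate(labels == k, 4) & ~any_inner
            np.testing.assert_array_equal(rings[k], expected)

    def test_matches_bruteforce_on_random_masks(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            labels = np.zeros((32, 32), dtype=np.int32)
            n_obj = rng.integers(1, 5)
            for k in range(1, n_obj + 1):
                r, c = rng.integers(2, 30, size=2)
                labels[max(r - 1, 0):r + 2, max(c - 1, 0):c + 2] = k
            mask = label_mask(labels)
            inner = int(rng.integers(0, 3))
            outer = int(rng.integers(inner + 1, 5))
            rings = background_ring(mask, inner, outer)
            any_inner = brute_dilate(labels > 0, inner)
            for k in mask.object_ids():
                if not (labels == k).any():
                    continue
                expected = brute_dilate(labels == k, outer) & ~any_inner
                np.testing.assert_array_equal(rings[k], expected)

    def test_ring_disjoint_from_all_objects(self, default_scene):
        _scene, channels = default_scene
        mask = segment_nuclei(channels["marker"])
        rings = background_ring(mask)
        all_objects = mask.labels > 0
        for ring in rings.values():
            assert not (ring & all_objects).any()

    def test_invalid_steps_rejected(self):
        labels = np.zeros((8, 8), dtype=np.int32)
        labels[4, 4] = 1
        with pytest.raises(ValueError):
            background_ring(label_mask(labels), inner_steps=4, outer_steps=4)
        with pytest.raises(ValueError):
            dilate(labels > 0, -1)


class TestMeasureObjects:
    def test_corrected_is_object_minus_ring_mean(self):
        labels = np.zeros((16, 16), dtype=np.int32)
        labels[4:6, 4:6] = 1
        img = np.full((16, 16), 40.0)
        img[labels == 1] = 100.0
        rings = background_ring(label_mask(labels), 0, 2)
        (m,) = measure_objects(label_mask(labels), rings, {"reporter": img})
        assert m.mean["reporter"] == 100.0
        assert m.ring_mean["reporter"] == 40.0
        assert m.corrected["reporter"] == 60.0

    def test_uniform_image_corrected_zero(self):
        labels = np.zeros((16, 16), dtype=np.int32)
        labels[8:10, 8:10] = 1
        rings = background_ring(label_mask(labels))
        (m,) = measure_objects(label_mask(labels), rings,
                               {"reporter": np.full((16, 16), 3.5)})
        assert m.corrected["reporter"] == 0.0

    def test_corrected_plus_ring_equals_mean_exactly(self, default_scene):
        _scene, channels = default_scene
        mask = segment_nuclei(channels["marker"])
        rings = background_ring(mask)
        for m in measure_objects(mask, rings, {"marker": channels["marker"],
                                               "reporter": channels["reporter"]}):
            for ch in m.mean:
                assert m.corrected[ch] == m.mean[ch] - m.ring_mean[ch]

    def test_corrected_recovers_amplitude_over_gradient(self):
        # unblurred noise-free discs (amplitude 80) on a sloped background
        params = SceneParams(n_cells=2, psf_sigma=0.0, shot_noise=False,
                             read_noise_sd=0.0,
                             category_mixture=(0.0, 0.0, 1.0, 0.0),
                             stage_counts={"telophase": 2, "s_phase": 0, "g1": 0},
                             amplitude_cv=0.0, reporter_amplitude=80.0)
        scene = generate_scene(params, seed=5)
        channels = render_channels(scene)
        mask = segment_nuclei(channels["marker"])
        rings = background_ring(mask)
        measures = measure_objects(mask, rings, {"reporter": channels["reporter"]})
        nuclei = [m for m in measures if not m.on_border]  # downstream default
        assert len(nuclei) == 4
        for m in nuclei:
            assert m.corrected["reporter"] == pytest.approx(80.0, rel=0.02)

    def test_empty_ring_flags_undefined_background(self):
        labels = np.zeros((8, 8), dtype=np.int32)
        labels[3:5, 3:5] = 1
        (m,) = measure_objects(label_mask(labels), {},
                               {"reporter": np.ones((8, 8))})
        assert m.background_undefined
        assert np.isnan(m.corrected["reporter"])

    def test_shape_mismatch_rejected(self):
        labels = np.zeros((8, 8), dtype=np.int32)
        with pytest.raises(ValueError, match="shape"):
            measure_objects(label_mask(labels), {}, {"reporter": np.ones((9, 9))})


class TestBudneck:
    def test_blank_channel_yields_no_objects(self):
        assert segment_budneck(np.zeros((64, 64))).n_objects == 0

    def test_budneck_centers_recovered(self):
        params = SceneParams(n_cells=5, budneck_fraction=1.0,
                             stage_counts={"telophase": 5, "s_phase": 0, "g1": 0},
                             shot_noise=False, read_noise_sd=0.0)
        scene = generate_scene(params, seed=8)
        channels = render_channels(scene)
        mask = segment_budneck(channels["budneck"])
        assert mask.n_objects == 5
        measures = measure_objects(mask, {}, {"budneck": channels["budneck"]})
        truth = np.array([c.budneck_center for c in scene.cells], dtype=float)
        found = np.array([m.centroid for m in measures])
        assert len(greedy_match(truth, found, max_distance=2.0)) == 5

    def test_oversized_object_rejected_by_area_band(self):
        img = np.zeros((64, 64))
        rr, cc = np.mgrid[0:64, 0:64]
        img[(rr - 30) ** 2 + (cc - 30) ** 2 <= 25] = 100.0  # 81 px: a whole nucleus
        assert segment_budneck(img).n_objects == 0
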