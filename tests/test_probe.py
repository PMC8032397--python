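"""Encoder probes: firing thresholds, invariance, selectivity, occlusion."""

import numpy as np
import pytest

from cemcurate import (
    SynthConfig,
    apply_distortion,
    firing_thresholds,
    iou,
    make_informative_patch,
    make_toy_encoder,
    mean_firing_rate_curve,
    occlusion_map,
    point_biserial,
    select_Z,
    selectivity_map,
)


class ConstantEncoder:
    def __init__(self, value):
        self.value = value
    def pooled(self, image):
        return np.array([self.value], dtype=float)
    def feature_maps(self, image):
        return np.full((1, 112, 112), self.value)


class VectorEncoder:
    """Maps each image to a preassigned response vector (by id)."""
    def __init__(self, table):
        self.table = table
    def pooled(self, image):
        return np.asarray(self.table[int(image[0, 0])], dtype=float)


class FlatEncoder:
    """Identity on the flattened image; dot products count shared mass."""
    def pooled(self, image):
        return np.asarray(image, dtype=float).ravel()
    def feature_maps(self, image):
        return np.asarray(image, dtype=float)[None]


@pytest.fixture(scope="module")
def probe_images():
    cfg = SynthConfig()
    return [make_informative_patch(cfg, 100 + i)[0] for i in range(20)]


class TestFiringThresholds:
    def test_constant_encoders(self):
        assert firing_thresholds(ConstantEncoder(1.0), 100, seed=0)[0] == 1.0
        assert firing_thresholds(ConstantEncoder(0.0), 100, seed=0)[0] == 0.0

    def test_global_mean_concentrates(self):
        enc = make_toy_encoder("global_mean")
        th = firing_thresholds(enc, n_noise=1000, seed=1)
        assert abs(th[0] - 127.5) <= 1.0

    def test_too_few_noise_images(self):
        with pytest.raises(ValueError):
            firing_thresholds(ConstantEncoder(1.0), n_noise=99, seed=0)


class TestSelectZ:
    def test_top_decile_size(self):
        # 100 fake images with distinct single-neuron responses
        table = {i: [float(i)] for i in range(100)}
        imgs = [np.full((2, 2), i, dtype=np.uint8) for i in range(100)]
        Z, sel = select_Z(VectorEncoder(table), imgs, np.array([0.0]))
        assert Z.shape == (1, 10)
        assert set(Z[0]) == set(range(90, 100))
        assert sel[0]

    def test_dead_neuron_excluded(self):
        table = {i: [0.0] for i in range(20)}
        imgs = [np.full((2, 2), i, dtype=np.uint8) for i in range(20)]
        _, sel = select_Z(VectorEncoder(table), imgs, np.array([0.5]))
        assert not sel[0]

    def test_tied_responses_resolved_by_index(self):
        table = {i: [7.0] for i in range(20)}
        imgs = [np.full((2, 2), i, dtype=np.uint8) for i in range(20)]
        Z, sel = select_Z(VectorEncoder(table), imgs, np.array([1.0]))
        assert set(Z[0]) == set(range(2))  # top ceil(0.1*20) by index
        assert sel[0]

    def test_empty_probe_set(self):
        with pytest.raises(ValueError):
            select_Z(ConstantEncoder(1.0), [], np.array([0.0]))


class TestApplyDistortion:
    @pytest.mark.parametrize("transform,identity", [
        ("rotation", 0), ("blur", 0), ("noise", 0),
        ("brightness", 1), ("contrast", 1), ("scale", 1),
    ])
    def test_identity_levels(self, transform, identity, probe_images):
        img = probe_images[0]
        out = apply_distortion(img, transform, identity)
        np.testing.assert_array_equal(out, img)

    @pytest.mark.parametrize("angle", [90, 180, 270])
    def test_quarter_rotations_are_permutations(self, angle, probe_images):
        img = probe_images[0]
        out = apply_distortion(img, "rotation", angle)
        expect = np.rot90(img, k=angle // 90)
        np.testing.assert_array_equal(out, expect)

    def test_full_rotation_near_identity(self, probe_images):
        img = probe_images[0].astype(float)
        out = apply_distortion(img, "rotation", 360.0)
        assert np.abs(out - img).max() < 1e-6

    def test_brightness_scales(self):
        img = np.full((8, 8), 100, dtype=np.uint8)
        assert (apply_distortion(img, "brightness", 0.5) == 50).all()
        assert (apply_distortion(img, "brightness", 3.0) == 255).all()  # clipped

    def test_contrast_preserves_mean(self, probe_images):
        img = probe_images[0].astype(float)
        out = apply_distortion(img, "contrast", 0.5)
        assert out.mean() == pytest.approx(img.mean(), rel=1e-6)

    def test_noise_seeded(self, probe_images):
        img = probe_images[0]
        a = apply_distortion(img, "noise", 10,
                             rng=np.random.default_rng(3))
        b = apply_distortion(img, "noise", 10,
                             rng=np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, img)

    def test_scale_preserves_shape(self, probe_images):
        img = probe_images[0]
        for f in (0.5, 2.0):
            assert apply_distortion(img, "scale", f).shape == img.shape

    def test_unknown_transform(self):
        with pytest.raises(ValueError):
            apply_distortion(np.zeros((4, 4)), "shear", 1.0)


class TestMeanFiringRate:
    def test_identity_rate_exactly_one(self, probe_images):
        enc = make_toy_encoder("global_mean")
        th = firing_thresholds(enc, 1000, seed=1)
        curve = mean_firing_rate_curve(enc, probe_images, "blur", [0.0, 3.0],
                                       th, seed=2)
        assert curve.mean_firing_rate[0] == 1.0

    def test_global_mean_invariant_to_quarter_rotations(self, probe_images):
        enc = make_toy_encoder("global_mean")
        th = firing_thresholds(enc, 1000, seed=1)
        curve = mean_firing_rate_curve(enc, probe_images, "rotation",
                                       [0, 90, 180, 270], th, seed=2)
        np.testing.assert_array_equal(curve.mean_firing_rate, [1, 1, 1, 1])

    def test_corner_encoder_drops_at_180(self, probe_images):
        imgs = [im.copy() for im in probe_images]
        for im in imgs[:5]:
            im[:3, :3] = 255  # corner landmarks
        enc = make_toy_encoder("corner_pixel")
        th = firing_thresholds(enc, 1000, seed=1)
        curve = mean_firing_rate_curve(enc, imgs, "rotation", [0, 180],
                                       th, seed=2)
        assert curve.mean_firing_rate[0] == 1.0
        assert curve.mean_firing_rate[1] < curve.mean_firing_rate[0]

    def test_no_selective_neurons_diagnostic(self, probe_images):
        enc = make_toy_encoder("corner_pixel")
        # threshold above any reachable response
        with pytest.raises(ValueError, match="selective"):
            mean_firing_rate_curve(enc, probe_images, "blur", [0.0],
                                   np.array([1e9]), seed=0)


class TestPointBiserial:
    def test_known_example(self):
        r = point_biserial(np.array([1.0, 2, 3, 4]), np.array([0, 0, 1, 1]))
        assert r == pytest.approx(0.8944, abs=1e-4)

    def test_map_equal_to_mask(self):
        m = np.array([[0, 1], [1, 0]])
        assert point_biserial(m.astype(float), m) == pytest.approx(1.0)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            point_biserial(np.ones(4), np.array([1, 1, 1, 1]))
        with pytest.raises(ValueError):
            point_biserial(np.ones(4), np.array([0, 1, 0, 1]))

    def test_equals_pearson_oracle_fuzz(self, rng):
        from scipy.stats import pearsonr
        for _ in range(100):
            n = int(rng.integers(5, 200))
            mask = rng.integers(0, 2, size=n)
            if mask.min() == mask.max():
                mask[0] = 1 - mask[0]
            x = rng.normal(size=n)
            assert point_biserial(x, mask) == pytest.approx(
                pearsonr(x, mask).statistic, abs=1e-10)


class TestIoU:
    def test_identical(self):
        m = np.array([[1, 0], [0, 1]], dtype=bool)
        assert iou(m, m) == 1.0

    def test_disjoint(self):
        a = np.array([1, 0, 0, 0], dtype=bool)
        b = np.array([0, 1, 0, 0], dtype=bool)
        assert iou(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros(8, dtype=bool); a[:2] = True
        b = np.zeros(8, dtype=bool); b[:4] = True
        assert iou(a, b) == 0.5

    def test_both_empty(self):
        z = np.zeros((3, 3), dtype=bool)
        assert iou(z, z) == 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            iou(np.zeros(3, bool), np.zeros(4, bool))


class TestSelectivityMap:
    def test_planted_channel_recovered(self):
        cfg = SynthConfig()
        img, masks = make_informative_patch(cfg, 200)
        enc = make_toy_encoder("planted_filter", seed=0)
        res = selectivity_map(enc, img, masks["organelle"], k=1)
        assert res.top_channels[0] == enc.planted_channel
        assert res.iou_vs_truth >= 0.9
        assert res.heatmap.min() >= 0.0 and res.heatmap.max() <= 1.0

    def test_full_mask_rejected(self):
        enc = make_toy_encoder("planted_filter", seed=0)
        img = np.zeros((224, 224), dtype=np.uint8)
        with pytest.raises(ValueError):
            selectivity_map(enc, img, np.ones((224, 224), dtype=bool))

    def test_k_equals_C_boundary(self, probe_images):
        img, masks = make_informative_patch(SynthConfig(), 201)
        enc = make_toy_encoder("random_conv", seed=1)
        res = selectivity_map(enc, img, masks["organelle"], k=8)
        assert len(res.top_channels) == 8

    def test_k_too_large(self):
        img, masks = make_informative_patch(SynthConfig(), 202)
        enc = make_toy_encoder("random_conv", seed=1)
        with pytest.raises(ValueError):
            selectivity_map(enc, img, masks["organelle"], k=9)


class TestOcclusionMap:
    def test_grid_shape_follows_floor_formula(self):
        img = np.zeros((224, 224), dtype=np.uint8)
        img[0, 0] = 1  # avoid a fully degenerate grid
        res = occlusion_map(FlatEncoder(), img, img, window=61, stride=30)
        assert res.grid.shape == (6, 6)

    def test_bright_blob_window_has_peak_importance(self):
        img = np.zeros((224, 224), dtype=np.uint8)
        img[65:95, 65:95] = 255  # fully inside window (2, 2): rows 60..120
        res = occlusion_map(FlatEncoder(), img, img)
        assert np.unravel_index(res.grid.argmax(), res.grid.shape) == (2, 2)
        assert res.grid.max() == 1.0

    def test_zero_window_zero_importance(self):
        img = np.zeros((224, 224), dtype=np.uint8)
        img[200:220, 200:220] = 255
        res = occlusion_map(FlatEncoder(), img, img)
        # window (0,0) is already all zeros: occluding changes nothing
        assert res.grid[0, 0] == 0.0

    def test_heatmap_bounds(self, probe_images):
        enc = make_toy_encoder("random_conv", seed=0)
        res = occlusion_map(enc, probe_images[0], probe_images[1])
        assert res.heatmap.min() >= 0.0 and res.heatmap.max() <= 1.0

    def test_errors(self):
        img = np.zeros((224, 224), dtype=np.uint8)
        with pytest.raises(ValueError):
            occlusion_map(FlatEncoder(), img, np.zeros((100, 100), np.uint8))
        with pytest.raises(ValueError):
            occlusion_map(FlatEncoder(), img, img, window=300)
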