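"""Standardization: intensity mapping, plane planning, tiling, sampling."""

import numpy as np
import pytest

from cemcurate import (
    SourceImage,
    downsample_to_budget,
    normalize_to_uint8,
    plan_planes,
    sample_random_patches,
    slice_volume,
    standardize_source,
    tile_image,
)
from cemcurate.types import MIN_KEEP, PATCH_SIZE, SlicePlan


def brute_force_tiles(h, w, size=PATCH_SIZE, min_keep=MIN_KEEP):
    """Independent enumeration of expected (y0, x0) crop offsets.

    Grid windows at multiples of `size`; a remainder strip of width in
    [min_keep, size) adds an edge-anchored window at dim-size; whole axes
    in [min_keep, size) give a single padded window at 0; axes below
    min_keep kill the image.
    """
    def axis(dim):
        if dim < min_keep:
            return None
        if dim < size:
            return [0]
        offs = [i * size for i in range(dim // size)]
        if dim - (dim // size) * size >= min_keep:
            offs.append(dim - size)
        return offs
    ys, xs = axis(h), axis(w)
    if ys is None or xs is None:
        return set()
    return {(y, x) for y in ys for x in xs}


class TestNormalizeToUint8:
    def test_uint8_passthrough(self):
        img = np.array([[0, 128, 255]], dtype=np.uint8)
        assert normalize_to_uint8(img) is img

    def test_constant_maps_to_zero(self):
        img = np.full((4, 4), 500, dtype=np.uint16)
        assert (normalize_to_uint8(img) == 0).all()

    def test_affine_16bit(self):
        img = np.array([0, 32768, 65535], dtype=np.uint16)
        np.testing.assert_array_equal(normalize_to_uint8(img), [0, 127, 255])

    def test_matches_closed_form_floor(self, rng):
        vals = rng.integers(0, 65536, size=(30, 30)).astype(np.uint16)
        out = normalize_to_uint8(vals)
        v = vals.astype(float)
        expect = np.floor(255.0 * (v - v.min()) / (v.max() - v.min()))
        expect[vals == vals.max()] = 255
        np.testing.assert_array_equal(out, expect.astype(np.uint8))

    def test_idempotent(self, rng):
        img = rng.normal(0, 100, size=(16, 16))
        once = normalize_to_uint8(img)
        np.testing.assert_array_equal(normalize_to_uint8(once), once)

    def test_nonfinite_names_source(self):
        img = np.array([[1.0, np.nan]])
        with pytest.raises(ValueError, match="vol7"):
            normalize_to_uint8(img, source_id="vol7")


class TestPlanPlanes:
    @pytest.mark.parametrize("spacing,planes", [
        ((10, 10, 10), ("xy", "xz", "yz")),   # isotropic
        ((24, 20, 20), ("xy",)),              # deviation exactly 20%: strict <
        ((23, 20, 20), ("xy", "xz", "yz")),   # deviation 15%
        ((50, 10, 10), ("xy",)),              # grossly anisotropic
        (None, ("xy",)),                      # unknown spacing
    ])
    def test_anisotropy_rule(self, spacing, planes):
        assert plan_planes(spacing).planes == planes

    def test_nonpositive_spacing_rejected(self):
        with pytest.raises(ValueError):
            plan_planes((0, 10, 10))


class TestDownsampleToBudget:
    def test_under_budget_untouched(self):
        vol = np.zeros((100, 100, 100), dtype=np.uint8)
        out, factors = downsample_to_budget(vol, 10**9)
        assert out is vol or out.shape == vol.shape
        assert factors == (1, 1, 1)

    def test_smallest_passing_factor(self):
        vol = np.zeros((200, 200, 200), dtype=np.uint8)  # 8e6 bytes
        out, factors = downsample_to_budget(vol, 10**6)
        assert factors == (2, 2, 2)
        assert out.nbytes == 10**6

    def test_budget_boundary_inclusive(self):
        vol = np.zeros((50, 40, 30), dtype=np.uint8)
        out, factors = downsample_to_budget(vol, vol.nbytes)
        assert factors == (1, 1, 1)

    def test_bad_budget(self):
        with pytest.raises(ValueError):
            downsample_to_budget(np.zeros((2, 2, 2)), 0)


class TestSliceVolume:
    def test_xy_only(self):
        vol = np.arange(3 * 4 * 5).reshape(3, 4, 5)
        secs = list(slice_volume(vol, SlicePlan(planes=("xy",))))
        assert len(secs) == 3
        np.testing.assert_array_equal(secs[1][2], vol[1])

    def test_three_plane_count(self):
        vol = np.zeros((3, 4, 5))
        secs = list(slice_volume(vol, SlicePlan(planes=("xy", "xz", "yz"))))
        assert len(secs) == 3 + 4 + 5
        counts = {p: sum(1 for s in secs if s[0] == p) for p in ("xy", "xz", "yz")}
        assert counts == {"xy": 3, "xz": 4, "yz": 5}

    def test_single_slice(self):
        vol = np.arange(20).reshape(1, 4, 5)
        (plane, idx, sec), = slice_volume(vol, SlicePlan(planes=("xy",)))
        np.testing.assert_array_equal(sec, vol[0])


class TestTileImage:
    @pytest.mark.parametrize("shape,n,n_flagged", [
        ((448, 448), 4, 0),   # exact multiple
        ((448, 600), 6, 2),   # remainder 152 >= 112: edge-anchored column
        ((448, 559), 4, 0),   # remainder 111 < 112 discarded
        ((150, 150), 1, 0),   # reflect-padded whole image
        ((100, 100), 0, 0),   # too small entirely
    ])
    def test_counts(self, shape, n, n_flagged):
        tiles = list(tile_image(np.zeros(shape, dtype=np.uint8)))
        assert len(tiles) == n
        assert sum(t[3]["edge_anchored"] for t in tiles) == n_flagged

    def test_padded_flag_and_shape(self):
        tiles = list(tile_image(np.zeros((150, 300), dtype=np.uint8)))
        assert all(t[2].shape == (PATCH_SIZE, PATCH_SIZE) for t in tiles)
        assert all(t[3]["padded"] for t in tiles)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(300):
            h, w = rng.integers(50, 1001, size=2)
            got = {(y, x) for y, x, _, _ in
                   tile_image(np.zeros((h, w), dtype=np.uint8))}
            assert got == brute_force_tiles(h, w), (h, w)

    def test_rejects_non_2d(self):
        with pytest.raises(ValueError):
            list(tile_image(np.zeros((4, 4, 4), dtype=np.uint8)))


class TestSampleRandomPatches:
    def test_empty_request(self):
        vol = np.zeros((3, 300, 300), dtype=np.uint8)
        assert sample_random_patches(vol, n=0, seed=1) == []

    def test_deterministic(self):
        vol = (np.arange(5 * 300 * 300) % 251).reshape(5, 300, 300).astype(np.uint8)
        a = sample_random_patches(vol, n=20, seed=9)
        b = sample_random_patches(vol, n=20, seed=9)
        assert [p.record.to_dict() for p in a] == [p.record.to_dict() for p in b]
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.image, pb.image)

    def test_offsets_within_bounds(self):
        vol = np.zeros((10, 448, 448), dtype=np.uint8)
        patches = sample_random_patches(vol, n=500, seed=42)
        assert all(0 <= p.record.y0 <= 224 for p in patches)
        assert all(0 <= p.record.x0 <= 224 for p in patches)
        assert all(0 <= p.record.slice_index <= 9 for p in patches)

    def test_too_small_volume(self):
        with pytest.raises(ValueError):
            sample_random_patches(np.zeros((3, 50, 50), dtype=np.uint8), n=1, seed=0)


class TestStandardizeSource:
    def test_2d_composition(self):
        src = SourceImage("img1", np.zeros((448, 448), dtype=np.uint8))
        patches = list(standardize_source(src))
        assert len(patches) == 4
        assert all(p.record.plane == "xy" and p.record.slice_index == 0
                   for p in patches)

    def test_isotropic_volume_counts(self, rng):
        vol = rng.integers(0, 256, size=(8, 300, 448)).astype(np.uint8)
        src = SourceImage("vol1", vol, spacing_nm=(10, 10, 10))
        patches = list(standardize_source(src))
        # xy: 8 slices of 300x448 -> 1 row x 2 cols each (remainders 76/0 < 112)
        n_xy = sum(p.record.plane == "xy" for p in patches)
        assert n_xy == 8 * 2
        # xz sections are 8x448: below 112 rows, nothing; yz 8x300 likewise
        assert sum(p.record.plane != "xy" for p in patches) == 0

    def test_anisotropic_volume_xy_only(self, rng):
        vol = rng.integers(0, 256, size=(4, 224, 224)).astype(np.uint8)
        src = SourceImage("vol2", vol, spacing_nm=(50, 10, 10))
        planes = {p.record.plane for p in standardize_source(src)}
        assert planes == {"xy"}

    def test_all_patches_uniform_shape_dtype(self, rng):
        vol = rng.integers(0, 1000, size=(3, 500, 250)).astype(np.uint16)
        src = SourceImage("vol3", vol, spacing_nm=(10, 10, 10))
        for p in standardize_source(src):
            assert p.image.shape == (PATCH_SIZE, PATCH_SIZE)
            assert p.image.dtype == np.uint8

    def test_provenance_ids_unique(self, rng):
        vol = rng.integers(0, 256, size=(3, 448, 448)).astype(np.uint8)
        src = SourceImage("vol4", vol, spacing_nm=(10, 10, 10))
        ids = [p.record.patch_id for p in standardize_source(src)]
        assert len(ids) == len(set(ids))

    def test_polarity_inversion(self):
        img = np.zeros((224, 224), dtype=np.uint8)
        img[0, 0] = 200
        src = SourceImage("inv1", img, inverted=True)
        (patch,), = [list(standardize_source(src, unify_polarity=True))]
        assert patch.image[0, 0] == 55
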