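"""Tissue masking, tiling, stain normalization, standardization, augmentation."""

import numpy as np
import pytest

from pathomil.core import DegenerateHistogramError, RGBPatch, StainEstimationError
from pathomil import preprocess as pp


def brute_force_otsu(gray):
    """Exhaustive between-class-variance maximizer over all 256 split levels.

    Uses exact rational arithmetic so plateau ties are compared without
    floating-point noise: sigma_b^2(t) = w0*w1*(mu0-mu1)^2 with class
    weights/means taken over {< t} and {>= t}.
    """
    from fractions import Fraction

    hist = np.bincount(gray.ravel(), minlength=256)
    best_t, best_v = None, Fraction(-1)
    for t in range(1, 256):
        n0 = int(hist[:t].sum())
        n1 = int(hist[t:].sum())
        if n0 == 0 or n1 == 0:
            continue
        s0 = int((hist[:t] * np.arange(t)).sum())
        s1 = int((hist[t:] * np.arange(t, 256)).sum())
        mu0 = Fraction(s0, n0)
        mu1 = Fraction(s1, n1)
        v = Fraction(n0, 1) * n1 * (mu0 - mu1) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return best_t


class TestTissueMask:
    def test_half_black_half_white_masks_black_half(self):
        img = np.full((64, 64, 3), 255, dtype=np.uint8)
        img[:, :32] = 0
        mask = pp.compute_tissue_mask(img)
        assert mask.mask[:, :32].all()
        assert not mask.mask[:, 32:].any()

    def test_constant_image_raises(self):
        img = np.full((32, 32, 3), 255, dtype=np.uint8)
        with pytest.raises(DegenerateHistogramError):
            pp.compute_tissue_mask(img)

    def test_threshold_matches_exhaustive_scan_on_random_images(self, rng):
        for _ in range(50):
            lo, hi = sorted(rng.integers(0, 256, size=2))
            if hi - lo < 30:
                hi = min(255, lo + 40)
            img = np.where(rng.random((48, 48)) < 0.5, lo, hi).astype(np.uint8)
            img = np.clip(img + rng.integers(-8, 9, size=img.shape), 0, 255).astype(np.uint8)
            if np.unique(img).size < 2:
                continue
            assert pp.otsu_threshold(img) == brute_force_otsu(img)

    def test_downsample_shrinks_mask(self, rng):
        img = rng.integers(0, 256, size=(64, 64, 3)).astype(np.uint8)
        mask = pp.compute_tissue_mask(img, downsample=4)
        assert mask.mask.shape == (16, 16)


class TestTiling:
    def _all_tissue_mask(self, shape):
        return pp.TissueMask(mask=np.ones(shape, dtype=bool), otsu_threshold=128, downsample=1)

    def test_exact_partition_of_1024(self, rng):
        img = rng.integers(0, 255, size=(1024, 1024, 3)).astype(np.uint8)
        tiles = pp.tile_slide(img, self._all_tissue_mask((1024, 1024)), tile_size=512,
                              min_tissue_fraction=0.0)
        origins = {t.origin_xy for t in tiles}
        assert origins == {(0, 0), (512, 0), (0, 512), (512, 512)}

    def test_partial_edge_tiles_dropped(self, rng):
        img = rng.integers(0, 255, size=(700, 700, 3)).astype(np.uint8)
        tiles = pp.tile_slide(img, self._all_tissue_mask((700, 700)), tile_size=512,
                              min_tissue_fraction=0.0)
        assert len(tiles) == 1 and tiles[0].origin_xy == (0, 0)

    def test_tiles_disjoint_and_inside(self, rng):
        img = rng.integers(0, 255, size=(300, 260, 3)).astype(np.uint8)
        tiles = pp.tile_slide(img, self._all_tissue_mask((300, 260)), tile_size=64,
                              min_tissue_fraction=0.0)
        boxes = [(t.origin_xy[0], t.origin_xy[1]) for t in tiles]
        assert len(set(boxes)) == len(boxes)
        for t in tiles:
            x, y = t.origin_xy
            assert x + 64 <= 260 and y + 64 <= 300
        assert len(tiles) * 64 * 64 <= 300 * 260

    def test_tissue_fraction_filter_by_enumeration(self):
        # checkerboard mask at tile granularity 2x2 -> every tile 25% tissue
        mask2d = np.zeros((128, 128), dtype=bool)
        for r in range(0, 128, 2):
            for c in range(0, 128, 2):
                mask2d[r, c] = True
        img = np.zeros((128, 128, 3), dtype=np.uint8)
        mask = pp.TissueMask(mask=mask2d, otsu_threshold=128, downsample=1)
        tiles = pp.tile_slide(img, mask, tile_size=32, min_tissue_fraction=0.5)
        assert len(tiles) == 0
        # by direct enumeration every candidate tile has fraction 0.25
        assert all(abs(v - 0.25) < 1e-12 for v in mask.tissue_fraction_per_tile.values())

    def test_too_small_image_warns_and_returns_empty(self, rng):
        img = rng.integers(0, 255, size=(40, 40, 3)).astype(np.uint8)
        with pytest.warns(UserWarning):
            tiles = pp.tile_slide(img, self._all_tissue_mask((40, 40)), tile_size=64)
        assert tiles == []


class TestMacenko:
    def test_self_normalization_is_fixed_point(self, he_like_patch):
        ref = pp.estimate_stain_reference(he_like_patch)
        out = pp.macenko_normalize(he_like_patch, ref)
        delta = np.abs(out.pixels.astype(float).mean(axis=(0, 1))
                       - he_like_patch.pixels.astype(float).mean(axis=(0, 1)))
        assert (delta < 2.0).all()
        ref2 = pp.estimate_stain_reference(out)
        cos = np.abs((ref.stain_vectors * ref2.stain_vectors).sum(axis=0))
        angles = np.degrees(np.arccos(np.clip(cos, -1, 1)))
        assert (angles < 1.0).all()

    def test_pure_white_patch_raises(self):
        white = RGBPatch("w", 0, 0, (0, 0), np.full((64, 64, 3), 250, dtype=np.uint8))
        with pytest.raises(StainEstimationError):
            pp.estimate_stain_reference(white)
        ref = pp.StainReference(
            stain_vectors=np.array([[0.65, 0.07], [0.70, 0.99], [0.29, 0.11]])
            / np.linalg.norm([[0.65, 0.07], [0.70, 0.99], [0.29, 0.11]], axis=0),
            max_concentrations=np.array([1.0, 1.0]))
        with pytest.raises(StainEstimationError):
            pp.macenko_normalize(white, ref)

    def test_recovers_known_two_dye_basis(self, rng):
        # synthesize pixels from a known OD basis; the Macenko assumption
        # needs near-pure pixels of each dye, so include some of each
        basis = np.array([[0.65, 0.07], [0.70, 0.99], [0.29, 0.11]])
        basis = basis / np.linalg.norm(basis, axis=0)
        n = 96 * 96
        conc = rng.uniform(0.3, 1.4, size=(2, n))
        pure = rng.integers(0, 3, size=n)
        conc[0, pure == 0] *= 0.01  # nearly pure dye 2
        conc[1, pure == 1] *= 0.01  # nearly pure dye 1
        od = basis @ conc
        pixels = np.rint(255.0 * 10.0 ** (-od.T)).clip(0, 255).astype(np.uint8)
        patch = RGBPatch("syn", 0, 0, (0, 0), pixels.reshape(96, 96, 3))
        ref = pp.estimate_stain_reference(patch)
        cos = np.abs((ref.stain_vectors * basis).sum(axis=0))
        angles = np.degrees(np.arccos(np.clip(cos, -1, 1)))
        assert (angles < 3.0).all()


class TestZScore:
    def test_standardizes_channels(self, rng):
        px = rng.integers(0, 255, size=(64, 64, 3)).astype(np.uint8)
        out = pp.zscore_patch(px)
        assert np.abs(out.values.mean(axis=(0, 1))).max() < 1e-6
        assert np.abs(out.values.std(axis=(0, 1)) - 1.0).max() < 1e-6
        assert out.degenerate_channels == ()

    def test_constant_channel_flagged_and_zeroed(self, rng):
        px = rng.integers(0, 255, size=(32, 32, 3)).astype(np.uint8)
        px[:, :, 1] = 77
        out = pp.zscore_patch(px)
        assert out.degenerate_channels == (1,)
        assert (out.values[:, :, 1] == 0).all()

    def test_invariant_under_channel_affine_maps(self, rng):
        px = rng.integers(30, 200, size=(32, 32, 3)).astype(float)
        out1 = pp.zscore_patch(px.astype(np.uint8))
        transformed = px * np.array([0.5, 1.1, 0.9]) + np.array([10.0, -5.0, 3.0])
        out2 = pp.zscore_patch(np.clip(transformed, 0, 255))
        # affine maps with positive scale leave z-scores unchanged
        assert np.allclose(pp.zscore_patch(px * 0.5 + 10.0).values, pp.zscore_patch(px).values)


class TestAugment:
    def _patch(self, rng):
        px = rng.integers(0, 255, size=(64, 64, 3)).astype(np.uint8)
        return RGBPatch("a", 0, 0, (0, 0), px)

    def test_all_disabled_is_identity(self, rng):
        p = self._patch(rng)
        out = pp.augment_patch(p, pp.AugmentConfig())
        assert np.array_equal(out.pixels, p.pixels)

    def test_hflip_is_involution(self, rng):
        p = self._patch(rng)
        cfg = pp.AugmentConfig(hflip=True)
        twice = pp.augment_patch(pp.augment_patch(p, cfg), cfg)
        assert np.array_equal(twice.pixels, p.pixels)

    def test_same_seed_bit_identical(self, rng):
        p = self._patch(rng)
        cfg = pp.AugmentConfig(hflip=True, blur=True, color_jitter=True, sprinkle=True, seed=7)
        a = pp.augment_patch(p, cfg)
        b = pp.augment_patch(p, cfg)
        assert np.array_equal(a.pixels, b.pixels)

    def test_sprinkle_occludes_target_fraction(self, rng):
        size = 256
        px = np.zeros((size, size, 3), dtype=np.uint8)
        p = RGBPatch("a", 0, 0, (0, 0), px)
        cfg = pp.AugmentConfig(sprinkle=True, sprinkle_fraction=0.1, seed=3)
        out = pp.augment_patch(p, cfg)
        frac = (out.pixels[:, :, 0] == 127).mean()
        assert abs(frac - 0.1) <= 0.02

    def test_progress_scales_occlusion(self):
        px = np.zeros((256, 256, 3), dtype=np.uint8)
        p = RGBPatch("a", 0, 0, (0, 0), px)
        f_half = (pp.augment_patch(p, pp.AugmentConfig(sprinkle=True, sprinkle_fraction=0.2,
                                                       progress=0.5, seed=3)).pixels[:, :, 0] == 127).mean()
        f_full = (pp.augment_patch(p, pp.AugmentConfig(sprinkle=True, sprinkle_fraction=0.2,
                                                       progress=1.0, seed=3)).pixels[:, :, 0] == 127).mean()
        assert f_half < f_full
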