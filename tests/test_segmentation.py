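"""Board segmentation: thresholding, morphology, ROI logic, tiling, sides."""

import numpy as np
import pytest

from fruitmorph import fixtures, segmentation as seg
from _oracles import LUMA, brute_force_otsu


def _gray_rgb(gray2d):
    return np.stack([gray2d] * 3, axis=2).astype(np.uint8)


class TestBinarize:
    def test_mean_threshold_on_two_level_image(self):
        img = np.zeros((40, 40), dtype=np.uint8)
        img[:, 20:] = 200
        mask = seg.binarize(_gray_rgb(img), "mean", blur_size=1)
        assert np.array_equal(mask, img == 200)

    def test_otsu_matches_exhaustive_search_oracle(self):
        rng = np.random.default_rng(0)
        gray = (
            np.concatenate([rng.normal(50, 10, 5000), rng.normal(180, 12, 5000)])
            .clip(0, 255)
            .astype(np.uint8)
            .reshape(100, 100)
        )
        img = _gray_rgb(gray)
        mask = seg.binarize(img, "otsu", blur_size=1)
        t = brute_force_otsu(np.round(img @ LUMA).astype(np.uint8))
        # same foreground as the brute-force threshold (within the integer bin)
        oracle = (img @ LUMA) > t
        assert (mask ^ oracle).mean() < 0.001

    def test_board_foreground_recovery(self, board_and_truth):
        img, gt = board_and_truth
        mask = seg.binarize(img, "mean")
        fg = gt.foreground
        assert (mask & fg).sum() / fg.sum() >= 0.99

    def test_constant_image_under_otsu_warns_all_background(self):
        img = np.full((20, 20, 3), 77, dtype=np.uint8)
        with pytest.warns(UserWarning):
            mask = seg.binarize(img, "otsu", blur_size=1)
        assert not mask.any()

    def test_offset_invariance_below_threshold_crossing(self):
        img = np.zeros((30, 30), dtype=np.uint8)
        img[:15] = 100
        base = seg.binarize(_gray_rgb(img), "mean", blur_size=1)
        shifted = seg.binarize(_gray_rgb(img + 20), "mean", blur_size=1)
        assert np.array_equal(base, shifted)

    def test_even_blur_size_rejected(self):
        with pytest.raises(ValueError):
            seg.binarize(np.zeros((5, 5, 3), np.uint8), "mean", blur_size=4)


class TestMorphClean:
    def test_single_pixel_removed_by_erosion(self):
        mask = np.zeros((11, 11), bool)
        mask[5, 5] = True
        assert not seg.morph_clean(mask, 1, 0, 3).any()

    def test_opening_preserves_large_square(self):
        mask = np.zeros((120, 120), bool)
        mask[10:110, 10:110] = True
        assert np.array_equal(seg.morph_clean(mask, 1, 1, 3), mask)

    def test_speckle_noise_removed_without_eroding_fruits(self, board_and_truth):
        img, gt = board_and_truth
        mask = seg.binarize(img, "mean")
        rng = np.random.default_rng(1)
        noisy = mask.copy()
        speck = (rng.random(mask.shape) < 0.001) & ~seg.morph_clean(mask, 0, 2, 3)
        noisy |= speck
        cleaned = seg.morph_clean(noisy, 1, 1, 3)
        assert not (cleaned & speck).any()
        area_before = mask.sum()
        assert abs(int(cleaned.sum()) - int(area_before)) / area_before < 0.01


class TestExtractRois:
    def test_board_yields_fruits_and_one_label(self, board_and_truth):
        img, gt = board_and_truth
        mask = seg.morph_clean(seg.binarize(img, "mean"))
        rois = seg.extract_rois(mask, img)
        classes = sorted(r.object_class for r in rois)
        assert classes == ["fruit"] * 4 + ["label"]

    def test_blank_board_warns_empty(self):
        img = np.full((100, 100, 3), 10, dtype=np.uint8)
        with pytest.warns(UserWarning):
            rois = seg.extract_rois(np.zeros((100, 100), bool), img)
        assert rois == []

    def test_blob_under_min_area_dropped(self):
        img = np.full((100, 100, 3), 10, dtype=np.uint8)
        mask = np.zeros((100, 100), bool)
        mask[50, 50] = True  # 1 px < 0.05% of 10000 px
        assert seg.extract_rois(mask, img) == []

    def test_area_matches_mask(self, board_and_truth):
        img, gt = board_and_truth
        mask = seg.morph_clean(seg.binarize(img, "mean"))
        for r in seg.extract_rois(mask, img):
            assert r.area_px == r.mask.sum()


class TestMakeTile:
    def test_fruit_centered_within_two_pixels(self, board_and_truth):
        img, gt = board_and_truth
        mask = seg.morph_clean(seg.binarize(img, "mean"))
        roi = next(r for r in seg.extract_rois(mask, img) if r.object_class == "fruit")
        tile = seg.make_tile(roi, img, size=400)
        rr, cc = np.nonzero(tile.fruit_mask)
        assert abs(rr.mean() - 200) <= 2 and abs(cc.mean() - 200) <= 2
        assert tile.pixels.shape == (400, 400, 3)

    def test_background_exactly_black(self, matched_tiles):
        tiles, _ = matched_tiles
        t = tiles[0]
        assert not t.pixels[~t.fruit_mask].any()

    def test_non_fruit_object_rejected(self, board_and_truth):
        img, gt = board_and_truth
        mask = seg.morph_clean(seg.binarize(img, "mean"))
        label_roi = next(r for r in seg.extract_rois(mask, img) if r.object_class == "label")
        with pytest.raises(ValueError):
            seg.make_tile(label_roi, img)

    def test_resegmenting_tile_preserves_area(self, board_and_truth):
        img, gt = board_and_truth
        mask = seg.morph_clean(seg.binarize(img, "mean"))
        roi = next(r for r in seg.extract_rois(mask, img) if r.object_class == "fruit")
        tile = seg.make_tile(roi, img, size=400)
        again = seg.extract_rois(tile.fruit_mask, tile.pixels, min_area_frac=0.0001,
                                 max_area_frac=1.0)
        fruits = [r for r in again if r.object_class == "fruit"]
        assert len(fruits) == 1
        assert fruits[0].area_px == roi.area_px

    def test_tile_mask_matches_ground_truth_after_translation(self, board_and_truth):
        img, gt = board_and_truth
        mask = seg.morph_clean(seg.binarize(img, "mean"))
        roi = next(r for r in seg.extract_rois(mask, img) if r.object_class == "fruit")
        d = [np.hypot(roi.centroid[0] - c[0], roi.centroid[1] - c[1]) for c in gt.centroids]
        gt_mask = gt.masks[int(np.argmin(d))]
        tile = seg.make_tile(roi, img, size=400)
        # compare cropped bounding boxes; morphology may shave a thin rim
        sub_t = tile.fruit_mask
        rr, cc = np.nonzero(sub_t)
        rg, cg = np.nonzero(gt_mask)
        jaccard_area = min(sub_t.sum(), gt_mask.sum()) / max(sub_t.sum(), gt_mask.sum())
        assert jaccard_area > 0.97
        assert abs((rr.max() - rr.min()) - (rg.max() - rg.min())) <= 4

    def test_oversize_fruit_downscaled_with_flag(self, board_and_truth):
        img, gt = board_and_truth
        mask = seg.morph_clean(seg.binarize(img, "mean"))
        roi = next(r for r in seg.extract_rois(mask, img) if r.object_class == "fruit")
        tile = seg.make_tile(roi, img, size=64)
        assert tile.downscaled_by < 1.0
        assert tile.pixels.shape[:2] == (64, 64)
        with pytest.raises(ValueError):
            seg.make_tile(roi, img, size=64, allow_downscale=False)


class TestClassifySide:
    def test_recovers_ground_truth_sides(self, matched_tiles):
        tiles, truth = matched_tiles
        sides = seg.classify_side(tiles)
        assert sides == truth

    def test_pale_tile_labeled_internal(self):
        def solid(color, jitter_seed):
            rng = np.random.default_rng(jitter_seed)
            t = np.zeros((60, 60, 3), np.uint8)
            vals = np.clip(np.array(color) + rng.normal(0, 3, (40, 40, 3)), 1, 255)
            t[10:50, 10:50] = vals.astype(np.uint8)
            return seg.FruitTile(t)

        tiles = [solid((120, 20, 20), 0), solid((240, 235, 230), 1)]
        sides = seg.classify_side(tiles)
        assert sides == ["external", "internal"]

    def test_duplicated_batch_assigns_duplicates_identically(self, matched_tiles):
        tiles, _ = matched_tiles
        doubled = [seg.FruitTile(t.pixels.copy()) for t in tiles for _ in range(2)]
        sides = seg.classify_side(doubled)
        assert sides[0::2] == sides[1::2]

    def test_identical_tiles_rejected(self):
        t = np.zeros((40, 40, 3), np.uint8)
        t[10:30, 10:30] = 100
        with pytest.raises(ValueError):
            seg.classify_side([seg.FruitTile(t.copy()), seg.FruitTile(t.copy())])

    def test_fewer_than_two_tiles_rejected(self):
        t = np.zeros((40, 40, 3), np.uint8)
        t[10:30, 10:30] = 100
        with pytest.raises(ValueError):
            seg.classify_side([seg.FruitTile(t)])


class TestSegmentBoard:
    def test_tile_count_matches_ground_truth(self):
        for s in range(4):
            img, gt = fixtures.render_board(fixtures.BoardSpec(seed=s))
            tiles = seg.segment_board(img, tile_size=360)
            assert len(tiles) == len(gt.masks)

    def test_genotype_defaults_to_source_stem(self, board_and_truth):
        img, _ = board_and_truth
        tiles = seg.segment_board(img, tile_size=360, source="GENO-42")
        assert all(t.genotype == "GENO-42" for t in tiles)
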