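"""Feature factors against brute-force per-pixel oracles and the frozen order."""

import numpy as np
import pytest

import daqugrade as dq
from daqugrade.features import (
    FEATURE_NAMES_L1,
    FEATURE_NAMES_L2,
    FeatureTable,
    color_stats,
    pixel_features,
    rgb_histogram_4bin,
)


def brute_color_stats(image, mask):
    """Independent per-pixel oracle for the 12 color factors."""
    import colorsys

    px = image[mask].astype(float)
    out = list(px.mean(axis=0)) + list(px.std(axis=0))
    hsv = np.array([colorsys.rgb_to_hsv(*(p / 255.0)) for p in px])
    h = hsv[:, 0] * 2 * np.pi
    C, S = np.cos(h).mean(), np.sin(h).mean()
    mean_hue = (np.arctan2(S, C) / (2 * np.pi)) % 1.0
    R = np.hypot(C, S)
    std_hue = np.sqrt(max(-2.0 * np.log(max(R, 1e-300)), 0.0)) / (2 * np.pi)
    out += [mean_hue, hsv[:, 1].mean(), hsv[:, 2].mean(),
            std_hue, hsv[:, 1].std(), hsv[:, 2].std()]
    return np.array(out)


class TestColorStats:
    def test_constant_roi_has_zero_stds(self):
        img = np.full((6, 6, 3), (40, 80, 120), dtype=np.uint8)
        mask = np.ones((6, 6), dtype=bool)
        vals = color_stats(img, mask)
        names = dict(zip(FEATURE_NAMES_L1[:12], vals))
        for k in ("StdRed", "StdGreen", "StdBlue", "StdHue", "StdSaturation", "StdValue"):
            # circular hue std carries ~1e-9 floating-point residue
            assert names[k] == pytest.approx(0.0, abs=1e-8)

    def test_two_pixel_hand_arithmetic(self):
        img = np.zeros((1, 2, 3), dtype=np.uint8)
        img[0, 0] = (100, 0, 0)
        img[0, 1] = (200, 0, 0)
        vals = color_stats(img, np.ones((1, 2), dtype=bool))
        assert vals[0] == pytest.approx(150.0)   # MeanRed
        assert vals[3] == pytest.approx(50.0)    # StdRed, population divisor

    def test_pure_red_hsv(self):
        img = np.full((4, 4, 3), (255, 0, 0), dtype=np.uint8)
        vals = color_stats(img, np.ones((4, 4), dtype=bool))
        named = dict(zip(FEATURE_NAMES_L1[:12], vals))
        assert named["MeanSaturation"] == pytest.approx(1.0)
        assert named["MeanValue"] == pytest.approx(1.0)
        assert named["MeanHue"] == pytest.approx(0.0, abs=1e-9)

    def test_hue_wraps_circularly(self):
        # hues at 0.99 and 0.01 must average to ~0.0, not 0.5
        img = np.zeros((1, 2, 3), dtype=np.uint8)
        img[0, 0] = (255, 0, 15)    # hue just below 1
        img[0, 1] = (255, 15, 0)    # hue just above 0
        vals = color_stats(img, np.ones((1, 2), dtype=bool))
        mean_hue = dict(zip(FEATURE_NAMES_L1[:12], vals))["MeanHue"]
        assert min(mean_hue, 1 - mean_hue) < 0.02

    def test_matches_brute_force_oracle(self, rng):
        img = rng.integers(0, 256, (16, 16, 3)).astype(np.uint8)
        mask = rng.random((16, 16)) < 0.6
        mask[0, 0] = True
        assert np.allclose(color_stats(img, mask), brute_color_stats(img, mask),
                           atol=1e-9)

    def test_empty_mask_rejected(self, rng):
        img = rng.integers(0, 256, (8, 8, 3)).astype(np.uint8)
        with pytest.raises(ValueError, match="empty"):
            color_stats(img, np.zeros((8, 8), dtype=bool))


class TestPixelFeatures:
    def solid_block(self):
        img = np.full((40, 40, 3), 200, dtype=np.uint8)
        mask = np.zeros((40, 40), dtype=bool)
        mask[10:20, 10:30] = True
        return img, mask

    def test_rect_area_and_no_dark(self):
        img, mask = self.solid_block()
        rect_area, dark = pixel_features(mask, img)
        assert rect_area == 200 and dark == 0

    def test_dark_pixel_count(self):
        img, mask = self.solid_block()
        rows, cols = np.nonzero(mask)
        img[rows[:17], cols[:17]] = 0
        _, dark = pixel_features(mask, img)
        assert dark == 17

    def test_dark_area_monotone_in_threshold(self, rng):
        img = rng.integers(0, 256, (30, 30, 3)).astype(np.uint8)
        mask = np.ones((30, 30), dtype=bool)
        darks = [pixel_features(mask, img, thr)[1] for thr in (0.1, 0.25, 0.5, 0.9)]
        assert darks == sorted(darks)


class TestHistogram:
    def test_all_zero_roi_in_first_bin(self):
        img = np.zeros((5, 5, 3), dtype=np.uint8)
        vals = rgb_histogram_4bin(img, np.ones((5, 5), dtype=bool))
        assert np.allclose(vals.reshape(3, 4), [[1, 0, 0, 0]] * 3)

    def test_one_value_per_bin(self):
        img = np.zeros((1, 4, 3), dtype=np.uint8)
        img[0, :, 0] = [10, 70, 150, 250]
        vals = rgb_histogram_4bin(img, np.ones((1, 4), dtype=bool))
        assert np.allclose(vals[:4], [0.25, 0.25, 0.25, 0.25])

    def test_matches_counting_oracle_and_sums_to_one(self, rng):
        img = rng.integers(0, 256, (12, 12, 3)).astype(np.uint8)
        mask = rng.random((12, 12)) < 0.5
        mask[3, 3] = True
        vals = rgb_histogram_4bin(img, mask).reshape(3, 4)
        px = img[mask]
        edges = [(0, 63), (64, 127), (128, 191), (192, 255)]
        for c in range(3):
            oracle = [np.sum((px[:, c] >= lo) & (px[:, c] <= hi)) / len(px)
                      for lo, hi in edges]
            assert np.allclose(vals[c], oracle)
            assert vals[c].sum() == pytest.approx(1.0)

    def test_invariant_to_pixel_order(self, rng):
        img = rng.integers(0, 256, (10, 10, 3)).astype(np.uint8)
        mask = np.ones((10, 10), dtype=bool)
        base = rgb_histogram_4bin(img, mask)
        perm = rng.permutation(100)
        shuffled = img.reshape(100, 3)[perm].reshape(10, 10, 3)
        assert np.allclose(rgb_histogram_4bin(shuffled, mask), base)


class TestExtractFeatures:
    def test_layer1_has_14_factors(self, p_image, p_segmented):
        vec = dq.extract_features(p_image, p_segmented, "L1")
        assert len(vec.values) == 14
        assert tuple(vec.names) == FEATURE_NAMES_L1

    def test_layer2_has_38_factors_with_24_histogram(self, p_image, p_segmented):
        vec = dq.extract_features(p_image, p_segmented, "L2")
        assert len(vec.values) == 38
        hist_names = [n for n in vec.names if "_Bin" in n]
        assert len(hist_names) == 24
        # two ROIs x 3 channels x 4 bins
        assert sum(n.startswith("Center_") for n in hist_names) == 12
        assert sum(n.startswith("Pizhang_") for n in hist_names) == 12

    def test_degenerate_segmentation_rejected(self, p_image):
        from daqugrade.segmentation import SegmentationResult

        bad = SegmentationResult(mask=np.zeros(p_image.pixels.shape[:2], dtype=bool),
                                 method="threshold", threshold=0, degenerate=True)
        with pytest.raises(ValueError, match="degenerate"):
            dq.extract_features(p_image, bad, "L1")

    def test_feature_order_frozen_across_runs(self, p_image, p_segmented, tmp_path):
        vec = dq.extract_features(p_image, p_segmented, "L2")
        golden = (
            "MeanRed,MeanGreen,MeanBlue,StdRed,StdGreen,StdBlue,"
            "MeanHue,MeanSaturation,MeanValue,StdHue,StdSaturation,StdValue,"
            "RectArea,DarkArea,"
            "Center_Red_Bin1,Center_Red_Bin2,Center_Red_Bin3,Center_Red_Bin4,"
            "Center_Green_Bin1,Center_Green_Bin2,Center_Green_Bin3,Center_Green_Bin4,"
            "Center_Blue_Bin1,Center_Blue_Bin2,Center_Blue_Bin3,Center_Blue_Bin4,"
            "Pizhang_Red_Bin1,Pizhang_Red_Bin2,Pizhang_Red_Bin3,Pizhang_Red_Bin4,"
            "Pizhang_Green_Bin1,Pizhang_Green_Bin2,Pizhang_Green_Bin3,Pizhang_Green_Bin4,"
            "Pizhang_Blue_Bin1,Pizhang_Blue_Bin2,Pizhang_Blue_Bin3,Pizhang_Blue_Bin4"
        )
        assert ",".join(vec.names) == golden


class TestFeatureTable:
    def test_layer2_data_points_per_grade(self, l2_table):
        counts = l2_table.data_point_counts()
        # 10 images/grade here: 10 x 38 = 380 weighted points per class
        assert counts == {0: 380.0, 1: 380.0}

    def test_layer1_weighted_balance(self, l1_table):
        counts = l1_table.data_point_counts()
        # {P,F}: 20 x 1 x 14 = 280; S: 10 x 2 x 14 = 280
        assert counts == {0: 280.0, 1: 280.0}

    def test_empty_weight_map_gives_unit_weights(self, small_corpus):
        images, _ = small_corpus
        table = dq.build_feature_table(images, "L1", weight_map={})
        assert np.allclose(table.weights, 1.0)

    def test_csv_round_trip(self, l2_table, tmp_path):
        path = l2_table.to_csv(tmp_path / "l2.csv")
        back = FeatureTable.from_csv(path, layer="L2", task="P_vs_F")
        assert np.allclose(back.matrix, l2_table.matrix)
        assert list(back.feature_names) == list(l2_table.feature_names)
        assert np.array_equal(back.labels, l2_table.labels)

    def test_subset_columns_preserves_order(self, l2_table):
        sub = l2_table.subset_columns(["MeanRed", "DarkArea"])
        assert sub.p == 2
        assert np.allclose(sub.matrix[:, 0], l2_table.matrix[:, 0])
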