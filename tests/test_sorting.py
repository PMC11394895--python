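"""Quality sorter vs. brute-force loop oracles and its documented tie rules."""

import numpy as np
import pytest

from peppersort.sorting import (BLACK, WHITE, FlatMask, SortingConfig,
                                assess_flat_mask, compute_vald,
                                mark_flat_regions, select_high_quality,
                                sort_granule, to_gray)


# --- literal loop oracles -------------------------------------------------

def vald_oracle(img: np.ndarray, include_center=True) -> np.ndarray:
    h, w = img.shape
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            vals = []
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if not include_center and di == 0 and dj == 0:
                        continue
                    ii = min(max(i + di, 0), h - 1)   # replicate padding
                    jj = min(max(j + dj, 0), w - 1)
                    vals.append(img[ii, jj])
            out[i, j] = abs(img[i, j] - np.mean(vals))
    return out


def gad_oracle(img: np.ndarray) -> float:
    mu = img.mean()
    return float(np.mean([abs(v - mu) for v in img.ravel()]))


def mask_oracle(img, frac=0.10):
    v = vald_oracle(img)
    g = gad_oracle(img)
    return np.where(v <= frac * g, WHITE, BLACK).astype(np.uint8)


def window_oracle(mask, window, stride):
    h, w = mask.shape
    props = []
    for i in range(0, h - window + 1, stride):
        for j in range(0, w - window + 1, stride):
            win = mask[i:i + window, j:j + window]
            props.append((win == BLACK).mean())
    return props


class TestComputeVald:
    def test_uniform_image_has_no_variation(self):
        stats = compute_vald(np.full((6, 6), 137.0))
        np.testing.assert_array_equal(stats.vald, 0.0)
        assert stats.gad == 0.0

    def test_center_spike_hand_value(self):
        img = np.zeros((3, 3))
        img[1, 1] = 90.0
        stats = compute_vald(img)
        assert stats.vald[1, 1] == pytest.approx(80.0)   # 90 − 90/9

    @pytest.mark.parametrize("size", [(8, 8), (11, 13), (16, 16)])
    def test_matches_loop_oracle(self, rng, size):
        img = rng.integers(0, 256, size=size).astype(float)
        stats = compute_vald(img)
        np.testing.assert_allclose(stats.vald, vald_oracle(img), atol=1e-10)
        assert stats.gad == pytest.approx(gad_oracle(img), abs=1e-10)

    def test_excluding_center_variant(self):
        img = np.zeros((3, 3))
        img[1, 1] = 90.0
        mask_inc = mark_flat_regions(img, 1.0, include_center=True)
        mask_exc = mark_flat_regions(img, 1.0, include_center=False)
        # 8-neighbor vALD at the spike is 90 (vs 80 inclusive)
        assert mask_inc.mask.shape == mask_exc.mask.shape

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_vald(np.empty((0, 0)))


class TestMarkFlatRegions:
    def test_uniform_image_fully_flat(self):
        mask = mark_flat_regions(np.full((8, 8), 42.0))
        np.testing.assert_array_equal(mask.mask, WHITE)

    def test_checkerboard_fully_non_flat(self):
        img = np.indices((4, 4)).sum(axis=0) % 2 * 255.0
        mask = mark_flat_regions(img)
        np.testing.assert_array_equal(mask.mask, BLACK)
        # oracle confirmation of the threshold arithmetic
        assert gad_oracle(img) == pytest.approx(127.5)
        assert vald_oracle(img).min() > 12.75

    def test_matches_loop_oracle_on_random_images(self, rng):
        for _ in range(100):
            h, w = rng.integers(8, 17, size=2)
            img = rng.integers(0, 256, size=(h, w)).astype(float)
            got = mark_flat_regions(img).mask
            np.testing.assert_array_equal(got, mask_oracle(img))

    def test_shift_invariance(self, rng):
        img = rng.integers(0, 200, size=(10, 10)).astype(float)
        m1 = mark_flat_regions(img).mask
        m2 = mark_flat_regions(img + 55.0).mask
        np.testing.assert_array_equal(m1, m2)


class TestAssessMask:
    def test_all_white(self):
        cfg = SortingConfig(window=4, stride=4)
        stats = assess_flat_mask(FlatMask(np.full((8, 8), WHITE, np.uint8)), cfg)
        assert stats["global_black"] == 0.0
        assert stats["max_window_black"] == 0.0

    def test_all_black(self):
        cfg = SortingConfig(window=4, stride=4)
        stats = assess_flat_mask(FlatMask(np.full((8, 8), BLACK, np.uint8)), cfg)
        assert stats["global_black"] == 1.0
        assert np.all(stats["window_black"] == 1.0)

    def test_quarter_block_hand_count(self):
        m = np.full((8, 8), WHITE, np.uint8)
        m[:4, :4] = BLACK
        stats = assess_flat_mask(FlatMask(m), SortingConfig(window=4, stride=4))
        assert stats["global_black"] == pytest.approx(0.25)
        assert sorted(stats["window_black"]) == [0.0, 0.0, 0.0, 1.0]

    def test_matches_window_oracle(self, rng):
        cfg = SortingConfig(window=5, stride=3)
        m = np.where(rng.uniform(size=(16, 16)) < 0.3, BLACK, WHITE).astype(np.uint8)
        stats = assess_flat_mask(FlatMask(m), cfg)
        np.testing.assert_allclose(sorted(stats["window_black"]),
                                   sorted(window_oracle(m, 5, 3)))

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValueError, match="window"):
            assess_flat_mask(FlatMask(np.full((8, 8), WHITE, np.uint8)),
                             SortingConfig(window=16))


class TestSelect:
    def test_all_white_accepted(self):
        v = select_high_quality(FlatMask(np.full((16, 16), WHITE, np.uint8)))
        assert v.accepted and v.reason == "ok"

    def test_all_black_rejected_with_global_reason(self):
        v = select_high_quality(FlatMask(np.full((16, 16), BLACK, np.uint8)))
        assert not v.accepted and v.reason == "global_black"

    def test_exact_threshold_accepted(self):
        # global black exactly 0.25 with the default ≤ rule
        m = np.full((16, 16), WHITE, np.uint8)
        m[:8, :8] = BLACK
        cfg = SortingConfig(window=8, stride=8, scatter_threshold=0.25)
        v = select_high_quality(FlatMask(m), cfg)
        assert v.global_black == pytest.approx(0.25)
        assert v.accepted

    def test_monotone_in_black_pixels(self, rng):
        cfg = SortingConfig(window=8, stride=8)
        for _ in range(25):
            m = np.where(rng.uniform(size=(16, 16)) < rng.uniform(0, 0.6),
                         BLACK, WHITE).astype(np.uint8)
            before = select_high_quality(FlatMask(m), cfg).accepted
            m2 = m.copy()
            whites = np.argwhere(m2 == WHITE)
            if len(whites) == 0:
                continue
            for idx in whites[rng.permutation(len(whites))[:5]]:
                m2[tuple(idx)] = BLACK
            after = select_high_quality(FlatMask(m2), cfg).accepted
            assert not (after and not before)

    def test_invalid_mask_values_rejected(self):
        with pytest.raises(ValueError):
            FlatMask(np.full((4, 4), 7, np.uint8))


class TestEndToEnd:
    def test_grayscale_conversion_luma(self):
        rgb = np.zeros((2, 2, 3))
        rgb[..., 0] = 100
        assert to_gray(rgb)[0, 0] == pytest.approx(29.9)

    def test_uniform_color_granule_accepted(self, rng):
        from peppersort.synthetic import generate_granule_crop
        crop = generate_granule_crop("mature", rng=np.random.default_rng(0))
        assert sort_granule(crop).accepted

    def test_mottled_granule_rejected(self):
        from peppersort.synthetic import generate_granule_crop
        crop = generate_granule_crop("semi_mature", rng=np.random.default_rng(0))
        assert not sort_granule(crop).accepted
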