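"""Quality metrics against closed forms and brute-force oracles."""

import math

import numpy as np
import pytest

from mammofuse.image_io import GrayImage
from mammofuse.metrics import EMEConfig, ambe, eme, entropy, full_report, iqi, std_dev


def brute_force_eme(px, bh=3, bw=3, eps=1.0):
    """Independent double-loop oracle over non-overlapping blocks."""
    h, w = px.shape
    vals = []
    for i in range(0, h - bh + 1, bh):
        for j in range(0, w - bw + 1, bw):
            block = px[i:i + bh, j:j + bw]
            bmax, bmin = block.max(), block.min()
            if bmax < eps:
                vals.append(0.0)
            else:
                vals.append(20 * math.log10(bmax / max(bmin, eps)))
    return sum(vals) / len(vals)


def brute_force_iqi(x, y, window=8):
    """Independent sliding-window oracle with explicit moment formulas."""
    h, w = x.shape
    vals = []
    for i in range(h - window + 1):
        for j in range(w - window + 1):
            a = x[i:i + window, j:j + window].ravel()
            b = y[i:i + window, j:j + window].ravel()
            ma, mb = a.mean(), b.mean()
            va = ((a - ma) ** 2).mean()
            vb = ((b - mb) ** 2).mean()
            cov = ((a - ma) * (b - mb)).mean()
            denom = (va + vb) * (ma * ma + mb * mb)
            if denom > 0:
                vals.append(4 * cov * ma * mb / denom)
    return sum(vals) / len(vals)


class TestEME:
    def test_constant_image_scores_zero(self):
        assert eme(GrayImage(np.full((9, 9), 80.0))) == 0.0

    def test_single_block_closed_form(self):
        block = np.array([[50.0, 100, 200], [60, 70, 80], [90, 110, 130]])
        assert eme(GrayImage(block)) == pytest.approx(20 * math.log10(4), abs=1e-12)

    def test_matches_brute_force_oracle_on_random_images(self, rng):
        for _ in range(50):
            px = rng.uniform(0, 255, size=(12, 12))
            assert eme(GrayImage(px)) == pytest.approx(brute_force_eme(px), abs=1e-10)

    def test_block_permutation_invariance(self, rng):
        px = rng.uniform(0, 255, size=(12, 12))
        blocks = px.reshape(4, 3, 4, 3).transpose(0, 2, 1, 3).reshape(16, 3, 3)
        perm = blocks[rng.permutation(16)]
        shuffled = perm.reshape(4, 4, 3, 3).transpose(0, 2, 1, 3).reshape(12, 12)
        assert eme(GrayImage(px)) == pytest.approx(eme(GrayImage(shuffled)), abs=1e-10)

    def test_partial_trailing_blocks_dropped(self, rng):
        px = rng.uniform(0, 255, size=(12, 12))
        padded = np.zeros((13, 13))
        padded[:12, :12] = px
        # the trailing row/column cannot fill a 3x3 block, so the block set
        # is identical to the 12x12 image's
        assert eme(GrayImage(padded)) == pytest.approx(eme(GrayImage(px)), abs=1e-10)

    def test_dark_blocks_contribute_zero(self):
        assert eme(GrayImage(np.zeros((3, 3)))) == 0.0

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            eme(GrayImage(np.zeros((2, 2))))

    def test_custom_block_geometry(self, rng):
        px = rng.uniform(0, 255, size=(8, 10))
        cfg = EMEConfig(block_h=4, block_w=5)
        assert eme(GrayImage(px), cfg) == pytest.approx(
            brute_force_eme(px, 4, 5), abs=1e-10
        )


class TestAMBE:
    def test_identical_images_score_zero(self, random_raw_image):
        assert ambe(random_raw_image, random_raw_image) == 0.0

    def test_constant_offset(self):
        a = GrayImage(np.full((5, 5), 100.0))
        b = GrayImage(np.full((5, 5), 140.0))
        assert ambe(a, b) == pytest.approx(40.0, abs=1e-12)

    def test_symmetry(self, rng):
        for _ in range(10):
            a = GrayImage(rng.uniform(0, 255, size=(6, 6)))
            b = GrayImage(rng.uniform(0, 255, size=(6, 6)))
            assert ambe(a, b) == ambe(b, a)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ambe(GrayImage(np.zeros((4, 4))), GrayImage(np.zeros((5, 4))))


class TestEntropy:
    def test_constant_image_zero_bits(self):
        assert entropy(GrayImage(np.full((8, 8), 42.0))) == 0.0

    def test_two_equal_levels_one_bit(self):
        px = np.zeros((4, 4))
        px[:, 2:] = 255.0
        assert entropy(GrayImage(px)) == pytest.approx(1.0, abs=1e-12)

    def test_all_levels_equal_gives_eight_bits(self):
        px = np.arange(256.0).reshape(16, 16)
        assert entropy(GrayImage(px)) == pytest.approx(8.0, abs=1e-12)

    def test_pixel_permutation_invariance(self, rng):
        px = rng.integers(0, 256, size=(10, 10)).astype(float)
        shuffled = rng.permutation(px.ravel()).reshape(10, 10)
        assert entropy(GrayImage(px)) == pytest.approx(
            entropy(GrayImage(shuffled)), abs=1e-12
        )

    def test_bounded_by_alphabet_size(self, rng):
        px = rng.integers(0, 256, size=(20, 20)).astype(float)
        assert 0.0 <= entropy(GrayImage(px)) <= 8.0


class TestStdDev:
    def test_constant_image_zero(self):
        assert std_dev(GrayImage(np.full((4, 4), 9.0))) == 0.0

    def test_half_zero_half_full_scale(self):
        px = np.zeros((4, 4))
        px[2:, :] = 255.0
        assert std_dev(GrayImage(px)) == pytest.approx(127.5, abs=1e-12)

    def test_matches_two_pass_formula(self, rng):
        px = rng.uniform(0, 255, size=(9, 9))
        mean = sum(px.ravel()) / px.size
        var = sum((v - mean) ** 2 for v in px.ravel()) / px.size
        assert std_dev(GrayImage(px)) == pytest.approx(math.sqrt(var), rel=1e-12)

    def test_scaling_multiplies_sd(self, rng):
        px = rng.uniform(0, 100, size=(6, 6))
        assert std_dev(GrayImage(2.5 * px)) == pytest.approx(
            2.5 * std_dev(GrayImage(px)), rel=1e-12
        )


class TestIQI:
    def test_self_comparison_is_one(self, random_raw_image):
        assert iqi(random_raw_image, random_raw_image) == pytest.approx(1.0, abs=1e-12)

    def test_matches_sliding_window_oracle(self, rng):
        for _ in range(5):
            x = rng.uniform(0, 255, size=(16, 16))
            y = rng.uniform(0, 255, size=(16, 16))
            assert iqi(GrayImage(x), GrayImage(y)) == pytest.approx(
                brute_force_iqi(x, y), abs=1e-10
            )

    def test_symmetry(self, rng):
        x = GrayImage(rng.uniform(0, 255, size=(12, 12)))
        y = GrayImage(rng.uniform(0, 255, size=(12, 12)))
        assert iqi(x, y) == pytest.approx(iqi(y, x), abs=1e-12)

    def test_inversion_flips_sign(self, rng):
        x = rng.uniform(20, 235, size=(16, 16))
        inv = 255.0 - x
        # anticorrelated pair: every defined window has negative covariance
        assert iqi(GrayImage(x), GrayImage(inv)) < 0.0

    def test_result_within_unit_band(self, rng):
        for _ in range(10):
            x = GrayImage(rng.uniform(0, 255, size=(10, 10)))
            y = GrayImage(rng.uniform(0, 255, size=(10, 10)))
            assert -1.0 <= iqi(x, y) <= 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            iqi(GrayImage(np.zeros((8, 8))), GrayImage(np.zeros((9, 8))))

    def test_constant_pair_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            iqi(GrayImage(np.zeros((8, 8))), GrayImage(np.zeros((8, 8))))

    def test_oversized_window_rejected(self, random_raw_image):
        with pytest.raises(ValueError):
            iqi(random_raw_image, random_raw_image, window=17)


class TestFullReport:
    def test_reference_fields_absent_without_reference(self, random_raw_image):
        rep = full_report(random_raw_image)
        assert rep.ambe is None and rep.iqi is None
        assert rep.eme >= 0 and rep.sd >= 0 and 0 <= rep.entropy_bits <= 8

    def test_reference_fields_present_with_reference(self, random_raw_image, rng):
        other = GrayImage(rng.uniform(0, 255, size=random_raw_image.shape))
        rep = full_report(other, reference=random_raw_image)
        assert rep.ambe is not None and -1 <= rep.iqi <= 1
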