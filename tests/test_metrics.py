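"""Loss and metric correctness against independent small-scale oracles."""

import itertools

import numpy as np
import pytest

from multipath25d.metrics import (
    MetricValidationError,
    SizeClass,
    classify_lesion_size,
    dice_coefficient,
    soft_dice,
    two_channel_loss,
    two_channel_loss_from_logits,
    wilcoxon_rank_sum,
)


# ---------------------------------------------------------------------------
# soft Dice
# ---------------------------------------------------------------------------

class TestSoftDice:
    def test_perfect_overlap_is_one(self):
        r = np.zeros((5, 5))
        r[1:3, 1:4] = 1
        assert soft_dice(r, r) == pytest.approx(1.0, abs=1e-6)

    def test_hand_counted_binary_case(self):
        # TP=2, FP=1, FN=1 -> 2*2 / (2*2+1+1) = 4/6
        p = np.array([1, 1, 1, 0, 0], dtype=float)
        r = np.array([1, 1, 0, 1, 0], dtype=float)
        assert soft_dice(p, r) == pytest.approx(4 / 6, abs=1e-6)

    def test_zero_prediction_on_nonempty_target(self):
        r = np.ones((3, 3))
        assert soft_dice(np.zeros((3, 3)), r) == pytest.approx(0.0, abs=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(MetricValidationError):
            soft_dice(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_binary_input_equals_hard_dice(self, rng):
        """On binary p, D(p) reduces to Eq-style 2TP/(2TP+FP+FN) exactly."""
        for _ in range(50):
            p = (rng.random((6, 7, 5)) < 0.3).astype(np.uint8)
            r = (rng.random((6, 7, 5)) < 0.3).astype(np.uint8)
            hard = dice_coefficient(p, r)
            if hard.tp + hard.fp + hard.fn == 0:
                continue
            assert soft_dice(p, r) == pytest.approx(hard.dice, abs=1e-6)


class TestTwoChannelLoss:
    def test_perfect_prediction_zero_loss(self):
        r = np.zeros((4, 4))
        r[1:3, 1:3] = 1
        assert two_channel_loss(r, 1 - r, r) == pytest.approx(0.0, abs=1e-5)

    def test_inverted_prediction_max_loss(self):
        r = np.zeros((4, 4))
        r[0, 0] = 1
        assert two_channel_loss(1 - r, r, r) == pytest.approx(2.0, abs=1e-5)

    def test_uniform_half_prediction_matches_direct_summation(self):
        # independent oracle: plug p=0.5 into the definition by direct sums
        n, f = 40, 10
        r = np.zeros(n)
        r[:f] = 1
        p = np.full(n, 0.5)
        d_p = 2 * (0.5 * f) / (n * 0.25 + f)
        d_q = 2 * (0.5 * (n - f)) / (n * 0.25 + (n - f))
        expect = 2 - d_p - d_q
        assert two_channel_loss(p, 1 - p, r) == pytest.approx(expect, abs=1e-6)

    def test_loss_decreases_toward_target(self):
        """Strictly decreasing along the segment from inverted to exact."""
        rng = np.random.default_rng(0)
        r = (rng.random((5, 5)) < 0.4).astype(float)
        vals = []
        for a in np.linspace(0.0, 1.0, 7):
            p = a * r + (1 - a) * (1 - r)
            vals.append(two_channel_loss(p, 1 - p, r))
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_logit_gradient_matches_finite_differences(self, rng):
        logits = rng.standard_normal((2, 2, 4, 3))
        r = (rng.random((2, 4, 3)) < 0.4).astype(np.float32)
        _, dz = two_channel_loss_from_logits(logits, r)
        eps = 1e-5
        for idx in [(0, 0, 1, 2), (1, 1, 3, 0), (0, 1, 0, 0)]:
            pert = logits.copy()
            pert[idx] += eps
            l1, _ = two_channel_loss_from_logits(pert, r)
            pert[idx] -= 2 * eps
            l2, _ = two_channel_loss_from_logits(pert, r)
            assert dz[idx] == pytest.approx((l1 - l2) / (2 * eps), rel=1e-3, abs=1e-8)


# ---------------------------------------------------------------------------
# hard Dice
# ---------------------------------------------------------------------------

class TestDiceCoefficient:
    def test_identical_masks(self, small_mask):
        res = dice_coefficient(small_mask.data, small_mask.data)
        assert res.dice == 1.0 and res.fp == 0 and res.fn == 0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4), dtype=np.uint8)
        b = np.zeros((4, 4, 4), dtype=np.uint8)
        a[0, 0, 0] = 1
        b[3, 3, 3] = 1
        assert dice_coefficient(a, b).dice == 0.0

    def test_hand_counted_counts(self):
        # TP=3, FP=1, FN=2 -> 6/9
        pred = np.array([1, 1, 1, 1, 0, 0, 0])
        truth = np.array([1, 1, 1, 0, 1, 1, 0])
        res = dice_coefficient(pred, truth)
        assert (res.tp, res.fp, res.fn) == (3, 1, 2)
        assert res.dice == pytest.approx(6 / 9)

    def test_empty_vs_empty_is_one(self):
        z = np.zeros((3, 3, 3), dtype=np.uint8)
        assert dice_coefficient(z, z).dice == 1.0

    def test_symmetry(self, rng):
        a = (rng.random((5, 5, 5)) < 0.3).astype(np.uint8)
        b = (rng.random((5, 5, 5)) < 0.3).astype(np.uint8)
        assert dice_coefficient(a, b).dice == dice_coefficient(b, a).dice

    def test_non_binary_rejected(self):
        with pytest.raises(MetricValidationError):
            dice_coefficient(np.full((2, 2), 0.5), np.zeros((2, 2)))


# ---------------------------------------------------------------------------
# lesion size rule
# ---------------------------------------------------------------------------

class TestSizeRule:
    def _mask_with_extents(self, e0, e1, e2):
        m = np.zeros((40, 40, 40), dtype=np.uint8)
        m[5:5 + e0, 5:5 + e1, 5:5 + e2] = 1
        return m

    def test_below_all_thresholds_is_small(self):
        # extents (24, 19, 19) mm against (25, 20, 20)
        m = self._mask_with_extents(24, 19, 19)
        assert classify_lesion_size(m) is SizeClass.SMALL

    def test_one_axis_exceeding_is_large(self):
        m = self._mask_with_extents(24, 21, 19)
        assert classify_lesion_size(m) is SizeClass.LARGE

    def test_boundary_goes_to_large(self):
        m = self._mask_with_extents(25, 20, 20)
        assert classify_lesion_size(m) is SizeClass.LARGE

    def test_single_voxel_is_small(self):
        m = np.zeros((8, 8, 8), dtype=np.uint8)
        m[4, 4, 4] = 1
        assert classify_lesion_size(m) is SizeClass.SMALL

    def test_spacing_scales_extents(self):
        # 8 voxels at 3 mm = 24 mm on axis 1 -> large
        m = self._mask_with_extents(4, 8, 4)
        assert classify_lesion_size(m, spacing=(1, 3, 1)) is SizeClass.LARGE
        assert classify_lesion_size(m, spacing=(1, 1, 1)) is SizeClass.SMALL

    def test_empty_mask_rejected(self):
        with pytest.raises(MetricValidationError):
            classify_lesion_size(np.zeros((4, 4, 4)))


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def exact_rank_sum_pvalue(x, y):
    """Brute-force two-sided p-value by enumerating rank assignments."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = np.argsort(np.argsort(combined)) + 1
    w_obs = ranks[:nx].sum()
    mean = nx * (nx + ny + 1) / 2
    stats = []
    for comb in itertools.combinations(range(nx + ny), nx):
        stats.append(sum(c + 1 for c in comb))
    stats = np.array(stats)
    p = np.mean(np.abs(stats - mean) >= abs(w_obs - mean) - 1e-12)
    return p


class TestWilcoxon:
    def test_small_disjoint_samples_exact_value(self):
        # x={1,2}, y={3,4}: most extreme of C(4,2)=6 assignments -> p = 2/6
        assert wilcoxon_rank_sum([1, 2], [3, 4]) == pytest.approx(1 / 3, abs=1e-9)

    def test_symmetry_under_swap(self, rng):
        x = rng.normal(size=5)
        y = rng.normal(size=7)
        assert wilcoxon_rank_sum(x, y) == pytest.approx(wilcoxon_rank_sum(y, x))

    def test_identical_samples_fully_tied(self):
        assert wilcoxon_rank_sum([2.0, 2.0, 2.0], [2.0, 2.0]) == 1.0

    @pytest.mark.parametrize("nx,ny", [(2, 3), (3, 3), (4, 4), (5, 6), (6, 6)])
    def test_exact_matches_enumeration_oracle(self, nx, ny, rng):
        for _ in range(20):
            vals = rng.permutation(np.arange(1.0, nx + ny + 1))
            x, y = vals[:nx], vals[nx:]
            p = wilcoxon_rank_sum(x, y)
            assert p == pytest.approx(exact_rank_sum_pvalue(x, y), abs=1e-9)

    def test_exact_close_to_normal_approximation(self, rng):
        """Tie-free n=6+6: the exact and corrected-normal p agree closely."""
        from scipy import stats as sps

        for _ in range(10):
            x = rng.normal(size=6)
            y = rng.normal(0.5, size=6)
            exact = wilcoxon_rank_sum(x, y)
            approx = float(sps.mannwhitneyu(x, y, alternative="two-sided",
                                            method="asymptotic").pvalue)
            assert abs(exact - approx) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(MetricValidationError):
            wilcoxon_rank_sum([], [1.0])
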