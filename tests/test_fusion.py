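"""Union/majority vote against brute-force counting; 3D fuser contracts."""

import numpy as np
import pytest

from multipath25d.fusion import (
    Fusion3DNet,
    FuserConfig,
    FusionConfigurationError,
    StackedPathTensor,
    assemble_stack,
    binarize,
    fuse,
    fuse_cnn3d,
    fuse_majority,
    fuse_union,
    load_fuser,
    save_fuser,
)
from multipath25d.volume_io import BrainVolume, VolumeValidationError


def random_masks(rng, n=9, shape=(5, 6, 4), p=0.3):
    return [(rng.random(shape) < p).astype(np.uint8) for _ in range(n)]


class TestBinarize:
    def test_half_rounds_up_to_lesion(self):
        soft = np.array([0.0, 0.49, 0.5, 0.51, 1.0])
        np.testing.assert_array_equal(binarize(soft), [0, 0, 1, 1, 1])


class TestAssembleStack:
    def test_channel_count_and_layout(self, rng):
        vol = BrainVolume(data=rng.random((16, 16, 16)).astype(np.float32))
        preds = [rng.random((16, 16, 16)) for _ in range(9)]
        stack = assemble_stack(preds, vol)
        assert stack.data.shape == (18, 16, 16, 16)
        for k in range(9):
            np.testing.assert_array_equal(stack.data[2 * k],
                                          binarize(preds[k]).astype(np.float32))
            np.testing.assert_array_equal(stack.data[2 * k + 1], vol.data)

    def test_all_zero_predictions(self, rng):
        vol = BrainVolume(data=rng.random((8, 8, 8)).astype(np.float32))
        stack = assemble_stack([np.zeros((8, 8, 8))] * 9, vol)
        assert np.all(stack.data[0::2] == 0)

    def test_wrong_count_rejected(self, rng):
        vol = BrainVolume(data=np.zeros((8, 8, 8), dtype=np.float32))
        with pytest.raises(VolumeValidationError):
            assemble_stack([np.zeros((8, 8, 8))] * 8, vol)

    def test_wrong_shape_rejected(self, rng):
        vol = BrainVolume(data=np.zeros((8, 8, 8), dtype=np.float32))
        preds = [np.zeros((8, 8, 8))] * 8 + [np.zeros((4, 4, 4))]
        with pytest.raises(VolumeValidationError):
            assemble_stack(preds, vol)


class TestUnionMajority:
    def test_union_with_one_full_path(self, rng):
        masks = [np.zeros((4, 4, 4), dtype=np.uint8) for _ in range(9)]
        masks[3][:] = 1
        assert np.all(fuse_union(masks) == 1)

    def test_union_of_all_zero(self):
        assert np.all(fuse_union([np.zeros((3, 3, 3), np.uint8)] * 9) == 0)

    def test_union_majority_match_per_voxel_counting(self, rng):
        """Exact agreement with a brute-force vote count on random ensembles."""
        for _ in range(20):
            masks = random_masks(rng)
            votes = np.sum(masks, axis=0)
            np.testing.assert_array_equal(fuse_union(masks), (votes >= 1))
            np.testing.assert_array_equal(fuse_majority(masks), (votes >= 5))

    def test_majority_threshold_at_five_of_nine(self):
        shape = (2, 2, 2)
        for k in (4, 5):
            masks = [np.ones(shape, np.uint8)] * k + \
                    [np.zeros(shape, np.uint8)] * (9 - k)
            expect = 1 if k >= 5 else 0
            assert np.all(fuse_majority(masks) == expect)

    def test_majority_subset_of_union(self, rng):
        for _ in range(10):
            masks = random_masks(rng, p=0.5)
            maj = fuse_majority(masks)
            uni = fuse_union(masks)
            assert np.all(maj <= uni)

    def test_union_foreground_at_least_max_single_path(self, rng):
        masks = random_masks(rng)
        assert fuse_union(masks).sum() >= max(m.sum() for m in masks)

    def test_monotonicity_under_single_vote_flip(self, rng):
        masks = random_masks(rng, shape=(3, 3, 3), p=0.5)
        before_u, before_m = fuse_union(masks), fuse_majority(masks)
        masks[0] = masks[0].copy()
        masks[0][1, 1, 1] = 1
        assert np.all(fuse_union(masks) >= before_u)
        assert np.all(fuse_majority(masks) >= before_m)

    def test_even_path_count_rejected(self, rng):
        with pytest.raises(FusionConfigurationError):
            fuse_majority(random_masks(rng, n=8))

    def test_unanimous_paths_identity(self, rng):
        m = (rng.random((4, 4, 4)) < 0.4).astype(np.uint8)
        assert np.array_equal(fuse_majority([m] * 9), m)
        assert np.array_equal(fuse_union([m] * 9), m)


class TestFusion3DNet:
    def test_channel_plan_and_shape_preservation(self, rng):
        net = Fusion3DNet(seed=0)
        plan = [c.params["weight"].shape for c in net.convs]
        assert plan == [(36, 18, 3, 3, 3), (9, 36, 3, 3, 3),
                        (9, 9, 3, 3, 3), (2, 9, 3, 3, 3)]
        x = rng.standard_normal((1, 18, 6, 5, 4)).astype(np.float32)
        assert net.forward(x).shape == (1, 2, 6, 5, 4)

    def test_softmax_channels_sum_to_one(self, rng):
        net = Fusion3DNet(seed=0)
        stack = StackedPathTensor(
            data=rng.standard_normal((18, 5, 5, 5)).astype(np.float32))
        p = fuse_cnn3d(stack, net)
        assert p.shape == (5, 5, 5)
        assert np.all((p >= 0) & (p <= 1))

    def test_zero_weight_fuser_ties_to_lesion(self, rng):
        net = Fusion3DNet(seed=0)
        for _, mod, name in net.named_parameters():
            mod.params[name] = np.zeros_like(mod.params[name])
        stack = StackedPathTensor(
            data=rng.standard_normal((18, 4, 4, 4)).astype(np.float32))
        p = fuse_cnn3d(stack, net)
        np.testing.assert_allclose(p, 0.5, atol=1e-7)
        assert np.all(binarize(p) == 1)

    def test_channel_mismatch_rejected(self, rng):
        net = Fusion3DNet(seed=0)
        with pytest.raises(VolumeValidationError):
            net.forward(np.zeros((1, 12, 4, 4, 4), dtype=np.float32))

    def test_checkpoint_roundtrip(self, tmp_path, rng):
        net = Fusion3DNet(seed=2)
        save_fuser(net, tmp_path / "fuser.npz")
        back = load_fuser(tmp_path / "fuser.npz")
        x = rng.standard_normal((1, 18, 4, 4, 4)).astype(np.float32)
        np.testing.assert_array_equal(net.forward(x), back.forward(x))


class TestLearnedFusionQuality:
    def test_trained_fuser_matches_or_beats_majority_vote(self, rng):
        """Paths simulated as systematically dilated, noisy copies of truth:
        majority vote inherits the dilation bias, a trained 3D fuser can
        correct it using the stacked image channel."""
        from scipy import ndimage

        from multipath25d.training import TrainConfig, train_fuser

        def make_case(case_rng):
            shape = (24, 32, 24)
            truth = np.zeros(shape, dtype=np.float32)
            c = case_rng.integers(9, 16, size=3)
            xs = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
            r = case_rng.uniform(4.5, 6.5)
            blob = sum((x - ci) ** 2 for x, ci in zip(xs, c)) <= r * r
            truth[blob] = 1
            image = 1.0 - 0.4 * truth + 0.05 * case_rng.standard_normal(shape)
            chans = []
            for _ in range(9):
                path = ndimage.binary_dilation(truth).astype(np.float32)
                flip = case_rng.random(shape) < 0.05
                path[flip] = 1 - path[flip]
                chans.extend([path, image.astype(np.float32)])
            return StackedPathTensor(data=np.stack(chans)), truth

        train = [make_case(np.random.default_rng(s)) for s in range(6)]
        test = [make_case(np.random.default_rng(s)) for s in (100, 101)]
        fuser = Fusion3DNet(seed=0)
        cfg = TrainConfig(epochs=4, steps_per_epoch=15, lr0=0.01, seed=1)
        train_fuser([s for s, _ in train], [t for _, t in train], cfg, fuser,
                    patch_size=12, patch_batch=4)
        cnn_dice, maj_dice = [], []
        for stack, truth in test:
            truth = truth.astype(np.uint8)
            cnn = binarize(fuse_cnn3d(stack, fuser))
            maj = fuse_majority([stack.data[2 * k].astype(np.uint8)
                                 for k in range(9)])
            from multipath25d.metrics import dice_coefficient

            cnn_dice.append(dice_coefficient(cnn, truth).dice)
            maj_dice.append(dice_coefficient(maj, truth).dice)
        assert np.mean(cnn_dice) >= np.mean(maj_dice)


class TestFuseDispatch:
    def test_unknown_strategy_rejected(self, rng):
        vol = BrainVolume(data=np.zeros((4, 4, 4), dtype=np.float32))
        with pytest.raises(FusionConfigurationError):
            fuse([np.zeros((4, 4, 4))] * 9, vol, "average")

    def test_cnn3d_requires_network(self, rng):
        vol = BrainVolume(data=np.zeros((4, 4, 4), dtype=np.float32))
        with pytest.raises(FusionConfigurationError):
            fuse([np.zeros((4, 4, 4))] * 9, vol, "cnn3d")

    def test_union_strategy_binarizes_soft_inputs(self, rng):
        vol = BrainVolume(data=np.zeros((4, 4, 4), dtype=np.float32))
        soft = [np.full((4, 4, 4), 0.6)] + [np.zeros((4, 4, 4))] * 8
        assert np.all(fuse(soft, vol, "union") == 1)
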