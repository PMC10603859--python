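import numpy as np
import pytest

from caroseg import metrics as m
from caroseg import phantom as ph
from caroseg import segnet as sn
from caroseg.nn import UNetConfig


class TestPreprocess:
    def test_range_and_shape(self):
        rng = np.random.default_rng(0)
        img = rng.random((91, 122)) * 50 + 10
        out = sn.preprocess(img)
        assert out.shape == (192, 256)
        assert out.min() == pytest.approx(0.0)
        assert out.max() == pytest.approx(1.0)

    def test_native_size_identity_up_to_normalization(self):
        rng = np.random.default_rng(1)
        img = rng.random((192, 256))
        out = sn.preprocess(img)
        expect = (img - img.min()) / (img.max() - img.min())
        np.testing.assert_allclose(out, expect, atol=1e-6)

    def test_affine_intensity_invariance(self):
        rng = np.random.default_rng(2)
        img = rng.random((64, 64))
        np.testing.assert_allclose(sn.preprocess(img),
                                   sn.preprocess(3.0 * img + 7.0), atol=1e-5)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            sn.preprocess(np.full((32, 32), 5.0))


class TestSoftDiceLoss:
    def test_perfect_prediction(self):
        y = (np.random.default_rng(0).random((32, 32)) > 0.5).astype(float)
        assert sn.soft_dice_loss(y, y) < 1e-5

    def test_inverted_prediction(self):
        y = (np.random.default_rng(1).random((32, 32)) > 0.5).astype(float)
        assert sn.soft_dice_loss(y, 1 - y) == pytest.approx(1.0, abs=1e-4)

    def test_uniform_half_on_full_mask(self):
        y = np.ones((64, 64))
        yhat = np.full((64, 64), 0.5)
        assert sn.soft_dice_loss(y, yhat) == pytest.approx(1 / 3, abs=1e-6)


class TestATDL:
    def test_phase1_uniform_weights(self):
        state = sn.ATDLState()
        total, state = sn.atdl_step(state, (0.9, 0.8, 0.7))
        assert state.phase == 1
        assert state.weights == (pytest.approx(1 / 3), pytest.approx(1 / 3),
                                 pytest.approx(1 / 3))
        assert total == pytest.approx((0.9 + 0.8 + 0.7) / 3)

    def test_weights_always_sum_to_one(self):
        rng = np.random.default_rng(0)
        state = sn.ATDLState(warmup_steps=30, min_steps=5)
        for _ in range(100):
            losses = tuple(rng.uniform(0.0, 1.0, 3))
            _, state = sn.atdl_step(state, losses)
            assert sum(state.weights) == pytest.approx(1.0)
            assert min(state.weights) >= 0

    def test_phase2_proportional_with_floor(self):
        state = sn.ATDLState(phase=2, smoothed=(0.01, 0.01, 0.2),
                             min_steps=0, warmup_steps=0)
        _, state = sn.atdl_step(state, (0.01, 0.01, 0.2))
        a, b, c = state.weights
        assert c > a and c > b
        assert a == pytest.approx(b, abs=1e-9)
        assert min(a, b, c) >= state.floor - 1e-12

    def test_phase_switch_on_component_crossover(self):
        state = sn.ATDLState(min_steps=1, warmup_steps=1000)
        _, state = sn.atdl_step(state, (0.1, 0.1, 0.5))
        assert state.phase == 2

    def test_warmup_forces_switch(self):
        state = sn.ATDLState(min_steps=5, warmup_steps=3)
        for _ in range(3):
            _, state = sn.atdl_step(state, (0.9, 0.9, 0.2))
        assert state.phase == 2

    def test_negative_losses_rejected(self):
        with pytest.raises(ValueError):
            sn.atdl_step(sn.ATDLState(), (-0.1, 0.5, 0.5))


class TestAugmentation:
    @pytest.fixture(scope="class")
    def samples(self, rendered_case):
        return sn.slide_samples_from_case(rendered_case, step=3.0)

    def test_flips_multiply_count(self, samples):
        base = samples[:3]
        assert len(sn.augment_training_set(base, flip_h=True,
                                           flip_v=False)) == 6
        assert len(sn.augment_training_set(base, flip_h=True,
                                           flip_v=True)) == 12

    def test_label_invariants_preserved(self, samples):
        out = sn.augment_training_set(samples[:2], flip_h=True, flip_v=True,
                                      n_random=2, seed=1)
        for s in out:
            assert np.all(s.y_lib <= s.y_mab)
            assert set(np.unique(s.y_cvw)) <= {0.0, 1.0}

    def test_reslice_count_over_full_coverage(self, geometry_only_cases):
        # 15 mm CCA + 10 mm ICA at 0.5 mm spacing -> 31 + 20 = 51 slices
        stack = geometry_only_cases[0].geometry.truth_stack(0.5)
        assert len(stack.contours) == 51

    def test_deterministic(self, samples):
        a = sn.augment_training_set(samples[:2], n_random=2, seed=3)
        b = sn.augment_training_set(samples[:2], n_random=2, seed=3)
        for s1, s2 in zip(a, b):
            np.testing.assert_array_equal(s1.image, s2.image)


class _ConstantModel:
    """Stub returning fixed probability maps regardless of input."""

    def __init__(self, maps):
        self.maps = np.asarray(maps, dtype=np.float32)

    def forward(self, x, train=False):
        return np.repeat(self.maps[None], x.shape[0], axis=0)


class TestFlipEnsemble:
    def test_identical_predictions_equal_single(self):
        rng = np.random.default_rng(0)
        # left-right and up-down symmetric probability maps: all three
        # ensemble members then agree pixel-wise
        base = rng.random((2, 96, 128)).astype(np.float32)
        sym = (base + base[:, :, ::-1] + base[:, ::-1, :]
               + base[:, ::-1, ::-1]) / 4
        model = _ConstantModel(sym)
        img = np.zeros((96, 128), dtype=np.float32)
        mab, lib = sn.predict_with_flip_ensemble(model, img)
        np.testing.assert_array_equal(mab, sym[0] >= 0.5)
        np.testing.assert_array_equal(lib, sym[1] >= 0.5)

    def test_majority_vote_two_of_three(self):
        class PerMember:
            def __init__(self):
                self.maps = None

            def forward(self, x, train=False):
                out = np.zeros((3, 2, 4, 4), dtype=np.float32)
                out[0, :, 0, 0] = 1.0   # original predicts 1
                out[1, :, 0, 3] = 1.0   # un-flipping maps this to (0, 0)
                return out
        mab, lib = sn.predict_with_flip_ensemble(PerMember(),
                                                 np.zeros((4, 4),
                                                          dtype=np.float32))
        assert mab[0, 0] and lib[0, 0]  # votes (1,1,0) -> 1
        assert mab.sum() == 1  # a single vote elsewhere stays 0


class TestICARoiBoxes:
    def test_identical_end_boxes(self):
        boxes = sn.ica_roi_boxes((0, 0, 4, 4), (0, 0, 4, 4),
                                 [1.0, 2.0, 3.0])
        assert all(b == (0, 0, 4, 4) for b in boxes)

    def test_midpoint_arithmetic_mean(self):
        boxes = sn.ica_roi_boxes((0, 0, 10, 8), (2, 2, 6, 6),
                                 [0.0, 1.0, 2.0])
        assert boxes[1] == (1.0, 1.0, 8.0, 7.0)

    def test_linear_width_sequence(self):
        boxes = sn.ica_roi_boxes((0, 0, 20, 5), (0, 0, 10, 5),
                                 [0.0, 1.0, 2.0, 3.0, 4.0])
        widths = [b[2] - b[0] for b in boxes]
        np.testing.assert_allclose(widths, [20, 17.5, 15, 12.5, 10])

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            sn.ica_roi_boxes((-5, 0, 4, 4), (0, 0, 4, 4), [0.0, 1.0],
                             bounds=(0, 0, 10, 10))

    def test_invalid_box_rejected(self):
        with pytest.raises(ValueError):
            sn.ica_roi_boxes((4, 0, 0, 4), (0, 0, 4, 4), [0.0, 1.0])


class TestSegmentVolume:
    def test_oracle_model_recovers_truth(self, rendered_case):
        model = sn.OracleModel([rendered_case], isd=2.0)
        boxes = sn.ica_end_boxes_from_truth(rendered_case, isd=2.0)
        res = sn.segment_volume(model, rendered_case.volume,
                                rendered_case.bifurcation_z,
                                ica_end_boxes=boxes, isd=2.0)
        assert not res.missing
        manual = rendered_case.geometry.truth_stack(
            2.0, z_limits=rendered_case.volume.z_range)
        comps = m.compare_stacks(manual, res.stack, grid_spacing=0.1)
        assert all(c.dsc >= 0.97 for c in comps)
        assert np.mean([c.dsc for c in comps]) >= 0.99

    def test_untrained_model_flags_missing_without_crash(self,
                                                         rendered_case):
        from caroseg.nn import UNet
        model = UNet(UNetConfig(width_mult=0.0625, depth=2, seed=99))
        res = sn.segment_volume(model, rendered_case.volume,
                                rendered_case.bifurcation_z, isd=3.0)
        # every slice is accounted for: contoured or flagged missing
        n_slices = len(res.stack.contours) + len(res.missing)
        assert n_slices >= 8
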