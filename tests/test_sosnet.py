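"""Network mechanics: shapes, init determinism, gradients, training basics,
residual-head transfer learning.  Trains only tiny configurations; the
end-to-end recovery study lives in the acceptance tests."""

import numpy as np
import pytest

from echosos.sosnet import (NetworkConfig, build_model, predict_sos,
                            attach_residual_head, expected_parameter_count,
                            TrainConfig, train, fine_tune,
                            SOS_OFFSET, SOS_SCALE)
from echosos.sosnet.layers import Conv2d, BatchNorm2d


@pytest.fixture(scope="module")
def small_cfg():
    return NetworkConfig().small()


@pytest.fixture(scope="module")
def small_model(small_cfg):
    return build_model(small_cfg, seed=1)


class TestBuild:
    def test_forward_shape_and_finiteness(self, small_model):
        out = small_model.forward(np.zeros((1, 128, 1024), np.float32), train=False)
        assert out.shape == (1, 384, 384)
        assert np.isfinite(out).all()

    def test_same_seed_identical_parameters(self, small_cfg):
        a = build_model(small_cfg, seed=7)
        b = build_model(small_cfg, seed=7)
        sa, sb = a.state_dict(), b.state_dict()
        assert all(np.array_equal(sa[k], sb[k]) for k in sa)

    def test_different_seed_differs(self, small_cfg):
        a = build_model(small_cfg, seed=7)
        b = build_model(small_cfg, seed=8)
        assert a.checksum() != b.checksum()

    def test_parameter_count_matches_closed_form(self, small_cfg, small_model):
        assert small_model.n_parameters() == expected_parameter_count(small_cfg)

    def test_default_config_counts(self):
        cfg = NetworkConfig()
        model_free = expected_parameter_count(cfg)
        assert model_free > expected_parameter_count(cfg.small())


class TestGradients:
    def test_conv_gradients_match_numerics(self):
        rng = np.random.default_rng(3)
        conv = Conv2d(2, 3, (3, 5), stride=(2, 2), rng=rng)
        x = rng.standard_normal((2, 2, 8, 12)).astype(np.float32)
        y = conv.forward(x, True)
        dy = rng.standard_normal(y.shape).astype(np.float32)
        dx = conv.backward(dy)
        eps = 1e-3
        idx = (1, 1, 4, 7)
        xp, xm = x.copy(), x.copy()
        xp[idx] += eps
        xm[idx] -= eps
        num = ((conv.forward(xp, False) * dy).sum()
               - (conv.forward(xm, False) * dy).sum()) / (2 * eps)
        assert dx[idx] == pytest.approx(num, rel=1e-2)
        widx = (2, 1, 1, 3)
        W = conv.params["W"]
        W[widx] += eps
        fp = (conv.forward(x, False) * dy).sum()
        W[widx] -= 2 * eps
        fm = (conv.forward(x, False) * dy).sum()
        W[widx] += eps
        assert conv.grads["W"][widx] == pytest.approx((fp - fm) / (2 * eps), rel=1e-2)

    def test_batchnorm_gradients_match_numerics(self):
        rng = np.random.default_rng(4)
        bn = BatchNorm2d(3)
        bn.params["gamma"][:] = rng.uniform(0.5, 1.5, 3).astype(np.float32)
        x = rng.standard_normal((2, 3, 4, 5)).astype(np.float32)
        y = bn.forward(x, True)
        dy = rng.standard_normal(y.shape).astype(np.float32)
        dx = bn.backward(dy)
        eps = 1e-3
        idx = (0, 1, 2, 3)
        xp, xm = x.copy(), x.copy()
        xp[idx] += eps
        xm[idx] -= eps
        num = ((bn.forward(xp, True) * dy).sum()
               - (bn.forward(xm, True) * dy).sum()) / (2 * eps)
        assert dx[idx] == pytest.approx(num, abs=2e-2)


class TestTraining:
    def test_zero_lr_leaves_parameters_unchanged(self, small_cfg):
        model = build_model(small_cfg, seed=2)
        before = model.param_checksum()
        rng = np.random.default_rng(0)
        data = [(rng.standard_normal((128, 1024)).astype(np.float32),
                 np.full((384, 384), 1500.0, np.float32)) for _ in range(3)]
        train(model, data, TrainConfig(lr=0.0, batch=2, epochs=1, seed=0))
        assert model.param_checksum() == before

    def test_overfits_repeated_sample(self, small_cfg):
        """Capacity sanity: a repeated (rf, label) pair is memorized."""
        model = build_model(small_cfg, seed=3)
        rng = np.random.default_rng(1)
        rf = rng.standard_normal((128, 1024)).astype(np.float32)
        label = np.full((384, 384), 1460.0, np.float32)
        data = [(rf, label)] * 2
        _, hist = train(model, data,
                        TrainConfig(lr=0.05, momentum=0.9, batch=2, epochs=40, seed=0))
        assert hist["train_rmse"][-1] < 5.0
        assert hist["train_rmse"][-1] < hist["train_rmse"][0]

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(lr=-1.0)
        with pytest.raises(ValueError):
            TrainConfig(split=1.0)

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_nan_loss_aborts_with_diagnostics(self, small_cfg):
        model = build_model(small_cfg, seed=4)
        rng = np.random.default_rng(2)
        data = [(rng.standard_normal((128, 1024)).astype(np.float32),
                 np.full((384, 384), 1500.0, np.float32)) for _ in range(3)]
        with pytest.raises(FloatingPointError, match="lr"):
            train(model, data, TrainConfig(lr=1e9, momentum=0.99, batch=3,
                                           epochs=8, seed=0))


class TestPredict:
    def test_prediction_units_and_shape(self, small_model):
        rng = np.random.default_rng(5)
        rf = rng.standard_normal((128, 1024)).astype(np.float32)
        rf = (rf - rf.mean(axis=1, keepdims=True)) / rf.std(axis=1, keepdims=True)
        est = predict_sos(small_model, rf)
        assert est.values.shape == (384, 384)
        assert est.pixel_size_mm == 0.1
        # untrained network stays near the 1500 m/s prior of the output scale
        assert abs(est.values.mean() - SOS_OFFSET) < 2 * SOS_SCALE

    def test_unconditioned_rf_warns(self, small_model):
        rf = np.full((128, 1024), 3.0, np.float32)
        rf[:, 0] = 2.0  # nonzero variance, large mean
        with pytest.warns(UserWarning, match="conditioned"):
            predict_sos(small_model, rf)

    def test_wrong_shape_rejected(self, small_model):
        with pytest.raises(ValueError):
            predict_sos(small_model, np.zeros((64, 1024), np.float32))


class TestTransferLearning:
    def test_fresh_head_reproduces_base(self, small_model):
        aug = attach_residual_head(small_model, seed=0)
        rng = np.random.default_rng(6)
        x = rng.standard_normal((2, 128, 1024)).astype(np.float32)
        base = small_model.forward(x, train=False)
        augmented = aug.forward(x, train=False)
        assert np.allclose(augmented, base, atol=1e-3 / SOS_SCALE)

    def test_head_is_small_fraction_of_base(self, small_model):
        aug = attach_residual_head(small_model, seed=0)
        assert aug.n_parameters() < 0.05 * small_model.n_parameters()

    def test_base_frozen_through_fine_tuning(self, small_cfg):
        model = build_model(small_cfg, seed=9)
        aug = attach_residual_head(model, seed=1)
        before = model.checksum()
        rng = np.random.default_rng(7)
        data = [(rng.standard_normal((128, 1024)).astype(np.float32),
                 np.full((384, 384), 1520.0, np.float32)) for _ in range(6)]
        _, hist = fine_tune(aug, data, TrainConfig(lr=0.01, momentum=0.9,
                                                   batch=3, epochs=25, seed=0))
        assert model.checksum() == before  # bit-identical base
        assert len(hist["train_rmse"]) <= 20  # epoch cap honored

    def test_empty_fine_tune_dataset_rejected(self, small_model):
        aug = attach_residual_head(small_model, seed=0)
        with pytest.raises(ValueError):
            fine_tune(aug, [])
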