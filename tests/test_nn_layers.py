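import math

import numpy as np
import pytest

from cgmcast.nn import network as net
from cgmcast.nn.autodiff import Tensor, as_tensor
from oracles import attention_loops, conv1d_relu_loops, lstm_step_loops


def rand_lstm_params(rng, H, I=1):
    mats = {g: rng.normal(0, 0.5, size=(H + I, H)) for g in "fioc"}
    biases = {g: rng.normal(0, 0.1, size=H) for g in "fioc"}
    return mats, biases


class TestLstmStep:
    def test_matches_scalar_loop_oracle_on_random_instances(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            B = int(rng.integers(1, 5))
            H = int(rng.integers(1, 6))
            I = int(rng.integers(1, 4))
            mats, biases = rand_lstm_params(rng, H, I)
            x = rng.normal(size=(B, I))
            h0 = rng.normal(size=(B, H))
            c0 = rng.normal(size=(B, H))
            h, c = net.lstm_step(x, h0, c0,
                                 mats["f"], mats["i"], mats["o"], mats["c"],
                                 biases["f"], biases["i"], biases["o"], biases["c"])
            h_ref, c_ref = lstm_step_loops(x, h0, c0,
                                           mats["f"], mats["i"], mats["o"],
                                           mats["c"], biases["f"], biases["i"],
                                           biases["o"], biases["c"])
            assert np.abs(h.data - h_ref).max() < 1e-6
            assert np.abs(c.data - c_ref).max() < 1e-6

    def test_zero_parameters_give_zero_state(self):
        z = np.zeros((3, 2, 2)), np.zeros(2)
        h, c = net.lstm_step(np.ones((1, 1)), np.zeros((1, 2)), np.zeros((1, 2)),
                             *(np.zeros((3, 2)) for _ in range(4)),
                             *(np.zeros(2) for _ in range(4)))
        assert np.all(h.data == 0.0) and np.all(c.data == 0.0)

    def test_single_unit_hand_computation(self):
        theta = np.array([[0.5], [0.5]])
        h, c = net.lstm_step(np.array([[1.0]]), np.zeros((1, 1)), np.zeros((1, 1)),
                             theta, theta, theta, theta,
                             *(np.zeros(1) for _ in range(4)))
        gate = 1 / (1 + math.exp(-0.5))
        c_expect = gate * math.tanh(0.5)
        assert c.data[0, 0] == pytest.approx(c_expect, abs=1e-12)
        assert h.data[0, 0] == pytest.approx(gate * math.tanh(c_expect), abs=1e-12)

    def test_saturating_input_opens_gates(self):
        rng = np.random.default_rng(0)
        mats = {g: 0.5 + np.abs(rng.normal(size=(2, 1))) for g in "fioc"}
        h, c = net.lstm_step(np.array([[1000.0]]), np.zeros((1, 1)),
                             np.full((1, 1), 0.3),
                             mats["f"], mats["i"], mats["o"], mats["c"],
                             *(np.zeros(1) for _ in range(4)))
        assert h.data[0, 0] == pytest.approx(math.tanh(c.data[0, 0]), abs=1e-6)
        assert c.data[0, 0] == pytest.approx(0.3 + 1.0, abs=1e-6)  # f,i -> 1, ctil -> 1


class TestBiLstm:
    def shared_params(self, H, seed=0):
        cfg = net.ModelConfig(lstm_hidden=H, cnn_filters=4)
        params = net.init_params(cfg, np.random.default_rng(seed))
        for g in "fioc":
            params[f"lstm_bwd.{g}.W"] = params[f"lstm_fwd.{g}.W"]
            params[f"lstm_bwd.{g}.b"] = params[f"lstm_fwd.{g}.b"]
        return params

    def test_output_shape(self):
        for H in (1, 3, 8):
            params = net.init_params(net.ModelConfig(lstm_hidden=H, cnn_filters=4),
                                     np.random.default_rng(1))
            out = net.bilstm_forward(np.linspace(0, 1, 6), params, H)
            assert out.data.shape == (1, 6, 2 * H)

    def test_zero_parameters_give_zero_sequence(self):
        params = self.shared_params(3)
        for key, p in params.items():
            if key.startswith("lstm"):
                p.data = np.zeros_like(p.data)
        out = net.bilstm_forward(np.linspace(0, 1, 6), params, 3)
        assert np.all(out.data == 0.0)

    def test_reversal_swaps_streams_when_parameters_shared(self):
        H = 4
        params = self.shared_params(H, seed=3)
        w = np.random.default_rng(9).random(6)
        out = net.bilstm_forward(w, params, H).data[0]
        out_rev = net.bilstm_forward(w[::-1].copy(), params, H).data[0]
        for t in range(6):
            # forward stream on the reversed window = backward stream at 5-t
            assert np.allclose(out_rev[t, :H], out[5 - t, H:])
            assert np.allclose(out_rev[t, H:], out[5 - t, :H])

    def test_wrong_window_length_rejected(self):
        params = self.shared_params(2)
        with pytest.raises(ValueError, match="6 samples"):
            net.bilstm_forward(np.zeros(5), params, 2)


class TestSelfAttention:
    def test_identical_rows_give_uniform_weights_and_identity(self):
        y = np.tile(np.array([0.3, -0.2, 0.7]), (6, 1))
        out, w = net.self_attention(y, return_weights=True)
        assert np.allclose(w.data, 1.0 / 6)
        assert np.allclose(out.data, y)

    def test_weight_rows_sum_to_one(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            y = rng.normal(size=(6, int(rng.integers(1, 10))))
            _, w = net.self_attention(y, return_weights=True)
            assert np.abs(w.data.sum(axis=-1) - 1.0).max() < 1e-6

    def test_matches_two_loop_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            y = rng.normal(size=(6, 4))
            out = net.self_attention(y)
            assert np.abs(out.data - attention_loops(y)).max() < 1e-6

    def test_batched_equals_per_item(self):
        rng = np.random.default_rng(2)
        batch = rng.normal(size=(5, 6, 3))
        out = net.self_attention(batch).data
        for b in range(5):
            assert np.allclose(out[b], net.self_attention(batch[b]).data)

    def test_non_finite_input_rejected(self):
        y = np.zeros((6, 2))
        y[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            net.self_attention(y)


class TestConv1d:
    def test_centre_passthrough_kernel(self):
        x = np.abs(np.random.default_rng(0).normal(size=(6, 1))) + 0.1
        kernel = np.array([[0.0], [1.0], [0.0]])  # (3*1, 1)
        out = net.conv1d_relu(x, kernel, np.zeros(1))
        assert out.data.shape == (4, 1)
        assert np.allclose(out.data[:, 0], x[1:5, 0])

    def test_relu_zeroes_negative_preactivations(self):
        x = np.ones((6, 2))
        kernel = -np.ones((6, 3))
        out = net.conv1d_relu(x, kernel, np.zeros(3))
        assert np.all(out.data == 0.0)

    def test_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            C = int(rng.integers(1, 5))
            F = int(rng.integers(1, 6))
            x = rng.normal(size=(6, C))
            k3d = rng.normal(size=(3, C, F))
            bias = rng.normal(size=F)
            out = net.conv1d_relu(x, k3d.reshape(3 * C, F), bias)
            ref = conv1d_relu_loops(x, k3d, bias)
            assert np.abs(out.data - ref).max() < 1e-6

    def test_output_length_formula(self):
        cfg = net.ModelConfig()
        assert cfg.conv_positions == 4  # floor((6 - 3)/1) + 1

    def test_kernel_longer_than_input_rejected(self):
        with pytest.raises(ValueError, match="kernel"):
            net.conv1d_relu(np.ones((6, 1)), np.ones((7, 1)), np.zeros(1))


class TestInitialisation:
    def test_glorot_bounds(self):
        rng = np.random.default_rng(0)
        draws = net.glorot_uniform(rng, 3, 100, shape=(3, 100, 50))
        limit = math.sqrt(6 / 103)
        assert np.abs(draws).max() <= limit
        assert np.abs(draws).max() > 0.9 * limit  # actually fills the range

    def test_same_seed_identical_parameters(self):
        cfg = net.ModelConfig(lstm_hidden=4, cnn_filters=8, mode="multimodal",
                              baseline_dim=2)
        p1 = net.init_params(cfg, np.random.default_rng(5))
        p2 = net.init_params(cfg, np.random.default_rng(5))
        assert p1.keys() == p2.keys()
        for k in p1:
            assert np.array_equal(p1[k].data, p2[k].data)

    def test_biases_start_at_zero(self):
        cfg = net.ModelConfig(lstm_hidden=4, cnn_filters=8, mode="multimodal",
                              baseline_dim=2)
        params = net.init_params(cfg, np.random.default_rng(5))
        for name, p in params.items():
            if name.endswith(".b"):
                assert np.all(p.data == 0.0)


class TestEncodersAndFusion:
    def multimodal_cfg(self, **kw):
        return net.ModelConfig(lstm_hidden=4, cnn_filters=8, mode="multimodal",
                               baseline_dim=kw.pop("baseline_dim", 2), **kw)

    def test_baseline_encoder_zero_weights_give_relu_bias(self):
        cfg = self.multimodal_cfg(baseline_hidden=(3,))
        params = net.init_params(cfg, np.random.default_rng(0))
        params["baseline.0.W"].data[:] = 0.0
        params["baseline.0.b"].data[:] = np.array([-1.0, 0.5, 2.0])
        out = net.baseline_encoder(np.array([[4.0, 1.0]]), params, 1)
        assert np.allclose(out.data, [[0.0, 0.5, 2.0]])

    @pytest.mark.parametrize("vset,dim", [(0, 2), (2, 5)])
    def test_variable_set_input_dimensions(self, vset, dim):
        from cgmcast.synth import VARIABLE_SETS
        assert len(VARIABLE_SETS[vset]) == dim

    def test_incomplete_record_rejected(self):
        cfg = self.multimodal_cfg()
        params = net.init_params(cfg, np.random.default_rng(0))
        with pytest.raises(ValueError, match="absent"):
            net.baseline_encoder(np.array([[np.nan, 1.0]]), params, 2)

    def test_fusion_concatenates_on_feature_axis(self):
        cfg = net.ModelConfig(mode="multimodal", baseline_dim=2,
                              baseline_hidden=(16,), fusion_hidden=7)
        params = net.init_params(cfg, np.random.default_rng(0))
        assert params["fusion.W"].data.shape == (400 + 16, 7)
        z1 = np.random.default_rng(1).normal(size=(3, 400))
        z2 = np.zeros((3, 16))
        out = net.fuse(z1, z2, params)
        assert out.data.shape == (3, 7)
        # zero Z2 -> output depends only on Z1 block of the weights
        manual = np.maximum(z1 @ params["fusion.W"].data[:400] +
                            params["fusion.b"].data, 0.0)
        assert np.allclose(out.data, manual)


class TestForward:
    def test_output_strictly_inside_unit_interval(self):
        cfg = net.ModelConfig(lstm_hidden=3, cnn_filters=4)
        params = net.init_params(cfg, np.random.default_rng(0))
        out = net.forward(np.random.default_rng(1).random((10, 6)), None,
                          params, cfg)
        assert np.all(out.data > 0.0) and np.all(out.data < 1.0)

    def test_eval_mode_is_deterministic(self):
        cfg = net.ModelConfig(lstm_hidden=3, cnn_filters=4)
        params = net.init_params(cfg, np.random.default_rng(0))
        X = np.random.default_rng(1).random((4, 6))
        a = net.predict(X, None, params, cfg)
        assert np.array_equal(a, net.predict(X, None, params, cfg))

    def test_unimodal_ignores_record(self):
        cfg = net.ModelConfig(lstm_hidden=3, cnn_filters=4)
        params = net.init_params(cfg, np.random.default_rng(0))
        X = np.random.default_rng(1).random((4, 6))
        a = net.predict(X, None, params, cfg)
        b = net.predict(X, np.ones((4, 2)), params, cfg)
        assert np.array_equal(a, b)

    def test_multimodal_requires_record(self):
        cfg = net.ModelConfig(lstm_hidden=3, cnn_filters=4, mode="multimodal",
                              baseline_dim=2)
        params = net.init_params(cfg, np.random.default_rng(0))
        with pytest.raises(ValueError, match="record"):
            net.forward(np.zeros((2, 6)), None, params, cfg)


class TestObjectives:
    def test_singleton_candidate_set_contributes_zero(self):
        pred = np.array([0.7])
        assert net.loss_listwise_loglik(pred, [np.array([0])]).data == pytest.approx(0.0)

    def test_two_equal_candidates_give_minus_log2(self):
        pred = np.array([0.4, 0.4])
        loss = net.loss_listwise_loglik(pred, [np.array([0, 1]), np.array([0, 1])])
        assert loss.data == pytest.approx(-2 * math.log(2))

    def test_matches_naive_evaluation(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            pred = rng.normal(size=8)
            sets = [rng.choice(8, size=rng.integers(1, 8), replace=False)
                    for _ in range(8)]
            stable = net.loss_listwise_loglik(pred, sets).data
            naive = sum(pred[i] - math.log(sum(math.exp(pred[j]) for j in s))
                        for i, s in enumerate(sets))
            assert stable == pytest.approx(naive, abs=1e-6)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            net.loss_listwise_loglik(np.array([]), [])

    def test_mse_matches_definition(self):
        pred = Tensor(np.array([0.2, 0.4]))
        assert net.loss_mse(pred, np.array([0.0, 0.8])).data == \
            pytest.approx((0.04 + 0.16) / 2)
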