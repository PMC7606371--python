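import numpy as np
import pytest

from dmriqa.networks import (
    BatchNorm,
    CLFBlock,
    Conv3x3,
    DepthwiseConv3x3,
    DSRBlock,
    GlobalAvgPool,
    MaxPool2x2,
    NetSpec,
    NLDRBlock,
    NLRBlock,
    NonlocalBlock,
    PointwiseConv,
    SQANet,
    VQANet,
    dsconv_param_count,
    load_model,
    save_model,
)
from dmriqa.networks.layers import nonlocal_reference


def _upcast(layer):
    for name in layer.params:
        layer.params[name] = layer.params[name].astype(np.float64)
    for child in layer.children:
        _upcast(child)
    return layer


def _gradcheck(layer, x, n_checks=8, eps=1e-6, rtol=1e-5, training=True):
    """Central-difference check of parameter and input gradients.

    Loss is a fixed random projection of the output, so dL/dy is constant.
    """
    rng = np.random.default_rng(0)
    y = layer.forward(x, training)
    R = rng.normal(size=y.shape)

    def loss():
        return float(np.sum(layer.forward(x, training) * R))

    layer.zero_grads()
    layer.backward(R)
    items = [(l, n) for l in layer.walk() for n in l.params]
    for l, name in items:
        arr = l.params[name]
        for _ in range(min(n_checks, arr.size)):
            idx = tuple(rng.integers(0, s) for s in arr.shape)
            old = arr[idx]
            arr[idx] = old + eps
            lp = loss()
            arr[idx] = old - eps
            lm = loss()
            arr[idx] = old
            num = (lp - lm) / (2 * eps)
            ana = l.grads[name][idx]
            assert num == pytest.approx(ana, rel=rtol, abs=1e-8), (
                f"{type(l).__name__}.{name}{idx}: {ana} vs {num}"
            )


class TestDSConv:
    def test_param_count_closed_form(self):
        # depthwise 9*c_in + pointwise c_in*c_out, vs 9*c_in*c_out for full 3x3
        assert dsconv_param_count(32, 64) == 288 + 2048 == 2336
        assert 9 * 32 * 64 == 18432
        dw, pw = DepthwiseConv3x3(32), PointwiseConv(32, 64)
        assert dw.n_params() + pw.n_params() == 2336

    def test_delta_kernel_reduces_to_pointwise(self):
        """Centered-delta depthwise kernels make DSConv a pure 1x1 conv."""
        rng = np.random.default_rng(1)
        dw = _upcast(DepthwiseConv3x3(4, rng=rng))
        pw = _upcast(PointwiseConv(4, 6, rng=rng))
        dw.params["W"][:] = 0.0
        dw.params["W"][1, 1, :] = 1.0
        x = rng.normal(size=(2, 5, 5, 4))
        np.testing.assert_allclose(
            pw.forward(dw.forward(x)), pw.forward(x), atol=1e-12
        )

    def test_zero_input_gives_bias_only(self):
        pw = PointwiseConv(3, 2, bias=True)
        pw.params["b"][:] = np.array([0.5, -1.0], dtype=np.float32)
        y = pw.forward(np.zeros((1, 4, 4, 3), dtype=np.float32))
        np.testing.assert_allclose(y[0, 0, 0], [0.5, -1.0], atol=1e-7)

    @pytest.mark.parametrize("stride", [1, 2])
    def test_pointwise_gradients(self, stride):
        rng = np.random.default_rng(2)
        layer = _upcast(PointwiseConv(3, 5, stride=stride, bias=True, rng=rng))
        _gradcheck(layer, rng.normal(size=(2, 6, 6, 3)))

    def test_depthwise_gradients(self):
        rng = np.random.default_rng(3)
        _gradcheck(_upcast(DepthwiseConv3x3(3, rng=rng)), rng.normal(size=(2, 6, 6, 3)))

    def test_conv3x3_gradients(self):
        rng = np.random.default_rng(4)
        _gradcheck(_upcast(Conv3x3(3, 4, rng=rng)), rng.normal(size=(2, 5, 5, 3)))


class TestBatchNormAndPool:
    def test_batchnorm_gradients_training_mode(self):
        rng = np.random.default_rng(5)
        _gradcheck(_upcast(BatchNorm(4)), rng.normal(size=(3, 4, 4, 4)), rtol=1e-4)

    def test_batchnorm_eval_uses_debiased_running_stats(self):
        bn = _upcast(BatchNorm(2))
        rng = np.random.default_rng(6)
        x = rng.normal(loc=3.0, scale=2.0, size=(8, 5, 5, 2))
        for _ in range(50):
            bn.forward(x, training=True)
        y = bn.forward(x, training=False)
        # after convergence, eval output is standardized like train output
        assert abs(y.mean()) < 0.05 and abs(y.std() - 1.0) < 0.05

    def test_maxpool_forward_and_gradient(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(2, 4, 4, 3))
        pool = MaxPool2x2()
        y = pool.forward(x)
        assert y.shape == (2, 2, 2, 3)
        assert y[0, 0, 0, 0] == x[0, :2, :2, 0].max()
        R = rng.normal(size=y.shape)
        dx = pool.backward(R)
        # gradient routed only to the argmax of each window, sums preserved
        np.testing.assert_allclose(
            dx.reshape(2, 2, 2, 2, 2, 3).sum(axis=(2, 4)), R, atol=1e-12
        )

    def test_maxpool_rejects_odd(self):
        with pytest.raises(ValueError):
            MaxPool2x2().forward(np.zeros((1, 5, 4, 1)))


class TestNonlocal:
    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(8)
        block = _upcast(NonlocalBlock(2, rng=rng))
        for trial in range(3):
            x = rng.normal(size=(1, 5, 5, 2))
            fast = block.forward(x)[0]
            slow = nonlocal_reference(
                x[0], block.params["W_phi"], block.params["W_psi"], block.params["W_g"]
            )
            np.testing.assert_allclose(fast, slow, atol=1e-5)

    def test_attention_rows_stochastic(self):
        rng = np.random.default_rng(9)
        block = NonlocalBlock(3, rng=rng)
        block.forward(rng.normal(size=(2, 4, 4, 3)).astype(np.float32))
        rows = block.last_attention.sum(axis=2)
        np.testing.assert_allclose(rows, 1.0, atol=1e-6)

    def test_constant_features_average_to_g(self):
        """Identical feature vectors everywhere give r_i = g(v) at every i."""
        rng = np.random.default_rng(10)
        block = _upcast(NonlocalBlock(3, rng=rng))
        v = rng.normal(size=3)
        x = np.broadcast_to(v, (1, 4, 4, 3)).copy()
        out = block.forward(x)
        expected = v @ block.params["W_g"]
        np.testing.assert_allclose(out[0], np.broadcast_to(expected, (4, 4, 3)), atol=1e-10)

    def test_single_position_returns_g(self):
        rng = np.random.default_rng(11)
        block = _upcast(NonlocalBlock(4, rng=rng))
        x = rng.normal(size=(1, 1, 1, 4))
        np.testing.assert_allclose(
            block.forward(x)[0, 0, 0], x[0, 0, 0] @ block.params["W_g"], atol=1e-10
        )

    def test_two_position_scalar_hand_computed(self):
        """Scalar toy with identity kernels, positions (0, ln 3)."""
        block = _upcast(NonlocalBlock(1))
        for name in ("W_phi", "W_psi", "W_g"):
            block.params[name][:] = 1.0
        a = np.log(3.0)
        x = np.array([0.0, a]).reshape(1, 1, 2, 1)
        out = block.forward(x).ravel()
        # position 1: weights softmax(0, 0) = (1/2, 1/2) -> r = a/2
        r1 = a / 2
        # position 2: weights softmax(0, a^2) -> r = a e^{a^2} / (1 + e^{a^2})
        w2 = np.exp(a * a) / (1 + np.exp(a * a))
        r2 = w2 * a
        np.testing.assert_allclose(out, [r1, r2], atol=1e-12)
        assert r1 == pytest.approx(0.5493, abs=1e-4)

    def test_gradients(self):
        rng = np.random.default_rng(12)
        _gradcheck(_upcast(NonlocalBlock(2, rng=rng)), rng.normal(size=(2, 3, 3, 2)))


class TestBlocks:
    def test_dsr_shape_contract_full_scale(self):
        rng = np.random.default_rng(13)
        block = DSRBlock(1, 32, rng)
        y = block.forward(np.zeros((1, 144, 144, 1), dtype=np.float32))
        assert y.shape == (1, 72, 72, 32)

    def test_dsr_zero_weights_zero_output(self):
        rng = np.random.default_rng(14)
        block = DSRBlock(2, 4, rng)
        for layer in block.walk():
            for name in layer.params:
                if name != "gamma":
                    layer.params[name][:] = 0.0
        y = block.forward(np.random.default_rng(0).normal(size=(2, 8, 8, 2)).astype(np.float32))
        np.testing.assert_allclose(y, 0.0, atol=1e-7)

    def test_dsr_gradient_through_both_branches(self):
        """Numeric input-gradient check on an 8x8 toy (main + shortcut)."""
        rng = np.random.default_rng(15)
        block = _upcast(DSRBlock(2, 3, rng))
        x = rng.normal(size=(1, 8, 8, 2))
        R = rng.normal(size=(1, 4, 4, 3))
        block.forward(x, training=True)
        block.zero_grads()
        dx = block.backward(R)
        eps = 1e-6
        for _ in range(8):
            idx = tuple(rng.integers(0, s) for s in x.shape)
            old = x[idx]
            x[idx] = old + eps
            lp = float(np.sum(block.forward(x, training=True) * R))
            x[idx] = old - eps
            lm = float(np.sum(block.forward(x, training=True) * R))
            x[idx] = old
            assert (lp - lm) / (2 * eps) == pytest.approx(dx[idx], rel=1e-4, abs=1e-7)

    def test_dsr_rejects_odd_dims(self):
        block = DSRBlock(1, 2, np.random.default_rng(0))
        with pytest.raises(ValueError):
            block.forward(np.zeros((1, 7, 8, 1), dtype=np.float32))

    def test_nldr_shape_contract(self):
        rng = np.random.default_rng(16)
        block = NLDRBlock(4, 8, rng)
        y = block.forward(np.random.default_rng(1).normal(size=(2, 12, 12, 4)).astype(np.float32))
        assert y.shape == (2, 6, 6, 8)

    def test_nldr_with_zero_nonlocal_equals_dsr(self):
        """Zeroed attention value-kernel makes the nonlocal insert an identity,
        reducing NLDR to DSR with the same convolution weights."""
        rng = np.random.default_rng(17)
        nldr = NLDRBlock(2, 4, rng)
        nldr.main.children[2].nonlocal_op.params["W_g"][:] = 0.0
        dsr = DSRBlock(2, 4, np.random.default_rng(0))
        # copy shared-layer weights: two DSConv units and the shortcut
        for src, dst in zip(nldr.main.children[:2], dsr.main.children[:2]):
            for layer_s, layer_d in zip(src.walk(), dst.walk()):
                for name in layer_s.params:
                    layer_d.params[name] = layer_s.params[name].copy()
        dsr.shortcut.params["W"] = nldr.shortcut.params["W"].copy()
        x = np.random.default_rng(2).normal(size=(2, 8, 8, 2)).astype(np.float32)
        np.testing.assert_allclose(nldr.forward(x), dsr.forward(x), atol=1e-6)

    def test_nldr_finite_on_random_inputs(self):
        rng = np.random.default_rng(18)
        block = NLDRBlock(2, 4, rng)
        x = rng.normal(size=(100, 6, 6, 2)).astype(np.float32)
        assert np.all(np.isfinite(block.forward(x)))

    def test_nlr_zero_weights_identity(self):
        block = NLRBlock(3, np.random.default_rng(19))
        for name in block.nonlocal_op.params:
            block.nonlocal_op.params[name][:] = 0.0
        x = np.random.default_rng(3).normal(size=(2, 4, 4, 3)).astype(np.float32)
        np.testing.assert_allclose(block.forward(x), x, atol=1e-7)

    def test_nlr_shape_preserved_and_residual_exact(self):
        rng = np.random.default_rng(20)
        block = NLRBlock(8, rng)
        x = rng.normal(size=(1, 9, 9, 8)).astype(np.float32)
        y = block.forward(x)
        assert y.shape == x.shape
        np.testing.assert_allclose(y - x, block.nonlocal_op.forward(x), atol=1e-6)

    def test_clf_zero_weights_uniform(self):
        block = CLFBlock(4, np.random.default_rng(21))
        block.conv.params["W"][:] = 0.0
        block.conv.params["b"][:] = 0.0
        p = block.forward(np.random.default_rng(4).normal(size=(3, 4, 4, 4)).astype(np.float32))
        np.testing.assert_allclose(p, 1.0 / 3.0, atol=1e-7)

    def test_clf_logit_shift_invariance(self):
        block = CLFBlock(4, np.random.default_rng(22))
        x = np.random.default_rng(5).normal(size=(2, 4, 4, 4)).astype(np.float32)
        p0 = block.forward(x)
        block.conv.params["b"] += 7.0  # same constant on all three logits
        np.testing.assert_allclose(block.forward(x), p0, atol=1e-5)

    def test_clf_probabilities_sum_to_one(self):
        block = CLFBlock(3, np.random.default_rng(23))
        x = np.random.default_rng(6).normal(size=(100, 4, 4, 3)).astype(np.float32)
        np.testing.assert_allclose(block.forward(x).sum(axis=1), 1.0, atol=1e-6)


class TestModels:
    def test_sqa_shape_trace_full_scale(self):
        net = SQANet(NetSpec.full_scale(seed=0))
        probs, feats = net.forward(np.zeros((1, 144, 144), dtype=np.float32))
        assert probs.shape == (1, 3)
        assert feats.shape == (1, 9, 9, 256)  # 144 -> 72 -> 36 -> 18 -> 9

    def test_sqa_deterministic(self):
        net = SQANet(NetSpec.toy(seed=1))
        x = np.random.default_rng(7).uniform(0, 1, (2, 64, 64))
        p1, f1 = net.forward(x)
        p2, f2 = net.forward(x)
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_array_equal(f1, f2)

    def test_sqa_rejects_wrong_size(self):
        net = SQANet(NetSpec.toy(seed=0))
        with pytest.raises(ValueError):
            net.forward(np.zeros((1, 32, 32)))

    def test_same_seed_same_weights(self):
        a, b = SQANet(NetSpec.toy(seed=5)), SQANet(NetSpec.toy(seed=5))
        for (l1, n1, p1), (l2, n2, p2) in zip(a.parameter_items(), b.parameter_items()):
            np.testing.assert_array_equal(p1, p2)

    def test_vqa_single_slice_volume(self):
        spec = NetSpec.toy(seed=2)
        vqa = VQANet(spec, n_slices=1)
        feats = np.random.default_rng(8).normal(size=(2, 1, 4, 4, 64))
        p = vqa.forward(feats)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_vqa_slice_order_matters(self):
        """Concatenation preserves slice order; permutation may change output."""
        spec = NetSpec.toy(seed=3)
        vqa = VQANet(spec, n_slices=4)
        feats = np.random.default_rng(9).normal(size=(1, 4, 4, 4, 64))
        p0 = vqa.forward(feats)
        p1 = vqa.forward(feats[:, ::-1])
        assert not np.allclose(p0, p1)

    def test_vqa_rejects_mismatched_stack(self):
        vqa = VQANet(NetSpec.toy(seed=0), n_slices=4)
        with pytest.raises(ValueError):
            vqa.forward(np.zeros((1, 3, 4, 4, 64)))

    def test_checkpoint_roundtrip(self, tmp_path):
        net = SQANet(NetSpec.toy(seed=4))
        x = np.random.default_rng(10).uniform(0, 1, (2, 64, 64))
        net.forward(x, training=True)  # populate BN running stats
        p_ref = net.predict_proba(x)
        save_model(net, tmp_path / "sqa", extra={"stage": "test"})
        back = load_model(tmp_path / "sqa")
        np.testing.assert_array_equal(back.predict_proba(x), p_ref)

    def test_block_param_counts_match_closed_form(self):
        c_in, c_out = 8, 16
        block = DSRBlock(c_in, c_out, np.random.default_rng(24))
        expected = (
            dsconv_param_count(c_in, c_out) + dsconv_param_count(c_out, c_out)
            + 2 * 2 * c_out      # two BatchNorms: gamma + beta
            + c_in * c_out       # 1x1 strided shortcut
        )
        assert block.n_params() == expected
        nlr = NLRBlock(c_out, np.random.default_rng(25))
        assert nlr.n_params() == 3 * c_out * c_out
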