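"""Residual-network primitives and forward pass."""

import numpy as np
import pytest

from ecgmi.network import (NetworkSpec, ParamVector, ResBlockSpec, avgpool,
                           batch_norm, conv1d, conv2d, forward, make_preset,
                           maxpool, relu, residual_block)


class TestConv:
    def test_delta_kernel_identity(self):
        x = np.array([1.0, -2.0, 3.0, 4.0])
        assert np.allclose(conv1d(x, np.array([0.0, 1.0, 0.0])), x)

    def test_direct_summation_example(self):
        out = conv1d(np.array([1.0, 2.0, 3.0]), np.array([1.0, 1.0, 1.0]))
        assert np.allclose(out, [3.0, 6.0, 5.0])

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.standard_normal(rng.integers(5, 50))
            k = rng.standard_normal(3)
            out = conv1d(x, k)
            left = 1
            xp = np.pad(x, (left, 1))
            expect = np.array([np.sum(xp[i : i + 3] * k) for i in range(x.size)])
            assert np.allclose(out, expect, atol=1e-12)

    def test_linearity(self):
        rng = np.random.default_rng(1)
        x, y = rng.standard_normal(30), rng.standard_normal(30)
        k = rng.standard_normal(5)
        a, b = 2.5, -0.5
        assert np.allclose(conv1d(a * x + b * y, k),
                           a * conv1d(x, k) + b * conv1d(y, k), atol=1e-9)

    def test_conv2d_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((6, 7))
        k = rng.standard_normal((3, 3))
        out = conv2d(x, k)
        expect = np.array([[np.sum(x[i : i + 3, j : j + 3] * k)
                            for j in range(5)] for i in range(4)])
        assert np.allclose(out, expect, atol=1e-12)

    def test_shape_mismatch_reported(self):
        with pytest.raises(ValueError, match="shape"):
            conv1d(np.ones((2, 3)), np.ones(3))


def test_relu_branches():
    assert relu(np.array([-1.0]))[0] == 0.0
    assert relu(np.array([2.0]))[0] == 2.0
    assert relu(np.array([0.0]))[0] == 0.0


class TestPooling:
    def test_maxpool_example(self):
        assert np.allclose(maxpool(np.array([1.0, 3.0, 2.0, 5.0]), 2), [3.0, 5.0])

    def test_constant_preserved_by_both(self):
        x = np.full(9, 2.0)
        assert np.allclose(maxpool(x, 2), 2.0)
        assert np.allclose(avgpool(x, 2), 2.0)

    def test_trailing_partial_window_kept(self):
        out = maxpool(np.array([1.0, 2.0, 3.0, 4.0, 9.0]), 2)
        assert np.allclose(out, [2.0, 4.0, 9.0])

    def test_maxpool_dominates_avgpool(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(40)
        assert np.all(maxpool(x, 4) >= avgpool(x, 4) - 1e-12)

    def test_invalid_size(self):
        with pytest.raises(ValueError):
            maxpool(np.ones(4), 0)


class TestBatchNorm:
    def test_unit_gain_zero_shift_standardises(self):
        rng = np.random.default_rng(0)
        batch = rng.standard_normal((8, 3, 20)) * 4 + 2
        out = batch_norm(batch, np.ones(3), np.zeros(3))
        assert np.allclose(out.mean(axis=(0, 2)), 0.0, atol=1e-9)
        assert np.allclose(out.var(axis=(0, 2)), 1.0, atol=1e-3)

    def test_identical_rows_collapse_to_beta(self):
        batch = np.tile(np.arange(12.0).reshape(1, 3, 4), (5, 1, 1))
        batch = np.ones_like(batch)  # zero variance everywhere
        beta = np.array([1.0, -2.0, 0.5])
        out = batch_norm(batch, np.ones(3), beta)
        assert np.allclose(out, beta[None, :, None], atol=1e-2)

    def test_matching_gain_shift_is_identity(self):
        rng = np.random.default_rng(1)
        batch = rng.standard_normal((6, 2, 30)) * 3 + 1
        mu = batch.mean(axis=(0, 2))
        sd = batch.std(axis=(0, 2))
        out = batch_norm(batch, sd, mu)
        assert np.allclose(out, batch, atol=1e-4)


class TestResidualBlock:
    def test_zero_mapping_identity_shortcut(self):
        spec = ResBlockSpec(3, 3)
        net = NetworkSpec(input_len=16, stem_channels=3, blocks=[spec])
        params = ParamVector.zeros(net)
        rng = np.random.default_rng(0)
        x = rng.standard_normal((4, 3, 8))
        out = residual_block(x, params, "block0", spec, activation=False)
        assert np.allclose(out, x)

    def test_composition_matches_reference(self):
        spec = ResBlockSpec(2, 4)
        net = NetworkSpec(input_len=16, stem_channels=2, blocks=[spec])
        params = ParamVector.zeros(net)
        rng = np.random.default_rng(7)
        params.flat[:] = rng.uniform(-1, 1, params.flat.size)
        x = rng.standard_normal((3, 2, 10))
        out = residual_block(x, params, "block0", spec)

        from ecgmi.network import _multi_conv
        h = _multi_conv(x, params.get("block0.conv1.w"), params.get("block0.conv1.b"))
        h = relu(batch_norm(h, params.get("block0.bn1.gamma"), params.get("block0.bn1.beta")))
        h = _multi_conv(h, params.get("block0.conv2.w"), params.get("block0.conv2.b"))
        h = batch_norm(h, params.get("block0.bn2.gamma"), params.get("block0.bn2.beta"))
        sc = _multi_conv(x, params.get("block0.proj.w"), params.get("block0.proj.b"))
        assert np.allclose(out, relu(h + sc), atol=1e-12)


class TestForward:
    def test_probabilities_sum_to_one(self):
        spec = make_preset("tiny", 20)
        rng = np.random.default_rng(0)
        params = rng.uniform(-1, 1, ParamVector.zeros(spec).flat.size)
        probs = forward(spec, params, rng.standard_normal((7, 20)))
        assert probs.shape == (7, 2)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(probs >= 0)

    def test_zero_params_uniform_output(self):
        spec = make_preset("tiny", 12)
        probs = forward(spec, ParamVector.zeros(spec), np.random.default_rng(1).standard_normal((5, 12)))
        assert np.allclose(probs, 0.5)

    def test_flatten_unflatten_roundtrip_bit_identical(self):
        spec = make_preset("tiny", 16)
        rng = np.random.default_rng(2)
        flat = rng.uniform(-1, 1, ParamVector.zeros(spec).flat.size)
        pv = ParamVector.from_flat(spec, flat)
        assert np.array_equal(pv.flat, flat)
        X = rng.standard_normal((4, 16))
        assert np.array_equal(forward(spec, flat, X), forward(spec, pv, X))

    def test_wrong_param_length_rejected(self):
        spec = make_preset("tiny", 16)
        with pytest.raises(ValueError, match="length"):
            forward(spec, np.zeros(10), np.zeros((2, 16)))

    def test_wrong_feature_length_rejected(self):
        spec = make_preset("tiny", 16)
        with pytest.raises(ValueError, match="length"):
            forward(spec, ParamVector.zeros(spec), np.zeros((2, 10)))


class TestPresets:
    @pytest.mark.parametrize("name,limit", [("tiny", 1000), ("small", 20000)])
    def test_parameter_budgets(self, name, limit):
        spec = make_preset(name, 194)
        assert spec.n_params() <= limit

    def test_count_matches_layout_enumeration(self):
        for name in ("tiny", "base", "small"):
            spec = make_preset(name, 64)
            total = sum(int(np.prod(s)) for _n, s in spec.param_layout())
            assert spec.n_params() == total == ParamVector.zeros(spec).flat.size

    def test_save_load_roundtrip(self, tmp_path):
        from ecgmi.network import load_params, save_params
        spec = make_preset("tiny", 24)
        rng = np.random.default_rng(3)
        pv = ParamVector.from_flat(spec, rng.uniform(-1, 1, spec.n_params()))
        save_params(spec, pv, tmp_path / "spec.json", tmp_path / "w.csv")
        spec2, pv2 = load_params(tmp_path / "spec.json", tmp_path / "w.csv")
        assert spec2.n_params() == spec.n_params()
        X = rng.standard_normal((3, 24))
        assert np.allclose(forward(spec, pv, X), forward(spec2, pv2, X), atol=1e-12)
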