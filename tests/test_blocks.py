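"""Backbone blocks: shape contracts, ADown oracle, OREPA squeeze equivalence."""

import numpy as np
import pytest

from germinet import blocks, nn
from germinet.nn import tensor as T


def _rand_input(rng, c, h, w, n=1):
    return T.Tensor(rng.normal(size=(n, c, h, w)).astype(np.float32))


def _randomize_bn(module, rng):
    """Give every batch-norm non-trivial running statistics."""
    for m in module.modules():
        if isinstance(m, nn.BatchNorm2d):
            m.running_mean[:] = rng.normal(0, 0.5, m.running_mean.shape)
            m.running_var[:] = rng.uniform(0.5, 2.0, m.running_var.shape)


def test_cbs_conv_param_count_and_stride(rng):
    conv = nn.Conv2d(3, 16, 3, bias=False)
    assert conv.weight.size == 432  # Cin * K^2 * Cout
    cbs = blocks.CBS(3, 16, 3, 2).eval()
    with T.no_grad():
        out = cbs(_rand_input(rng, 3, 64, 64))
    assert out.shape == (1, 16, 32, 32)


def test_cbs_zero_input_constant_over_space(rng):
    cbs = blocks.CBS(3, 8, 3, 1).eval()
    _randomize_bn(cbs, rng)
    with T.no_grad():
        out = cbs(T.Tensor(np.zeros((1, 3, 10, 10), np.float32))).data
    assert np.allclose(out, out[:, :, :1, :1], atol=1e-6)


class TestADown:
    def test_shape_contract(self, rng):
        ad = blocks.ADown(64, 128).eval()
        with T.no_grad():
            out = ad(_rand_input(rng, 64, 80, 80))
        assert out.shape == (1, 128, 40, 40)

    def test_odd_channels_rejected(self):
        with pytest.raises(ValueError):
            blocks.ADown(63, 128)

    def test_constant_input_passes_average_pool_unchanged(self, rng):
        ad = blocks.ADown(8, 16).eval()
        x = T.Tensor(np.full((1, 8, 16, 16), 3.7, np.float32))
        with T.no_grad():
            pooled = T.avg_pool2d(x, 2, 1, 0)
        assert np.allclose(pooled.data, 3.7, atol=1e-6)
        h1, h2 = T.chunk(pooled, 2, axis=1)
        np.testing.assert_array_equal(h1.data, h2.data)

    def test_independent_reference_implementation(self, rng):
        """Plain-numpy re-implementation of the two-branch layout."""
        ad = blocks.ADown(16, 24).eval()
        _randomize_bn(ad, rng)
        x = rng.normal(size=(2, 16, 12, 12)).astype(np.float32)
        with T.no_grad():
            out = ad(T.Tensor(x)).data

        def silu(v):
            return v / (1 + np.exp(-v))

        def conv(v, w, s, p):
            vp = np.pad(v, ((0, 0), (0, 0), (p, p), (p, p)))
            co, ci, kh, kw = w.shape
            n, _, hp, wp = vp.shape
            ho, wo = (hp - kh) // s + 1, (wp - kw) // s + 1
            r = np.zeros((n, co, ho, wo), np.float32)
            for i in range(ho):
                for j in range(wo):
                    patch = vp[:, :, i * s:i * s + kh, j * s:j * s + kw]
                    r[:, :, i, j] = np.tensordot(patch, w, axes=([1, 2, 3], [1, 2, 3]))
            return r

        def bn(v, m):
            sc = m.weight.data / np.sqrt(m.running_var + m.eps)
            return v * sc[None, :, None, None] + (m.bias.data - m.running_mean * sc)[None, :, None, None]

        # avg pool 2x2 stride 1
        ap = (x[:, :, :-1, :-1] + x[:, :, 1:, :-1] + x[:, :, :-1, 1:] + x[:, :, 1:, 1:]) / 4
        x1, x2 = ap[:, :8], ap[:, 8:]
        b1 = silu(bn(conv(x1, ad.cv1.conv.weight.data, 2, 1), ad.cv1.bn))
        # max pool 3x3 stride 2 pad 1
        xp = np.pad(x2, ((0, 0), (0, 0), (1, 1), (1, 1)), constant_values=-np.inf)
        n, c, hp, wp = xp.shape
        ho = (hp - 3) // 2 + 1
        mp = np.zeros((n, c, ho, ho), np.float32)
        for i in range(ho):
            for j in range(ho):
                mp[:, :, i, j] = xp[:, :, 2 * i:2 * i + 3, 2 * j:2 * j + 3].max(axis=(2, 3))
        b2 = silu(bn(conv(mp, ad.cv2.conv.weight.data, 1, 0), ad.cv2.bn))
        ref = np.concatenate([b1, b2], axis=1)
        np.testing.assert_allclose(out, ref, atol=1e-5)


class TestGelan:
    def test_spatial_dims_preserved(self, rng):
        g = blocks.RepNCSPELAN4(32, 48, 32, 16).eval()
        with T.no_grad():
            assert g(_rand_input(rng, 32, 20, 20)).shape == (1, 48, 20, 20)

    def test_identity_computation_blocks_degenerate(self, rng):
        """With identity comp blocks the output is the transition of the
        concatenated split halves only."""
        nn.manual_seed(11)
        g = blocks.RepNCSPELAN4(32, 48, 32, 16)
        g.cv2 = nn.Identity()   # whole computation chains become identity
        g.cv3 = nn.Identity()   # (valid because c4 == c3 // 2)
        g.eval()
        x = _rand_input(rng, 32, 9, 9)
        with T.no_grad():
            out = g(x)
            y0, y1 = T.chunk(g.cv1(x), 2, axis=1)
            ref = g.cv4(T.concat([y0, y1, y1, y1], axis=1))
        np.testing.assert_allclose(out.data, ref.data, atol=1e-6)

    def test_swapping_identical_computation_blocks_is_invariant(self, rng):
        nn.manual_seed(5)
        g = blocks.RepNCSPELAN4(32, 48, 32, 16).eval()
        g.cv3.load_state_dict(g.cv2.state_dict())  # symmetric channel plan
        x = _rand_input(rng, 32, 9, 9)
        with T.no_grad():
            before = g(x).data.copy()
        g.cv2, g.cv3 = g.cv3, g.cv2
        with T.no_grad():
            after = g(x).data
        np.testing.assert_allclose(before, after, atol=1e-6)

    def test_odd_split_rejected(self):
        with pytest.raises(ValueError):
            blocks.RepNCSPELAN4(32, 48, 31, 16)


class TestOrepa:
    def _block(self, rng, c1=12, c2=20, mid=36):
        o = blocks.Orepa(c1, c2, 3, 1, mid=mid)
        _randomize_bn(o, rng)
        for s in (o.s_origin, o.s_1x1, o.s_seq, o.s_avg):
            s.data[...] = rng.uniform(0.1, 1.0, s.shape)
        return o.eval()

    def test_zero_scaling_annihilates_prenorm_sum(self, rng):
        o = self._block(rng)
        for s in (o.s_origin, o.s_1x1, o.s_seq, o.s_avg):
            s.data[...] = 0.0
        x = _rand_input(rng, 12, 7, 7)
        with T.no_grad():
            outs = o.branch_outputs(x)
            total = sum(out.data * s.data[None, :, None, None]
                        for out, s in zip(outs, (o.s_origin, o.s_1x1, o.s_seq, o.s_avg)))
        assert np.abs(total).max() == 0.0

    def test_single_branch_equals_plain_conv(self, rng):
        o = self._block(rng)
        o.s_origin.data[...] = 1.0
        for s in (o.s_1x1, o.s_seq, o.s_avg):
            s.data[...] = 0.0
        # neutral normalization
        o.bn.running_mean[:] = 0.0
        o.bn.running_var[:] = 1.0 - o.bn.eps
        o.bn.weight.data[...] = 1.0
        o.bn.bias.data[...] = 0.0
        x = _rand_input(rng, 12, 7, 7)
        with T.no_grad():
            out = o(x)
            ref = T.conv2d(x, o.w_origin, None, 1, 1).silu()
        np.testing.assert_allclose(out.data, ref.data, atol=1e-5)

    def test_parallel_kernel_hand_composition(self, rng):
        """3x3 + center-padded 1x1 composition, verified on a 5x5 input."""
        o = self._block(rng, c1=2, c2=3, mid=4)
        for s in (o.s_seq, o.s_avg):
            s.data[...] = 0.0
        o.s_origin.data[...] = 1.0
        o.s_1x1.data[...] = 1.0
        k = o.equivalent_kernel()
        manual = o.w_origin.data.astype(np.float64).copy()
        manual[:, :, 1, 1] += o.w_1x1.data[:, :, 0, 0]
        np.testing.assert_allclose(k, manual, atol=1e-7)
        x = _rand_input(rng, 2, 5, 5)
        with T.no_grad():
            two_branch = (T.conv2d(x, o.w_origin, None, 1, 1).data
                          + T.conv2d(x, o.w_1x1, None, 1, 0).data)
            one_conv = T.conv2d(x, T.Tensor(k), None, 1, 1).data
        np.testing.assert_allclose(two_branch, one_conv, atol=1e-5)

    def test_squeeze_equivalence_and_param_drop(self, rng):
        for _ in range(10):
            c1, c2 = int(rng.integers(4, 24)) * 2, int(rng.integers(4, 24))
            o = self._block(rng, c1=c1, c2=c2, mid=int(rng.integers(4, 64)))
            x = _rand_input(rng, c1, 9, 9, n=2)
            with T.no_grad():
                before = o(x).data.copy()
            p_before = o.num_params()
            o.squeeze()
            with T.no_grad():
                after = o(x).data
            assert np.abs(before - after).max() < 1e-4
            assert o.num_params() < p_before

    def test_squeeze_idempotent_with_warning(self, rng):
        o = self._block(rng)
        o.squeeze()
        with pytest.warns(UserWarning):
            o.squeeze()

    def test_train_form_unavailable_after_squeeze(self, rng):
        o = self._block(rng)
        o.squeeze()
        with pytest.raises(RuntimeError):
            o.branch_outputs(_rand_input(rng, 12, 7, 7))


class TestOrepaGelan:
    def test_squeezed_matches_train_form(self, rng):
        nn.manual_seed(2)
        g = blocks.orepa_gelan(32, 48, 32, 16, mid1=40, mid2=24)
        _randomize_bn(g, rng)
        g.eval()
        x = _rand_input(rng, 32, 11, 11)
        with T.no_grad():
            before = g(x).data.copy()
        p_before = g.num_params()
        n = blocks.squeeze_all(g)
        assert n == 2
        with T.no_grad():
            after = g(x).data
        assert np.abs(before - after).max() < 1e-4
        assert g.num_params() < p_before
        with T.no_grad():
            assert g(x).shape == (1, 48, 11, 11)
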