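"""Capsule-network blocks: shapes, attention contracts, routing oracle."""

import numpy as np
import pytest

import eegcaps as eg
from eegcaps.capsnet import (
    CapsNetConfig,
    CapsuleEncoder,
    DynamicRouting,
    ECABlock,
    SEBlock,
    eca_kernel_size,
    squash,
)
from eegcaps.nn import Tensor, cross_entropy

RNG = np.random.default_rng(0)


def routing_oracle(W, u, n_out, d_out, iters):
    """Straight-line reimplementation of routing by agreement (one sample)."""
    n, d_in = u.shape
    uhat = np.empty((n, n_out, d_out))
    for i in range(n):
        for j in range(n_out):
            uhat[i, j] = W[i, j] @ u[i]
    b = np.zeros((n, n_out))
    v = None
    for it in range(iters):
        c = np.exp(b) / np.exp(b).sum(axis=1, keepdims=True)
        s = np.zeros((n_out, d_out))
        for j in range(n_out):
            for i in range(n):
                s[j] += c[i, j] * uhat[i, j]
        v = np.empty_like(s)
        for j in range(n_out):
            nrm2 = float(s[j] @ s[j])
            nrm = np.sqrt(nrm2 + 1e-12)
            v[j] = (nrm2 / (1 + nrm2)) * s[j] / nrm
        if it + 1 < iters:
            for i in range(n):
                for j in range(n_out):
                    b[i, j] += uhat[i, j] @ v[j]
    return v


class TestEcaKernel:
    @pytest.mark.parametrize("C,expected", [(256, 5), (2, 1), (64, 3), (128, 5),
                                            (512, 5), (32, 3)])
    def test_standard_offsets(self, C, expected):
        assert eca_kernel_size(C, gamma=2.0, b=1.0) == expected

    def test_always_odd_and_positive(self):
        for C in range(1, 1025):
            k = eca_kernel_size(C)
            assert k % 2 == 1 and k >= 1


class TestECABlock:
    def test_shape_preserved(self):
        blk = ECABlock(16, RNG)
        x = Tensor(RNG.standard_normal((2, 16, 5, 6)))
        assert blk(x).shape == x.shape

    def test_zero_weights_halve_input(self):
        blk = ECABlock(16, RNG)
        blk.weight.data[:] = 0.0
        x = Tensor(RNG.standard_normal((2, 16, 5, 6)))
        assert np.allclose(blk(x).data, x.data / 2)

    def test_k1_permutation_equivariance(self):
        blk = ECABlock(2, RNG)  # C=2 -> k=1
        assert blk.k == 1
        x = RNG.standard_normal((1, 2, 3, 3))
        perm = [1, 0]
        out = blk(Tensor(x)).data
        out_p = blk(Tensor(x[:, perm])).data
        assert np.allclose(out_p, out[:, perm])


class TestSEBlock:
    def test_shape_preserved(self):
        blk = SEBlock(32, RNG, reduction=8)
        x = Tensor(RNG.standard_normal((2, 32, 4, 5)))
        assert blk(x).shape == x.shape

    def test_zero_weights_halve_input(self):
        blk = SEBlock(32, RNG, reduction=8)
        blk.fc1.weight.data[:] = 0.0
        blk.fc2.weight.data[:] = 0.0
        x = Tensor(RNG.standard_normal((2, 32, 4, 5)))
        assert np.allclose(blk(x).data, x.data / 2)

    def test_zero_input_stays_zero(self):
        blk = SEBlock(32, RNG, reduction=8)
        out = blk(Tensor(np.zeros((1, 32, 4, 5))))
        assert not out.data.any()

    def test_reduction_larger_than_channels(self):
        with pytest.raises(ValueError):
            SEBlock(8, RNG, reduction=16)


class TestSquash:
    def test_zero_maps_to_zero(self):
        assert not squash(Tensor(np.zeros((1, 8)))).data.any()

    def test_unit_norm_halves(self):
        s = np.zeros((1, 8))
        s[0, 0] = 1.0
        v = squash(Tensor(s)).data
        assert np.isclose(np.linalg.norm(v), 0.5)

    def test_norm_monotone_and_direction_preserved(self):
        direction = RNG.standard_normal(8)
        direction /= np.linalg.norm(direction)
        norms = []
        for scale in (0.1, 0.5, 1.0, 5.0, 50.0):
            v = squash(Tensor(scale * direction[None])).data[0]
            norms.append(np.linalg.norm(v))
            assert np.allclose(v / np.linalg.norm(v), direction)
        assert norms == sorted(norms)
        assert norms[-1] < 1.0


class TestRouting:
    def test_uniform_couplings_at_init(self):
        r = DynamicRouting(5, 4, 3, 6, iters=2, rng=RNG)
        u = Tensor(RNG.standard_normal((2, 5, 4)))
        _, couplings = r(u, return_couplings=True)
        assert np.allclose(couplings[0], 1.0 / 3.0)

    def test_couplings_normalize_every_iteration(self):
        r = DynamicRouting(7, 4, 2, 5, iters=4, rng=RNG)
        u = Tensor(RNG.standard_normal((3, 7, 4)))
        _, couplings = r(u, return_couplings=True)
        assert len(couplings) == 4
        for c in couplings:
            assert np.allclose(c.sum(axis=2), 1.0)

    def test_matches_straightline_oracle(self):
        n, d_in, n_out, d_out, iters = 3, 8, 2, 16, 2
        r = DynamicRouting(n, d_in, n_out, d_out, iters=iters, rng=RNG,
                           init_scale=0.2)
        W = r.weight.data.reshape(n, n_out, d_out, d_in)
        u = RNG.standard_normal((1, n, d_in)) * 0.5
        v = r(Tensor(u)).data[0]
        expected = routing_oracle(W, u[0], n_out, d_out, iters)
        assert np.abs(v - expected).max() < 1e-6

    def test_single_iteration_closed_form(self):
        n, d_in, n_out, d_out = 4, 3, 2, 5
        r = DynamicRouting(n, d_in, n_out, d_out, iters=1, rng=RNG)
        u = RNG.standard_normal((1, n, d_in))
        W = r.weight.data.reshape(n, n_out, d_out, d_in)
        uhat = np.einsum("ijkl,il->ijk", W, u[0])
        s = uhat.sum(axis=0) / n_out  # uniform couplings 1/J
        expected = np.stack([
            (sj @ sj / (1 + sj @ sj)) * sj / np.sqrt(sj @ sj + 1e-12) for sj in s
        ])
        assert np.allclose(r(Tensor(u)).data[0], expected)


class TestEncoder:
    def test_published_width_shapes(self):
        cfg = CapsNetConfig()  # 256 planes, 32 x 8D capsules
        enc = CapsuleEncoder(cfg, np.random.default_rng(1))
        x = Tensor(RNG.standard_normal((1, 3, 16, 18)))
        h = enc.conv(x).relu()
        assert h.shape == (1, 256, 7, 8)
        assert np.all(h.data >= 0)
        assert enc.n_primary == 32 * 5 * 6 == 960
        u = enc.primary(h)
        assert u.shape == (1, 960, 8)
        assert np.all(np.linalg.norm(u.data, axis=2) < 1.0)
        v = enc(x)
        assert v.shape == (1, 2, 16)
        norms = np.linalg.norm(v.data, axis=2)
        assert np.all((norms >= 0) & (norms < 1.0))

    def test_zero_input_zero_bias_gives_zero_conv(self):
        cfg = CapsNetConfig()
        enc = CapsuleEncoder(cfg, np.random.default_rng(1))
        out = enc.conv(Tensor(np.zeros((1, 3, 16, 18)))).relu()
        assert not out.data.any()

    def test_wrong_input_shape(self):
        enc = CapsuleEncoder(CapsNetConfig(), np.random.default_rng(1))
        with pytest.raises(ValueError):
            enc(Tensor(np.zeros((1, 3, 8, 9))))

    def test_forward_deterministic(self):
        enc = CapsuleEncoder(
            CapsNetConfig(conv_out_channels=32, primary_caps_channels=4,
                          se_reduction=8),
            np.random.default_rng(2))
        x = RNG.standard_normal((2, 3, 16, 18))
        assert np.array_equal(enc(Tensor(x)).data, enc(Tensor(x)).data)

    def test_invalid_width_combination(self):
        with pytest.raises(ValueError):
            CapsNetConfig(conv_out_channels=128)  # 32*8 != 128

    def test_gradients_reach_every_parameter(self):
        cfg = eg.reduced_width_config(seed=0)
        model = eg.EmotionCapsTransformer(cfg)
        x = RNG.standard_normal((4, 4, 3, 16, 18))
        y = np.array([0, 1, 0, 1])
        loss = cross_entropy(model.forward(x), y)
        model.zero_grad()
        loss.backward()
        for name, p in model.named_parameters():
            assert p.grad is not None, name
            assert np.abs(p.grad).max() > 0, name
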