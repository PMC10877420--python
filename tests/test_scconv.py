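"""SCConv: group normalization, SRU gating/reconstruction, CRU fusion."""

import numpy as np
import pytest

from micropest import nn
from micropest.scconv import CRU, SCConvBlock, SRU, group_normalize


class TestGroupNormalize:
    def test_constant_input_maps_to_zero(self):
        x = np.full((1, 4, 3, 3), 7.0)
        out = group_normalize(x, num_groups=2)
        assert np.abs(out).max() < 1e-2  # (x-mu)=0 up to eps damping

    def test_standardize_known_values(self):
        # single group over [1,2,3,4]: population variance 1.25
        x = np.array([1.0, 2.0, 3.0, 4.0]).reshape(1, 1, 1, 4)
        out = group_normalize(x, num_groups=1, eps=1e-12).ravel()
        expected = (np.array([1, 2, 3, 4]) - 2.5) / np.sqrt(1.25)
        assert np.allclose(out, expected, atol=1e-4)
        assert np.allclose(out, [-1.3416, -0.4472, 0.4472, 1.3416], atol=1e-4)

    def test_gamma_zero_yields_beta(self, rng):
        x = rng.normal(size=(2, 4, 3, 3))
        out = group_normalize(x, 2, gamma=np.zeros(4), beta=np.full(4, 0.7))
        assert np.allclose(out, 0.7)


class TestSRU:
    def test_output_shape_conserved(self, rng):
        sru = SRU(8)
        x = nn.Tensor(rng.normal(size=(2, 8, 5, 5)))
        out = sru(x)
        assert out.shape == x.shape

    def test_gate_partitions_channels(self, rng):
        sru = SRU(8)
        sru.gn.gamma.data[:] = rng.normal(size=8)
        gate = sru.gate()
        assert gate.channel_weights.sum() == pytest.approx(1.0)
        assert np.all(gate.informative_mask ^ gate.noninformative_mask)

    def test_dominant_channel_lands_in_informative_stream(self):
        sru = SRU(4, gn_groups=1)
        sru.gn.gamma.data[:] = [10.0, 0.1, 0.1, 0.1]
        gate = sru.gate()
        assert gate.informative_mask[0]
        assert not gate.informative_mask[1:].any()
        # trace a 4-channel toy input: stream 1 carries only channel 0 content
        x = nn.Tensor(np.arange(4 * 4, dtype=float).reshape(1, 4, 2, 2))
        xn = sru.gn(x).data
        w = np.abs(sru.gn.gamma.data) / np.abs(sru.gn.gamma.data).sum()
        x1_expected = xn * (w * gate.informative_mask).reshape(1, 4, 1, 1)
        out = sru(x).data
        # cross-reconstruction: out[:, :2] = x1[:, :2] + x2[:, 2:]
        x2_expected = xn * (w * gate.noninformative_mask).reshape(1, 4, 1, 1)
        assert np.allclose(out[:, :2], x1_expected[:, :2] + x2_expected[:, 2:], atol=1e-12)
        assert np.allclose(out[:, 2:], x1_expected[:, 2:] + x2_expected[:, :2], atol=1e-12)

    def test_reconstruction_conserves_weighted_mass(self, rng):
        sru = SRU(8)
        sru.gn.gamma.data[:] = rng.normal(size=8)
        x = nn.Tensor(rng.normal(size=(3, 8, 4, 4)))
        out = sru(x)
        xn = sru.gn(x).data
        w = np.abs(sru.gn.gamma.data) / np.abs(sru.gn.gamma.data).sum()
        assert out.data.sum() == pytest.approx((xn * w.reshape(1, 8, 1, 1)).sum(), abs=1e-6)

    def test_odd_channel_count_rejected(self, rng):
        sru = SRU(3, gn_groups=1)
        with pytest.raises(ValueError):
            sru(nn.Tensor(rng.normal(size=(1, 3, 2, 2))))


class TestCRU:
    def test_beta_normalization(self, rng):
        cru = CRU(8, rng=rng)
        _, state = cru(nn.Tensor(rng.normal(size=(2, 8, 4, 4))), return_state=True)
        assert np.allclose(state.beta1 + state.beta2, 1.0, atol=1e-15)
        assert np.all((state.beta1 > 0) & (state.beta1 < 1))

    def test_equal_pooled_scores_give_half_half(self, rng):
        cru = CRU(4, gwc_groups=1, rng=rng)
        # zero all transforms: Y1 = 0 and PWC2 part of Y2 = 0; pooled scores
        # then agree wherever both are zero
        for conv in (cru.gwc, cru.pwc1, cru.pwc2, cru.squeeze_low):
            conv.zero_()
        _, state = cru(nn.Tensor(rng.normal(size=(1, 4, 2, 2))), return_state=True)
        assert np.allclose(state.beta1, 0.5)
        assert np.allclose(state.beta2, 0.5)

    def test_worked_convex_combination_on_1x1_input(self):
        """2-channel 1x1-spatial example pushed through split/transform/fuse
        by hand."""
        cru = CRU(2, squeeze_ratio=1, gwc_groups=1, gwc_kernel=1,
                  rng=np.random.default_rng(0))
        # squeezes become identity 1x1 convs
        cru.squeeze_up.weight.data[:] = 1.0
        cru.squeeze_low.weight.data[:] = 1.0
        cru.gwc.weight.data[:] = np.array([[[[1.0]]], [[[0.0]]]])   # ch0 <- up
        cru.pwc1.weight.data[:] = np.array([[[[0.0]]], [[[1.0]]]])  # ch1 <- up
        cru.pwc2.weight.data[:] = 1.0                               # ch0 of Y2 <- low
        x = nn.Tensor(np.array([2.0, 3.0]).reshape(1, 2, 1, 1))
        y, state = cru(x, return_state=True)
        y1 = np.array([2.0, 2.0])       # [gwc(up), pwc1(up)]
        y2 = np.array([3.0, 3.0])       # [pwc2(low), low]
        e1, e2 = np.exp(y1), np.exp(y2)
        expected = (e1 * y1 + e2 * y2) / (e1 + e2)
        assert np.allclose(y.data.ravel(), expected, atol=1e-12)

    def test_channel_mismatch_configuration_error(self):
        with pytest.raises(ValueError):
            CRU(4, split_ratio=0.5, squeeze_ratio=1, gwc_groups=3)


class TestSCConvBlock:
    @pytest.mark.parametrize("shape", [(1, 8, 4, 4), (2, 16, 8, 8), (3, 32, 6, 6)])
    def test_shape_conserved(self, rng, shape):
        blk = SCConvBlock(shape[1], rng=rng)
        out = blk(nn.Tensor(rng.normal(size=shape)))
        assert out.shape == shape

    def test_zeroed_operators_reduce_to_identity(self, rng):
        blk = SCConvBlock(8, rng=rng)
        blk.restore.zero_()
        x = nn.Tensor(rng.normal(size=(2, 8, 4, 4)))
        assert np.allclose(blk(x).data, x.data)

    def test_gradient_flows_to_input(self, rng):
        blk = SCConvBlock(8, rng=rng)
        x = nn.Tensor(rng.normal(size=(1, 8, 4, 4)), requires_grad=True)
        (blk(x) ** 2).mean().backward()
        assert np.all(np.isfinite(x.grad))
        assert np.abs(x.grad).max() > 0


def test_random_configuration_sweep():
    """Shape conservation, beta normalization, GN standardization and gate
    partition over 200 random configurations."""
    rng = np.random.default_rng(2024)
    for _ in range(200):
        c = int(rng.choice([8, 16, 32]))
        n = int(rng.integers(1, 3))
        hw = int(rng.choice([4, 6, 8]))
        blk = SCConvBlock(c, gn_groups=int(rng.choice([1, 2, 4])), rng=rng)
        blk.sru.gn.gamma.data[:] = rng.normal(size=c // 2)
        x = nn.Tensor(rng.normal(size=(n, c, hw, hw)))
        out = blk(x)
        assert out.shape == x.shape
        assert np.all(np.isfinite(out.data))
        gate = blk.sru.gate()
        assert np.all(gate.informative_mask ^ gate.noninformative_mask)
        _, state = blk.cru(blk.sru(blk.compress(x)), return_state=True)
        assert np.allclose(state.beta1 + state.beta2, 1.0, atol=1e-12)
        y = blk.sru.gn(blk.compress(x)).data
        gamma = blk.sru.gn.gamma.data.reshape(1, -1, 1, 1)
        beta = blk.sru.gn.beta.data.reshape(1, -1, 1, 1)
        xhat = np.where(np.abs(gamma) > 1e-12, (y - beta) / gamma, 0.0)
        g = blk.sru.gn.num_groups
        xg = xhat.reshape(n, g, -1)
        assert np.abs(xg.mean(axis=-1)).max() < 1e-6
        assert np.abs(xg.var(axis=-1) - 1.0).max() < 1e-4
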