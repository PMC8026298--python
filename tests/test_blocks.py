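"""Block-level correctness: RFU, self-attention, SE gate, SCA fusion, SEPP."""

import numpy as np
import pytest

from vesselseg import autodiff as ad
from vesselseg import blocks
from vesselseg.autodiff import Tensor

from oracles import bilinear_upsample_oracle, sca_fuse_oracle, self_attention_oracle


def _f64(module):
    """Cast a module's parameters to float64 for tight oracle comparisons."""
    for p in module.parameters():
        p.data = p.data.astype(np.float64)
    return module


# -- RFU ----------------------------------------------------------------------

def test_rfu_outputs_nonnegative_and_shape(rng):
    rfu = blocks.RFU(2, 5, np.random.default_rng(0))
    out = rfu(Tensor(rng.standard_normal((3, 2, 8, 8)).astype(np.float32)))
    assert out.shape == (3, 5, 8, 8)
    assert out.data.min() >= 0.0


def test_rfu_zero_kernels_give_zero_output(rng):
    rfu = blocks.RFU(1, 4, np.random.default_rng(0))
    rfu.conv.weight.data[:] = 0.0
    rfu.eval()
    out = rfu(Tensor(rng.standard_normal((1, 1, 6, 6)).astype(np.float32)))
    np.testing.assert_array_equal(out.data, 0.0)


def test_rfu_identity_kernel_inference_is_relu(rng):
    """With a centered identity kernel and neutral BN statistics, the unit
    reduces to ReLU of the input (up to the BN epsilon factor)."""
    rfu = _f64(blocks.RFU(1, 1, np.random.default_rng(0)))
    rfu.conv.weight.data[:] = 0.0
    rfu.conv.weight.data[0, 0, 1, 1] = 1.0
    rfu.conv.bias.data[:] = 0.0
    rfu.eval()
    x = rng.standard_normal((1, 1, 5, 5))
    out = rfu(Tensor(x))
    np.testing.assert_allclose(out.data[0, 0], np.maximum(x[0, 0], 0.0), atol=1e-4)


def test_rfu_rejects_nonfinite_input():
    rfu = blocks.RFU(1, 1, np.random.default_rng(0))
    bad = np.zeros((1, 1, 4, 4), dtype=np.float32)
    bad[0, 0, 0, 0] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        rfu(Tensor(bad))


# -- self-attention -----------------------------------------------------------

def test_attention_rows_sum_to_one(rng):
    att = blocks.SelfAttention2d(3, np.random.default_rng(1))
    for _ in range(20):
        x = Tensor(rng.standard_normal((2, 3, 6, 6)).astype(np.float32))
        _, beta = att(x, return_attention=True)
        assert beta.data.min() >= 0.0
        np.testing.assert_allclose(beta.data.sum(axis=-1), 1.0, atol=1e-6)


def test_attention_zero_projections_give_uniform_weights(rng):
    att = blocks.SelfAttention2d(2, np.random.default_rng(1))
    att.query.weight.data[:] = 0.0
    att.key.weight.data[:] = 0.0
    x = Tensor(rng.standard_normal((1, 2, 3, 3)).astype(np.float32))
    _, beta = att(x, return_attention=True)
    np.testing.assert_allclose(beta.data, 1.0 / 9.0, atol=1e-7)


@pytest.mark.parametrize("channels,size", [(1, 2), (2, 3), (4, 4)])
def test_attention_matches_double_loop_oracle(rng, channels, size):
    att = _f64(blocks.SelfAttention2d(channels, np.random.default_rng(2)))
    att.value.weight.data = rng.standard_normal(att.value.weight.data.shape)
    x = rng.standard_normal((channels, size, size))
    mu, beta = att(Tensor(x[None]), return_attention=True)
    mu_o, beta_o = self_attention_oracle(
        x,
        att.query.weight.data[:, :, 0, 0],
        att.key.weight.data[:, :, 0, 0],
        att.value.weight.data[:, :, 0, 0])
    np.testing.assert_allclose(beta.data[0], beta_o, atol=1e-10)
    np.testing.assert_allclose(mu.data[0], mu_o, atol=1e-10)


def test_attention_budget_rejected_without_subsampling():
    att = blocks.SelfAttention2d(1, np.random.default_rng(0), budget=16, subsample=False)
    with pytest.raises(ValueError, match="subsampling"):
        att(Tensor(np.zeros((1, 1, 8, 8), dtype=np.float32)))


def test_attention_budget_subsamples_to_fit():
    att = blocks.SelfAttention2d(1, np.random.default_rng(0), budget=16, subsample=True)
    mu = att(Tensor(np.random.default_rng(3).random((1, 1, 8, 8)).astype(np.float32)))
    assert mu.shape == (1, 1, 4, 4)


# -- SE gate ------------------------------------------------------------------

def test_se_gate_values_in_open_unit_interval(rng):
    se = blocks.SEGate(8, np.random.default_rng(4))
    g = se.gate(Tensor(rng.standard_normal((3, 8, 5, 5)).astype(np.float32)))
    assert np.all(g.data > 0.0) and np.all(g.data < 1.0)


def test_se_gate_zero_weights_halve_input(rng):
    se = blocks.SEGate(4, np.random.default_rng(4))
    for p in se.parameters():
        p.data[:] = 0.0
    x = rng.standard_normal((2, 4, 3, 3)).astype(np.float32)
    out = se(Tensor(x))
    np.testing.assert_allclose(out.data, 0.5 * x, atol=1e-7)


def test_se_gate_matches_hand_evaluation(rng):
    se = _f64(blocks.SEGate(4, np.random.default_rng(5), reduction=2))
    x = rng.standard_normal((1, 4, 2, 2))
    g = se.gate(Tensor(x)).data[0]
    # scalar evaluation of the two bottleneck matrix-vector products
    pooled = x[0].mean(axis=(1, 2))
    hidden = np.maximum(pooled @ se.fc1.weight.data + se.fc1.bias.data, 0.0)
    expect = 1.0 / (1.0 + np.exp(-(hidden @ se.fc2.weight.data + se.fc2.bias.data)))
    np.testing.assert_allclose(g, expect, atol=1e-12)


# -- SCA fusion ---------------------------------------------------------------

def test_sca_zero_value_projection_reduces_to_upsampling(rng):
    sca = blocks.SCAFusion(3, 6, np.random.default_rng(6))
    sca.attention.value.weight.data[:] = 0.0
    x_low = Tensor(rng.standard_normal((2, 3, 8, 8)).astype(np.float32))
    x_hig = Tensor(rng.standard_normal((2, 6, 4, 4)).astype(np.float32))
    out = sca(x_low, x_hig)
    xh = sca.reconcile(x_hig)
    expect = ad.upsample_bilinear(xh, (8, 8))
    np.testing.assert_array_equal(out.data, expect.data)


def test_bilinear_upsample_of_constant_is_constant():
    x = Tensor(np.full((1, 2, 2, 2), 3.25, dtype=np.float32))
    out = ad.upsample_bilinear(x, (4, 4))
    np.testing.assert_array_equal(out.data, 3.25)


def test_bilinear_upsample_matches_scalar_oracle(rng):
    x = rng.standard_normal((2, 3, 3))
    out = ad.upsample_bilinear(Tensor(x[None]), (6, 6)).data[0]
    np.testing.assert_allclose(out, bilinear_upsample_oracle(x, 6, 6), atol=1e-12)


def test_sca_matches_scalar_oracle(rng):
    sca = _f64(blocks.SCAFusion(2, 2, np.random.default_rng(7)))
    sca.attention.value.weight.data = rng.standard_normal(
        sca.attention.value.weight.data.shape)
    x_low = rng.standard_normal((2, 4, 4))
    x_hig = rng.standard_normal((2, 2, 2))
    out = sca(Tensor(x_low[None]), Tensor(x_hig[None])).data[0]
    expect = sca_fuse_oracle(
        x_low, x_hig,
        sca.reconcile.weight.data[:, :, 0, 0], sca.reconcile.bias.data,
        sca.attention.query.weight.data[:, :, 0, 0],
        sca.attention.key.weight.data[:, :, 0, 0],
        sca.attention.value.weight.data[:, :, 0, 0])
    np.testing.assert_allclose(out, expect, atol=1e-10)


def test_sca_rejects_wrong_spatial_ratio(rng):
    sca = blocks.SCAFusion(2, 2, np.random.default_rng(0))
    with pytest.raises(ValueError, match="half the skip resolution"):
        sca(Tensor(np.zeros((1, 2, 8, 8), dtype=np.float32)),
            Tensor(np.zeros((1, 2, 8, 8), dtype=np.float32)))


# -- SEPP ---------------------------------------------------------------------

def test_sepp_shape_contract(rng):
    sepp = blocks.SEPP(6, 5, np.random.default_rng(8))
    out = sepp(Tensor(rng.standard_normal((2, 6, 16, 16)).astype(np.float32)))
    assert out.shape == (2, 20, 16, 16)


def test_sepp_zero_kernels_give_zero_output(rng):
    sepp = blocks.SEPP(2, 3, np.random.default_rng(8))
    for p in sepp.parameters():
        p.data[:] = 0.0
    out = sepp(Tensor(rng.standard_normal((1, 2, 16, 16)).astype(np.float32)))
    np.testing.assert_array_equal(out.data, 0.0)


def test_sepp_dilated_receptive_field_locality(rng):
    """A single-pixel perturbation must only move the rate-12 branch's output
    at dilated-kernel offsets {-12, 0, +12} per axis.  The channel gate is
    frozen (zero FC weights -> constant 0.5) because its squeeze path is a
    global pool and would otherwise couple every pixel."""
    sepp = blocks.SEPP(1, 2, np.random.default_rng(9))
    branch = sepp.branches[3]
    assert branch.rate == 12
    for p in branch.se.parameters():
        p.data[:] = 0.0
    x = rng.standard_normal((1, 1, 32, 32)).astype(np.float32)
    base = branch(Tensor(x)).data
    for (r, c) in [(16, 16), (3, 28), (0, 0)]:
        xp = x.copy()
        xp[0, 0, r, c] += 1.0
        diff = np.abs(branch(Tensor(xp)).data - base).sum(axis=(0, 1))
        changed = set(zip(*np.nonzero(diff > 1e-6)))
        allowed = {(r + dr, c + dc)
                   for dr in (-12, 0, 12) for dc in (-12, 0, 12)
                   if 0 <= r + dr < 32 and 0 <= c + dc < 32}
        assert changed <= allowed, f"perturbation at {(r, c)} leaked to {changed - allowed}"
        assert (r, c) in changed


def test_sepp_translation_equivariance_away_from_borders(rng):
    sepp = blocks.SEPP(1, 2, np.random.default_rng(10))
    for b in sepp.branches:
        if b.se is not None:
            for p in b.se.parameters():
                p.data[:] = 0.0      # freeze global gate; see locality test
    x = rng.standard_normal((1, 1, 64, 64)).astype(np.float32)
    out = sepp(Tensor(x)).data
    out_shift = sepp(Tensor(np.roll(x, (1, 1), axis=(2, 3)))).data
    m = 14  # margin beyond the widest dilated footprint
    np.testing.assert_allclose(
        out_shift[:, :, 1 + m:-m, 1 + m:-m], out[:, :, m:-m - 1, m:-m - 1], atol=1e-5)


def test_sepp_rejects_nonfinite(rng):
    sepp = blocks.SEPP(1, 2, np.random.default_rng(8))
    bad = np.zeros((1, 1, 8, 8), dtype=np.float32)
    bad[0, 0, 2, 2] = np.inf
    with pytest.raises(ValueError, match="non-finite"):
        sepp(Tensor(bad))
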