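"""Encoder blocks against brute-force dense-attention oracles.

The oracle recomputes a whole Swin block with explicit per-token loops:
layer norm, dense softmax(QK^T/sqrt(d))V restricted by an allowed-pair
membership matrix, the output projection, residuals, and the token MLP.
It shares no code with the windowed implementation.
"""

import numpy as np
import pytest

from bafnet.blocks import (
    RConv,
    SwinBlock,
    SwinStage,
    SwinStageConfig,
    SwinTransConv,
    WindowAttention,
    shift_attention_mask,
    _window_partition,
)
from bafnet.nn import Tensor

from conftest import to_float64


# --------------------------------------------------------------------- oracle
def _layer_norm_np(x, gamma, beta, eps=1e-5):
    mu = x.mean(-1, keepdims=True)
    var = ((x - mu) ** 2).mean(-1, keepdims=True)
    return (x - mu) / np.sqrt(var + eps) * gamma + beta


def _allowed_pairs(H, W, w, shift):
    """Membership matrix over all H*W tokens: True where attention is legal."""
    idx = np.arange(H * W).reshape(H, W)
    if shift:
        rolled = np.roll(idx, (-shift, -shift), axis=(0, 1))
    else:
        rolled = idx
    window_id = np.zeros(H * W, dtype=int)
    for bi in range(H // w):
        for bj in range(W // w):
            toks = rolled[bi * w : (bi + 1) * w, bj * w : (bj + 1) * w].ravel()
            window_id[toks] = bi * (W // w) + bj

    def region(r, n):
        # slab label of a ROLLED coordinate (the wrap pattern of the shift)
        if r < n - w:
            return 0
        if r < n - shift:
            return 1
        return 2

    reg = np.zeros(H * W, dtype=int)
    for rr in range(H):
        for cc in range(W):
            token = rolled[rr, cc]  # original id sitting at rolled (rr, cc)
            reg[token] = region(rr, H) * 3 + region(cc, W)
    same_window = window_id[:, None] == window_id[None, :]
    same_region = reg[:, None] == reg[None, :]
    return same_window & (same_region if shift else True)


def dense_block_oracle(block: SwinBlock, x: np.ndarray, shift: int) -> np.ndarray:
    """Explicit-loop forward of one Swin block over all tokens of the map."""
    B, C, H, W = x.shape
    assert B == 1
    w = block.cfg.window_size
    tokens = x[0].reshape(C, H * W).T  # N, C
    n1 = _layer_norm_np(tokens, block.norm1.gamma.data, block.norm1.beta.data)
    Wqkv, bqkv = block.attn.qkv.weight.data, block.attn.qkv.bias.data
    qkv = n1 @ Wqkv + bqkv
    heads = block.attn.num_heads
    hd = C // heads
    allowed = _allowed_pairs(H, W, w, shift)
    N = H * W
    attended = np.zeros((N, C))
    for h in range(heads):
        q = qkv[:, h * hd : (h + 1) * hd]
        k = qkv[:, C + h * hd : C + (h + 1) * hd]
        v = qkv[:, 2 * C + h * hd : 2 * C + (h + 1) * hd]
        for i in range(N):
            logits = np.full(N, -np.inf)
            for j in range(N):
                if allowed[i, j]:
                    logits[j] = q[i] @ k[j] / np.sqrt(hd)
            weights = np.exp(logits - logits[allowed[i]].max())
            weights[~allowed[i]] = 0.0
            weights /= weights.sum()
            attended[i, h * hd : (h + 1) * hd] = weights @ v
    out = tokens + attended @ block.attn.proj.weight.data + block.attn.proj.bias.data
    n2 = _layer_norm_np(out, block.norm2.gamma.data, block.norm2.beta.data)
    hidden = n2 @ block.fc1.weight.data + block.fc1.bias.data
    from scipy.special import erf

    hidden = hidden * 0.5 * (1.0 + erf(hidden / np.sqrt(2.0)))
    out = out + hidden @ block.fc2.weight.data + block.fc2.bias.data
    return out.T.reshape(1, C, H, W)


CFG8 = SwinStageConfig(window_size=4, head_dim=4, use_rel_bias=False)


# ---------------------------------------------------------------------- RConv
def test_rconv_zero_weights_annihilate():
    rng = np.random.default_rng(0)
    block = RConv(4, rng)
    for p in block.parameters():
        p.data = np.zeros_like(p.data)
    out = block(Tensor(rng.random((2, 4, 6, 6), dtype=np.float32)))
    assert np.all(out.numpy() == 0)


def test_rconv_shape_preserved():
    block = RConv(16, np.random.default_rng(0))
    out = block(Tensor(np.random.default_rng(1).random((1, 16, 8, 8), dtype=np.float32)))
    assert out.shape == (1, 16, 8, 8)


def test_rconv_single_pixel_closed_form():
    """1x1 spatial input, unit scalar weights: out = relu(x)*1 + x."""
    block = RConv(1, np.random.default_rng(0))
    for conv in (block.conv1, block.conv2):
        conv.weight.data = np.zeros_like(conv.weight.data)
        conv.weight.data[0, 0, 1, 1] = 1.0  # centre tap only
        conv.bias.data[:] = 0.0
    out = block(Tensor(np.full((1, 1, 1, 1), 2.0)))
    assert out.numpy().item() == pytest.approx(4.0)


# ------------------------------------------------------------------ attention
def test_window_count_and_softmax_rows():
    rng = np.random.default_rng(3)
    attn = WindowAttention(8, 2, 4, rng, use_rel_bias=True)
    x = Tensor(rng.standard_normal((1, 8, 8, 8)))
    tokens = _window_partition(x, 4)
    assert tokens.shape == (4, 16, 8)  # (8/4)x(8/4) independent windows
    weights, _ = attn.attention_weights(tokens)
    np.testing.assert_allclose(weights.numpy().sum(-1), 1.0, atol=1e-6)


def test_masked_pairs_get_zero_weight():
    rng = np.random.default_rng(4)
    attn = WindowAttention(4, 1, 4, rng, use_rel_bias=False)
    mask = shift_attention_mask(8, 8, 4, 2)
    x = Tensor(rng.standard_normal((4, 16, 4)))
    weights, _ = attn.attention_weights(x, mask=mask)
    forbidden = mask < 0
    assert np.all(weights.numpy()[:, 0][forbidden] == 0.0)


def test_zeroed_projections_give_identity():
    rng = np.random.default_rng(5)
    block = SwinBlock(8, CFG8, rng, shifted=False)
    for lin in (block.attn.qkv, block.attn.proj, block.fc1, block.fc2):
        lin.weight.data[:] = 0.0
        lin.bias.data[:] = 0.0
    x = rng.standard_normal((1, 8, 8, 8))
    np.testing.assert_allclose(block(Tensor(x)).numpy(), x, atol=1e-12)


def test_shift_zero_equals_window_msa():
    rng = np.random.default_rng(6)
    cfg = SwinStageConfig(window_size=4, shift_size=0, head_dim=4,
                          use_rel_bias=False)
    b1 = SwinBlock(8, cfg, rng, shifted=True)
    b2 = SwinBlock(8, cfg, np.random.default_rng(6), shifted=False)
    x = Tensor(np.random.default_rng(7).standard_normal((1, 8, 8, 8)))
    np.testing.assert_allclose(b1(x).numpy(), b2(x).numpy(), atol=1e-12)


@pytest.mark.parametrize("size,shifted", [(8, False), (8, True), (12, True), (16, True)])
def test_dense_attention_oracle(size, shifted):
    rng = np.random.default_rng(8 + size)
    block = to_float64(SwinBlock(8, CFG8, rng, shifted=shifted))
    x = np.random.default_rng(9).standard_normal((1, 8, size, size))
    got = block(Tensor(x)).numpy()
    shift = block.cfg.resolved_shift() if shifted else 0
    want = dense_block_oracle(block, x, shift)
    np.testing.assert_allclose(got, want, atol=1e-5)


def test_single_window_oracle_one_head():
    """2x2 map, one window, one head: matches explicit softmax(QK^T/sqrt(d))V."""
    rng = np.random.default_rng(11)
    cfg = SwinStageConfig(window_size=2, head_dim=4, use_rel_bias=False)
    block = to_float64(SwinBlock(4, cfg, rng, shifted=False))
    x = np.random.default_rng(12).standard_normal((1, 4, 2, 2))
    got = block(Tensor(x)).numpy()
    want = dense_block_oracle(block, x, shift=0)
    np.testing.assert_allclose(got, want, atol=1e-8)


# -------------------------------------------------------------- hybrid block
def test_split_is_even():
    rng = np.random.default_rng(13)
    block = SwinTransConv(16, 32, SwinStageConfig(window_size=4), rng)
    assert block.rconv.channels == 16
    assert block.swin.block_w.dim == 16
    with pytest.raises(ValueError):
        SwinTransConv(16, 15, SwinStageConfig(), rng)  # odd working channels


def test_zero_weights_reduce_to_identity():
    rng = np.random.default_rng(14)
    block = SwinTransConv(8, 8, SwinStageConfig(window_size=4), rng)
    for p in block.parameters():
        p.data = np.zeros_like(p.data)
    x = np.random.default_rng(15).standard_normal((1, 8, 8, 8)).astype(np.float32)
    np.testing.assert_allclose(block(Tensor(x)).numpy(), x, atol=1e-7)


def test_split_block_has_fewer_params_than_unsplit():
    cfg = SwinStageConfig(window_size=4)
    rng = np.random.default_rng(16)
    C = 32
    split = SwinTransConv(C, C, cfg, rng)
    unsplit = SwinStage(C, cfg, np.random.default_rng(16)).num_parameters() + RConv(
        C, np.random.default_rng(16)
    ).num_parameters()
    assert split.num_parameters() < unsplit


def test_gradient_reaches_every_input_position():
    rng = np.random.default_rng(17)
    block = SwinTransConv(6, 6, SwinStageConfig(window_size=4), rng)
    x = Tensor(rng.standard_normal((1, 6, 8, 8)).astype(np.float32),
               requires_grad=True)
    block(x).sum().backward()
    assert np.all(np.abs(x.grad).sum(axis=1) > 0)


def test_shape_preservation_property():
    rng = np.random.default_rng(18)
    cfg = SwinStageConfig(window_size=4)
    for H, W in [(8, 8), (8, 12), (16, 8)]:
        block = SwinTransConv(4, 4, cfg, rng)
        x = Tensor(rng.standard_normal((2, 4, H, W)).astype(np.float32))
        assert block(x).shape == (2, 4, H, W)


def test_window_larger_than_map_falls_back():
    """Maps smaller than the window use one whole-map window without shift."""
    rng = np.random.default_rng(19)
    block = SwinTransConv(4, 4, SwinStageConfig(window_size=8), rng)
    out = block(Tensor(rng.standard_normal((1, 4, 4, 4)).astype(np.float32)))
    assert out.shape == (1, 4, 4, 4)
    assert np.isfinite(out.numpy()).all()
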