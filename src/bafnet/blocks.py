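"""Encoder building blocks: residual convolution, shifted-window attention,
and the cascaded hybrid Swin-Trans-Conv block.

A Swin stage treats every spatial position of the feature map as one token
(patch size 1) and runs one windowed attention block followed by one
shifted-window block, each with a pre-norm residual MLP.  The channel-split
hybrid block sends half the channels through the Swin stage (long-range
context) and half through a residual 3x3 convolution path (local detail),
then re-fuses them with a 1x1 convolution and a residual connection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (
    Conv2d,
    LayerNorm,
    Linear,
    Module,
    Parameter,
    Tensor,
    concat,
    trunc_normal,
)

__all__ = [
    "SwinStageConfig",
    "RConv",
    "WindowAttention",
    "SwinBlock",
    "SwinStage",
    "SwinTransConv",
]


@dataclass
class SwinStageConfig:
    """Hyperparameters of one Swin stage.

    window_size : side of the square attention window, in feature-map pixels.
    shift_size  : cyclic shift of the second block; defaults to window_size//2.
    head_dim    : per-head channel width used to derive the head count
                  (heads = max(channels // head_dim, 1)).
    mlp_ratio   : hidden width of the token MLP relative to the channel count.
    use_rel_bias: learned relative-position bias per head (off for oracle tests).
    """

    window_size: int = 8
    shift_size: int | None = None
    head_dim: int = 16
    mlp_ratio: int = 4
    use_rel_bias: bool = True

    def resolved_shift(self) -> int:
        return self.window_size // 2 if self.shift_size is None else self.shift_size

    def __post_init__(self):
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if self.shift_size is not None and self.shift_size >= self.window_size:
            raise ValueError("shift_size must be smaller than window_size")


class RConv(Module):
    """Residual double 3x3 convolution: Conv(ReLU(Conv(x))) + Conv(x).

    The residual adds the output of the *first* convolution, so with all
    weights zero the block maps everything to zero.
    """

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.channels = channels
        self.conv1 = Conv2d(channels, channels, 3, rng)
        self.conv2 = Conv2d(channels, channels, 3, rng)

    def forward(self, x: Tensor) -> Tensor:
        f3 = self.conv1(x)
        return self.conv2(f3.relu()) + f3


def _relative_index(w: int, table_w: int | None = None) -> np.ndarray:
    """Flat index into a (2*table_w-1)^2 bias table for in-window token pairs
    of a (possibly smaller) effective window of side ``w``."""
    tw = table_w or w
    coords = np.stack(np.meshgrid(np.arange(w), np.arange(w), indexing="ij"))
    flat = coords.reshape(2, -1)
    rel = flat[:, :, None] - flat[:, None, :]  # 2, S, S
    rel = rel + (tw - 1)
    return rel[0] * (2 * tw - 1) + rel[1]


class WindowAttention(Module):
    """Multi-head self-attention within non-overlapping windows."""

    def __init__(self, dim: int, num_heads: int, window_size: int,
                 rng: np.random.Generator, use_rel_bias: bool = True):
        super().__init__()
        if dim % num_heads:
            raise ValueError(f"{num_heads} heads do not divide dim {dim}")
        self.dim, self.num_heads, self.window_size = dim, num_heads, window_size
        self.scale = (dim // num_heads) ** -0.5
        self.qkv = Linear(dim, 3 * dim, rng, init="trunc")
        self.proj = Linear(dim, dim, rng, init="trunc")
        self.use_rel_bias = use_rel_bias
        if use_rel_bias:
            n = (2 * window_size - 1) ** 2
            self.rel_bias = Parameter(trunc_normal(rng, (n, num_heads)))
            self._rel_index_cache = {window_size: _relative_index(window_size)}

    def _rel_index(self, w: int) -> np.ndarray:
        if w not in self._rel_index_cache:
            self._rel_index_cache[w] = _relative_index(w, self.window_size)
        return self._rel_index_cache[w]

    def attention_weights(self, tokens: Tensor, mask: np.ndarray | None = None):
        """Softmax attention weights (nW, heads, S, S) and values (nW, heads, S, hd)."""
        nW, S, dim = tokens.shape
        h, hd = self.num_heads, dim // self.num_heads
        qkv = self.qkv(tokens).reshape(nW, S, 3, h, hd).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]  # nW, h, S, hd
        attn = (q @ k.transpose(0, 1, 3, 2)) * self.scale
        if self.use_rel_bias:
            w_eff = int(round(np.sqrt(S)))
            bias = self.rel_bias.gather_rows(self._rel_index(w_eff))  # S,S,h
            attn = attn + bias.transpose(2, 0, 1).reshape(1, h, S, S)
        if mask is not None:
            nm = mask.shape[0]
            attn = attn.reshape(nW // nm, nm, h, S, S) + Tensor(
                mask[None, :, None, :, :].astype(attn.dtype)
            )
            attn = attn.reshape(nW, h, S, S)
        return attn.softmax(axis=-1), v

    def forward(self, tokens: Tensor, mask: np.ndarray | None = None) -> Tensor:
        """tokens: (nW, S, dim); mask: (nW_per_image, S, S) additive or None."""
        nW, S, dim = tokens.shape
        weights, v = self.attention_weights(tokens, mask)
        out = (weights @ v).transpose(0, 2, 1, 3).reshape(nW, S, dim)
        return self.proj(out)


def _window_partition(x: Tensor, w: int) -> Tensor:
    """(B,C,H,W) -> (B*nH*nW, w*w, C) token windows."""
    B, C, H, W = x.shape
    x = x.reshape(B, C, H // w, w, W // w, w)
    x = x.transpose(0, 2, 4, 3, 5, 1)  # B, nH, nW, w, w, C
    return x.reshape(B * (H // w) * (W // w), w * w, C)


def _window_reverse(tokens: Tensor, w: int, B: int, C: int, H: int, W: int) -> Tensor:
    x = tokens.reshape(B, H // w, W // w, w, w, C)
    x = x.transpose(0, 5, 1, 3, 2, 4)  # B, C, nH, w, nW, w
    return x.reshape(B, C, H, W)


def shift_attention_mask(H: int, W: int, w: int, shift: int,
                         neg: float = -1e9) -> np.ndarray:
    """Additive mask forbidding attention between pre-shift-discontiguous tokens.

    Follows the standard shifted-window recipe: label spatial regions by the
    three slabs the cyclic shift wraps, partition the label map into windows,
    and mask pairs with differing labels.
    """
    img = np.zeros((H, W))
    cnt = 0
    for hs in (slice(0, -w), slice(-w, -shift), slice(-shift, None)):
        for ws in (slice(0, -w), slice(-w, -shift), slice(-shift, None)):
            img[hs, ws] = cnt
            cnt += 1
    win = img.reshape(H // w, w, W // w, w).transpose(0, 2, 1, 3).reshape(-1, w * w)
    diff = win[:, None, :] != win[:, :, None]
    return np.where(diff, neg, 0.0)


class SwinBlock(Module):
    """One pre-norm attention block: x + MSA(LN(x)), then x + MLP(LN(x)).

    ``shift`` > 0 gives the shifted-window variant (cyclic roll + mask).
    """

    def __init__(self, dim: int, cfg: SwinStageConfig, rng: np.random.Generator,
                 shifted: bool = False):
        super().__init__()
        self.dim, self.cfg, self.shifted = dim, cfg, shifted
        heads = max(dim // cfg.head_dim, 1)
        self.norm1 = LayerNorm(dim)
        self.attn = WindowAttention(dim, heads, cfg.window_size, rng,
                                    use_rel_bias=cfg.use_rel_bias)
        self.norm2 = LayerNorm(dim)
        hidden = dim * cfg.mlp_ratio
        self.fc1 = Linear(dim, hidden, rng, init="trunc")
        self.fc2 = Linear(hidden, dim, rng, init="trunc")

    def _effective(self, H: int, W: int) -> tuple[int, int]:
        w = min(self.cfg.window_size, H, W)
        shift = self.cfg.resolved_shift() if self.shifted else 0
        if w >= H and w >= W:
            shift = 0  # a single window already sees the whole map
        shift = min(shift, w - 1) if w > 1 else 0
        return w, shift

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        w, shift = self._effective(H, W)
        if w > min(H, W):
            raise ValueError("window larger than padded feature map")
        pad_h = (-H) % w
        pad_w = (-W) % w
        y = x.pad2d((0, pad_h, 0, pad_w), mode="reflect") if (pad_h or pad_w) else x
        Hp, Wp = H + pad_h, W + pad_w
        if shift:
            y = y.roll((-shift, -shift), (2, 3))
            mask = shift_attention_mask(Hp, Wp, w, shift)
        else:
            mask = None
        tokens = _window_partition(y, w)
        tokens = tokens + self.attn(self.norm1(tokens), mask=mask)
        y = _window_reverse(tokens, w, B, C, Hp, Wp)
        if shift:
            y = y.roll((shift, shift), (2, 3))
        if pad_h or pad_w:
            y = y[:, :, :H, :W]
        x = y  # the attention residual was applied on the token windows
        # MLP sub-block (token-wise, pre-norm residual)
        t = x.reshape(B, C, H * W).transpose(0, 2, 1)
        t = t + self.fc2(self.fc1(self.norm2(t)).gelu())
        return t.transpose(0, 2, 1).reshape(B, C, H, W)


class SwinStage(Module):
    """Depth-2 Swin stage: a windowed block followed by a shifted one."""

    def __init__(self, dim: int, cfg: SwinStageConfig, rng: np.random.Generator):
        super().__init__()
        self.block_w = SwinBlock(dim, cfg, rng, shifted=False)
        self.block_sw = SwinBlock(dim, cfg, rng, shifted=True)

    def forward(self, x: Tensor) -> Tensor:
        return self.block_sw(self.block_w(x))


class SwinTransConv(Module):
    """Channel-split hybrid block.

    1x1 conv -> split channels in half -> Swin stage / RConv in parallel ->
    concatenate -> 1x1 conv -> add the block input (projected if the channel
    count changes).
    """

    def __init__(self, in_ch: int, out_ch: int, cfg: SwinStageConfig,
                 rng: np.random.Generator):
        super().__init__()
        if out_ch % 2:
            raise ValueError("working channel count must be even to split")
        self.in_ch, self.out_ch = in_ch, out_ch
        half = out_ch // 2
        self.proj_in = Conv2d(in_ch, out_ch, 1, rng)
        self.swin = SwinStage(half, cfg, rng)
        self.rconv = RConv(half, rng)
        self.proj_out = Conv2d(out_ch, out_ch, 1, rng)
        self.shortcut = Conv2d(in_ch, out_ch, 1, rng) if in_ch != out_ch else None

    def forward(self, x: Tensor) -> Tensor:
        y = self.proj_in(x)
        half = self.out_ch // 2
        f_trans, f_conv = y[:, :half], y[:, half:]
        fused = concat([self.swin(f_trans), self.rconv(f_conv)], axis=1)
        res = x if self.shortcut is None else self.shortcut(x)
        return self.proj_out(fused) + res
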