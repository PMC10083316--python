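"""BAF-Net assembly: the multi-scale U-shaped branch (MSFF), the full-scale
full-resolution branch (FSFF), and the bidirectional attention fusion (BAF)
gates that exchange features between them at every decoder level.

The ablation flags reproduce the four nested variants used to justify each
component: a half-width U-Net baseline (SU-Net, single Conv-BN-ReLU per
encoder stage), + hybrid Swin-Trans-Conv encoder blocks (MSFF), + the
full-resolution branch (FSFF), + the attention gates (BAF).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .blocks import SwinStageConfig, SwinTransConv
from .nn import (
    Conv2d,
    ConvBNReLU,
    ConvTranspose2d,
    Module,
    ModuleList,
    Tensor,
    concat,
)

__all__ = ["ModelConfig", "BAFNet", "build_model", "ABLATION_VARIANTS"]

N_STAGES = 5
N_DECODER = 4

#: Table of the four ablation variants: name -> (use_msff, use_fsff, use_baf)
ABLATION_VARIANTS = {
    "SU-Net": (False, False, False),
    "SU-Net-MSFF": (True, False, False),
    "SU-Net-MSFF-FSFF": (True, True, False),
    "BAF-Net": (True, True, True),
}


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    base_channels: first-stage channel count; the encoder ladder is
        base * (1, 2, 4, 8, 16) — 32/64/128/256/512 at the default.
    image_size: nominal square input side; any H = W divisible by 16 works
        at forward time (the network is fully convolutional).
    use_msff / use_fsff / use_baf: ablation switches (BAF requires FSFF).
    """

    base_channels: int = 32
    image_size: int = 512
    in_channels: int = 3
    use_msff: bool = True
    use_fsff: bool = True
    use_baf: bool = True
    swin: SwinStageConfig = field(default_factory=SwinStageConfig)

    def __post_init__(self):
        if self.image_size % 16:
            raise ValueError("image_size must be divisible by 16")
        if self.base_channels % 2:
            raise ValueError("base_channels must be even")
        if self.use_baf and not self.use_fsff:
            raise ValueError("the BAF gates bridge the FSFF branch; enable use_fsff")

    @property
    def channel_ladder(self) -> tuple:
        return tuple(self.base_channels * 2 ** i for i in range(N_STAGES))


class DecodeStep(Module):
    """Stride-2 transposed-conv upsample, skip concatenation, Conv-BN-ReLU."""

    def __init__(self, deep_ch: int, skip_ch: int, rng: np.random.Generator):
        super().__init__()
        self.up = ConvTranspose2d(deep_ch, skip_ch, rng)
        self.conv = ConvBNReLU(2 * skip_ch, skip_ch, 3, rng)

    def forward(self, deep: Tensor, skip: Tensor) -> Tensor:
        up = self.up(deep)
        if up.shape[2:] != skip.shape[2:]:
            raise RuntimeError(
                f"decoder resolution mismatch: {up.shape[2:]} vs {skip.shape[2:]}"
            )
        return self.conv(concat([up, skip], axis=1))


class MSFG(Module):
    """Multi-scale feature gate: full-scale context modulates a decoder map.

    The full-resolution feature is average-pooled down to the decoder
    resolution, concatenated, compressed back to the decoder channel count by
    a 1x1 conv, projected to one channel, and squashed by a sigmoid into a
    spatial attention map that rescales the compressed feature.
    """

    def __init__(self, ms_ch: int, fg_ch: int, rng: np.random.Generator):
        super().__init__()
        self.compress = Conv2d(ms_ch + fg_ch, ms_ch, 1, rng)
        self.project = Conv2d(ms_ch, 1, 1, rng, init="trunc")

    def forward(self, f_ms: Tensor, f_fg: Tensor) -> tuple[Tensor, Tensor]:
        factor = f_fg.shape[2] // f_ms.shape[2]
        if factor * f_ms.shape[2] != f_fg.shape[2] or factor & (factor - 1):
            raise ValueError("resolutions must be related by a power of two")
        f_dn = f_fg.avg_pool2d(factor)
        f_c = self.compress(concat([f_ms, f_dn], axis=1))
        alpha = self.project(f_c).sigmoid()
        return alpha * f_c, alpha


class FSFG(Module):
    """Full-scale feature gate: decoder context modulates the full-scale map."""

    def __init__(self, ms_ch: int, fg_ch: int, rng: np.random.Generator):
        super().__init__()
        self.compress = Conv2d(ms_ch, fg_ch, 1, rng)
        self.fuse = Conv2d(fg_ch, fg_ch, 3, rng)
        self.project = Conv2d(fg_ch, 1, 1, rng, init="trunc")

    def forward(self, f_ms: Tensor, f_fg: Tensor) -> tuple[Tensor, Tensor]:
        factor = f_fg.shape[2] // f_ms.shape[2]
        if factor * f_ms.shape[2] != f_fg.shape[2] or factor & (factor - 1):
            raise ValueError("resolutions must be related by a power of two")
        f_up = self.compress(f_ms).upsample_nearest(factor)
        f_c = self.fuse(f_up + f_fg)
        alpha = self.project(f_c).sigmoid()
        return alpha * f_c, alpha


class BAFNet(Module):
    """The full segmentation network (or an ablation variant of it).

    ``forward`` returns a (B, 1, H, W) probability map.  After a forward
    pass, ``attention_maps_`` holds the sigmoid gate maps of every BAF module
    (empty for variants without BAF) and ``encoder_features_`` the per-stage
    encoder shapes, for inspection.
    """

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        ladder = cfg.channel_ladder
        b = cfg.base_channels

        self.encoder = ModuleList()
        in_ch = cfg.in_channels
        for ch in ladder:
            if cfg.use_msff:
                self.encoder.append(SwinTransConv(in_ch, ch, cfg.swin, rng))
            else:
                self.encoder.append(ConvBNReLU(in_ch, ch, 3, rng))
            in_ch = ch

        self.decoder = ModuleList(
            DecodeStep(ladder[i + 1], ladder[i], rng)
            for i in reversed(range(N_DECODER))
        )  # deep -> shallow: (512->256), (256->128), (128->64), (64->32)

        if cfg.use_fsff:
            # 1x1 reductions for encoder stages 2..4 and the bottleneck.
            self.fsff_reduce = ModuleList(
                Conv2d(ladder[i], b, 1, rng) for i in range(1, N_STAGES)
            )
            self.fsff_blocks = ModuleList(
                ConvBNReLU(b, b, 3, rng) for _ in range(N_DECODER)
            )
        if cfg.use_baf:
            dec_ch = [ladder[i] for i in reversed(range(N_DECODER))]
            self.msfg = ModuleList(MSFG(c, b, rng) for c in dec_ch)
            self.fsfg = ModuleList(FSFG(c, b, rng) for c in dec_ch)

        self.head = Conv2d(b, 1, 1, rng)
        self.attention_maps_: list = []
        self.encoder_features_: list = []

    # ------------------------------------------------------------------ parts
    def encode(self, x: Tensor) -> list[Tensor]:
        """Five encoder stage outputs; 2x average pooling between stages."""
        feats = []
        h = x
        for i, stage in enumerate(self.encoder):
            if i > 0:
                h = h.avg_pool2d(2)
            h = stage(h)
            feats.append(h)
        return feats

    def fsff_fuse(self, enc: list[Tensor]) -> Tensor:
        """Full-scale fusion: reduced+upsampled deep features plus stage 1."""
        fused = enc[0]
        for j, reduce in enumerate(self.fsff_reduce):
            r = reduce(enc[j + 1])
            fused = fused + r.upsample_nearest(2 ** (j + 1))
        return fused

    # ---------------------------------------------------------------- forward
    def forward(self, x: Tensor) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        B, C, H, W = x.shape
        if H % 16 or W % 16:
            raise ValueError(f"input size {H}x{W} must be divisible by 16")
        if C != self.cfg.in_channels:
            raise ValueError(f"expected {self.cfg.in_channels}-channel input")
        self.attention_maps_ = []
        enc = self.encode(x)
        self.encoder_features_ = [tuple(e.shape) for e in enc]

        f = self.fsff_fuse(enc) if self.cfg.use_fsff else None
        d = enc[-1]
        for k in range(N_DECODER):
            d = self.decoder[k](d, enc[N_STAGES - 2 - k])
            if self.cfg.use_fsff:
                f = self.fsff_blocks[k](f)
            if self.cfg.use_baf:
                d_gated, a_ms = self.msfg[k](d, f)
                f_gated, a_fg = self.fsfg[k](d, f)
                self.attention_maps_.extend([a_ms.numpy(), a_fg.numpy()])
                d, f = d_gated, f_gated
        head_in = f if self.cfg.use_fsff else d
        return self.head(head_in).sigmoid()


def build_model(cfg: ModelConfig | None = None, seed: int = 0, **kwargs) -> BAFNet:
    """Convenience constructor: ``build_model(base_channels=8, use_baf=False)``."""
    if cfg is None:
        cfg = ModelConfig(**kwargs)
    elif kwargs:
        raise TypeError("pass either a ModelConfig or keyword overrides, not both")
    return BAFNet(cfg, seed=seed)
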