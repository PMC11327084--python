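"""Multi-stage encoder with strided-convolution downsampling.

Stage 1 keeps the input resolution: two 3x3 conv blocks then global-context
attention.  Every deeper stage first halves the resolution with a 3x3
stride-2 convolution that doubles the channel count (replacing max-pooling,
so the downsampling step itself learns features), then applies two 3x3 conv
blocks and attention.  Stage i therefore runs at input_size / 2^(i-1) with
base_width * 2^(i-1) channels, and every stage output feeds both the mid
fusion layer and its same-level decoder skip.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import nn
from .autodiff import Tensor
from .gc_attention import make_attention


@dataclass(frozen=True)
class EncoderConfig:
    depth: int = 5
    base_width: int = 64
    input_size: int = 512
    in_channels: int = 3
    attention: bool = True
    gc_ratio: int = 8

    def __post_init__(self):
        if not 3 <= self.depth <= 5:
            raise ValueError(f"depth must be in 3..5, got {self.depth}")
        if self.input_size % (2 ** (self.depth - 1)) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^{self.depth - 1}"
            )

    def stage_width(self, stage: int) -> int:
        return self.base_width * 2 ** (stage - 1)

    def stage_resolution(self, stage: int) -> int:
        return self.input_size // 2 ** (stage - 1)

    @property
    def widths(self) -> list[int]:
        return [self.stage_width(i) for i in range(1, self.depth + 1)]


class EncoderStage(nn.Module):
    def __init__(self, cfg: EncoderConfig, stage: int):
        super().__init__()
        self.stage = stage
        width = cfg.stage_width(stage)
        if stage == 1:
            self.down = nn.Identity()
            in_ch = cfg.in_channels
        else:
            # stride-2 conv halves resolution and doubles channels
            self.down = nn.ConvBlock(cfg.stage_width(stage - 1), width, 3, stride=2)
            in_ch = width
        self.conv1 = nn.ConvBlock(in_ch, width, 3)
        self.conv2 = nn.ConvBlock(width, width, 3)
        self.attn = make_attention(width, cfg.gc_ratio, cfg.attention)

    def forward(self, x: Tensor) -> Tensor:
        x = self.down(x)
        x = self.conv2(self.conv1(x))
        return self.attn(x)


class Encoder(nn.Module):
    def __init__(self, cfg: EncoderConfig):
        super().__init__()
        self.cfg = cfg
        self.stages = nn.ModuleList(
            EncoderStage(cfg, i) for i in range(1, cfg.depth + 1)
        )

    def forward(self, x: Tensor) -> list[Tensor]:
        """Return all stage outputs, shallow to deep."""
        if x.shape[2] != self.cfg.input_size or x.shape[3] != self.cfg.input_size:
            raise ValueError(
                f"encoder configured for {self.cfg.input_size}, got {x.shape[2:]}"
            )
        outputs = []
        for stage in self.stages:
            x = stage(x)
            outputs.append(x)
        return outputs
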