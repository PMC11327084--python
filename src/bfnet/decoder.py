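"""Double-skip decoder.

Each decoder stage concatenates three sources at the stage's resolution:
the next-deeper decoder output (upsampled x2 with a 4x4 transposed
convolution, which always lands on an even size so no rows or columns are
discarded), the fused mid layer (resampled by at most a factor of 4), and
the same-stage encoder output.  A 1x1 convolution then cuts the
concatenated width to a quarter, followed by batch norm, ReLU and
global-context attention.  The deepest stage has no deeper decoder and
fuses only mid + encoder.
"""

from __future__ import annotations

import math

from . import nn
from .autodiff import Tensor, concat
from .encoder import EncoderConfig
from .gc_attention import make_attention
from .mid_fusion import MidFusion, resample_factor


def quarter(width: int) -> int:
    return math.ceil(width / 4)


class MidResample(nn.Module):
    """Bring the mid layer to a decoder stage's resolution (factor <= 4)."""

    def __init__(self, mid_width: int, stage: int, reference_stage: int):
        super().__init__()
        factor = resample_factor(stage, reference_stage)
        steps = []
        n = factor.bit_length() - 1
        if stage > reference_stage:  # coarser than mid: downsample
            for _ in range(n):
                steps.append(nn.ConvBlock(mid_width, mid_width, 3, stride=2))
        elif stage < reference_stage:  # finer than mid: upsample
            for _ in range(n):
                steps.append(nn.UpBlock(mid_width, mid_width))
        self.resample = nn.Sequential(*steps)

    def forward(self, x: Tensor) -> Tensor:
        return self.resample(x)


class DecoderStage(nn.Module):
    def __init__(
        self,
        enc: EncoderConfig,
        stage: int,
        mid_width: int,
        reference_stage: int,
        deeper_width: int | None,
    ):
        super().__init__()
        self.stage = stage
        self.mid_resample = MidResample(mid_width, stage, reference_stage)
        if deeper_width is not None:
            self.up = nn.UpBlock(deeper_width, deeper_width)
        else:
            self.up = None
        concat_width = enc.stage_width(stage) + mid_width + (deeper_width or 0)
        self.out_width = quarter(concat_width)
        self.reduce = nn.Conv2d(concat_width, self.out_width, 1, bias=False)
        self.norm = nn.BatchNorm2d(self.out_width)
        self.attn = make_attention(self.out_width, enc.gc_ratio, enc.attention)

    def forward(self, deeper: Tensor | None, mid: Tensor, enc_i: Tensor) -> Tensor:
        parts = []
        if self.up is not None:
            if deeper is None:
                raise ValueError(f"stage {self.stage} expects a deeper decoder input")
            parts.append(self.up(deeper))
        elif deeper is not None:
            raise ValueError("deepest stage takes no deeper decoder input")
        parts.append(self.mid_resample(mid))
        parts.append(enc_i)
        ref = enc_i.shape[2:]
        for p in parts:
            if p.shape[2:] != ref:
                raise ValueError(
                    f"decoder stage {self.stage}: resolution mismatch "
                    f"{p.shape[2:]} vs encoder {ref}"
                )
        x = self.norm(self.reduce(concat(parts, axis=1))).relu()
        return self.attn(x)


class Decoder(nn.Module):
    def __init__(self, enc: EncoderConfig, mid: MidFusion):
        super().__init__()
        ref = mid.cfg.reference_stage
        stages = []
        deeper_width: int | None = None
        for stage in range(enc.depth, 0, -1):  # deep -> shallow
            s = DecoderStage(enc, stage, mid.out_width, ref, deeper_width)
            deeper_width = s.out_width
            stages.append(s)
        self.stages = nn.ModuleList(stages)
        self.out_width = deeper_width

    def forward(self, encoder_outputs: list[Tensor], mid: Tensor) -> Tensor:
        deeper = None
        for s in self.stages:
            deeper = s(deeper, mid, encoder_outputs[s.stage - 1])
        return deeper
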