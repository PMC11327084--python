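"""Full-encoder "mid layer" fusion.

Every encoder stage is resampled to a common reference resolution (the
middle stage's), unified to a common branch width, attended, and channel-
concatenated into a single fused map that every decoder stage later
consumes.  With the default 5-stage, width-64 encoder the five 256-channel
branches concatenate to 1280 channels, which a 3x3 convolution then reduces
to a quarter (320) before two further 3x3 convolutions and a final
attention block.

Resampling never exceeds a factor of 4 in either direction: shallower
stages are downsampled with stride-2 convolutions (compressing real image
content), deeper stages are upsampled with 4x4 transposed convolutions —
the only stages where content must be inferred, kept to the minimum the
geometry forces.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import nn
from .autodiff import Tensor, concat
from .encoder import EncoderConfig
from .gc_attention import make_attention

MAX_RESAMPLE_FACTOR = 4


@dataclass(frozen=True)
class MidConfig:
    reference_stage: int
    branch_width: int
    reduce: bool = True

    @staticmethod
    def for_encoder(enc: EncoderConfig, reduce: bool = True) -> "MidConfig":
        # middle stage keeps every resampling factor within {1, 2, 4}
        return MidConfig(
            reference_stage=(enc.depth + 1) // 2,
            branch_width=4 * enc.base_width,
            reduce=reduce,
        )


def resample_factor(stage: int, reference_stage: int) -> int:
    """Spatial factor between a stage and the fusion reference (power of 2)."""
    f = 2 ** abs(stage - reference_stage)
    if f > MAX_RESAMPLE_FACTOR:
        raise ValueError(
            f"stage {stage} needs resampling x{f} to reach stage "
            f"{reference_stage}; the maximum step is {MAX_RESAMPLE_FACTOR}"
        )
    return f


class MidBranch(nn.Module):
    """One encoder stage -> (resample, unify channels, attend)."""

    def __init__(self, enc: EncoderConfig, stage: int, cfg: MidConfig):
        super().__init__()
        self.stage = stage
        width = enc.stage_width(stage)
        self.factor = resample_factor(stage, cfg.reference_stage)
        steps = []
        if stage < cfg.reference_stage:
            for _ in range(self.factor.bit_length() - 1):
                steps.append(nn.ConvBlock(width, width, 3, stride=2))
        elif stage > cfg.reference_stage:
            for _ in range(self.factor.bit_length() - 1):
                steps.append(nn.UpBlock(width, width))
        self.resample = nn.Sequential(*steps)
        self.unify = nn.ConvBlock(width, cfg.branch_width, 3)
        self.attn = make_attention(cfg.branch_width, enc.gc_ratio, enc.attention)

    def forward(self, x: Tensor) -> Tensor:
        return self.attn(self.unify(self.resample(x)))


class MidFusion(nn.Module):
    def __init__(self, enc: EncoderConfig, cfg: MidConfig):
        super().__init__()
        self.enc = enc
        self.cfg = cfg
        self.branches = nn.ModuleList(
            MidBranch(enc, i, cfg) for i in range(1, enc.depth + 1)
        )
        self.concat_width = enc.depth * cfg.branch_width
        self.out_width = self.concat_width // 4 if cfg.reduce else self.concat_width
        self.reduce = (
            nn.ConvBlock(self.concat_width, self.out_width, 3)
            if cfg.reduce
            else nn.Identity()
        )
        self.conv1 = nn.ConvBlock(self.out_width, self.out_width, 3)
        self.conv2 = nn.ConvBlock(self.out_width, self.out_width, 3)
        self.attn = make_attention(self.out_width, enc.gc_ratio, enc.attention)

    @property
    def resolution(self) -> int:
        return self.enc.stage_resolution(self.cfg.reference_stage)

    def forward(self, encoder_outputs: list[Tensor]) -> Tensor:
        if len(encoder_outputs) != len(self.branches):
            raise ValueError(
                f"expected {len(self.branches)} encoder outputs, "
                f"got {len(encoder_outputs)}"
            )
        parts = [branch(x) for branch, x in zip(self.branches, encoder_outputs)]
        ref_shape = parts[0].shape[2:]
        for p in parts:
            if p.shape[2:] != ref_shape:
                raise ValueError(f"branch resolutions differ: {p.shape[2:]} vs {ref_shape}")
        fused = concat(parts, axis=1)
        fused = self.conv2(self.conv1(self.reduce(fused)))
        return self.attn(fused)
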