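"""BFNet: the assembled encoder / mid-fusion / decoder network.

``ModelConfig`` spans the ablation matrix: stage depth (3-5), base channel
width, global-context attention on/off, mid+decoder channel reduction
on/off, and input size.  ``BFNet.segment`` maps a raw image array to a
per-pixel foreground probability map at the input resolution.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .autodiff import Tensor, no_grad
from .decoder import Decoder
from .encoder import Encoder, EncoderConfig
from .mid_fusion import MidConfig, MidFusion


@dataclass(frozen=True)
class ModelConfig:
    depth: int = 5
    base_width: int = 64
    input_size: int = 512
    in_channels: int = 3
    attention: bool = True
    reduce: bool = True
    gc_ratio: int = 8

    def encoder_config(self) -> EncoderConfig:
        return EncoderConfig(
            depth=self.depth,
            base_width=self.base_width,
            input_size=self.input_size,
            in_channels=self.in_channels,
            attention=self.attention,
            gc_ratio=self.gc_ratio,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "ModelConfig":
        return ModelConfig(**d)


class BFNet(nn.Module):
    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        enc_cfg = cfg.encoder_config()
        self.encoder = Encoder(enc_cfg)
        self.mid = MidFusion(enc_cfg, MidConfig.for_encoder(enc_cfg, reduce=cfg.reduce))
        self.decoder = Decoder(enc_cfg, self.mid)
        self.head = nn.Conv2d(self.decoder.out_width, 1, 1, bias=True)

    def forward(self, x: Tensor) -> Tensor:
        """(B, C, H, W) image batch -> (B, 1, H, W) foreground probabilities."""
        encs = self.encoder(x)
        mid = self.mid(encs)
        dec = self.decoder(encs, mid)
        return self.head(dec).sigmoid()

    def segment(self, image: np.ndarray) -> np.ndarray:
        """Segment one image array; returns an (H, W) probability map.

        Accepts (H, W, C), (C, H, W) or (H, W) grayscale; the spatial size
        must match the configured input size.
        """
        x = np.asarray(image, dtype=np.float32)
        if x.ndim == 2:
            x = np.stack([x] * self.cfg.in_channels, axis=0)
        elif x.ndim == 3 and x.shape[-1] == self.cfg.in_channels:
            x = x.transpose(2, 0, 1)
        elif x.ndim != 3 or x.shape[0] != self.cfg.in_channels:
            raise ValueError(f"cannot interpret image of shape {image.shape}")
        if x.shape[1] != self.cfg.input_size or x.shape[2] != self.cfg.input_size:
            raise ValueError(
                f"model configured for {self.cfg.input_size}px input, "
                f"got {x.shape[1:]}"
            )
        was_training = self.training
        self.eval()
        with no_grad():
            prob = self.forward(Tensor(x[None])).data[0, 0]
        if was_training:
            self.train()
        return prob


def build_model(cfg: ModelConfig, seed: int | None = None) -> BFNet:
    """Construct a BFNet; with a seed, construction is bit-reproducible."""
    if seed is not None:
        nn.seed_all(seed)
    return BFNet(cfg)
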