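"""Global-context (simplified non-local) attention.

The block computes a single context vector per feature map by softmax
attention pooling over all spatial positions, passes it through a
squeeze-excitation style bottleneck (1x1 down-projection, channel layer
norm, ReLU, 1x1 up-projection), and adds the result back identically at
every position:

    GCA(x) = x + W_up( relu( LN( W_down( pool(x) ) ) ) )
    pool(x) = sum_j softmax_j(w_k . x_j) * x_j

Because the context is pooled once per map, the added term is constant over
space — the simplification that makes the block cheap relative to a full
non-local block, which computes a query-specific context at every position.
A brute-force non-local implementation is provided as a reference oracle
for tests.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .autodiff import Tensor, matmul, softmax


def bottleneck_width(channels: int, ratio: int) -> int:
    """SE-style bottleneck width: max(1, floor(C / ratio))."""
    return max(1, channels // ratio)


def gc_param_count(channels: int, ratio: int = 8) -> int:
    """Closed-form parameter count of one GC block.

    context projection C->1 (+1 bias), two bias-free bottleneck projections
    C->Cb and Cb->C, and 2*Cb layer-norm parameters.
    """
    cb = bottleneck_width(channels, ratio)
    return channels + 1 + channels * cb + cb * channels + 2 * cb


class GCBlock(nn.Module):
    """Global-context attention over an NCHW feature map."""

    def __init__(self, channels: int, ratio: int = 8):
        super().__init__()
        self.channels = channels
        self.ratio = ratio
        cb = bottleneck_width(channels, ratio)
        self.context = nn.Conv2d(channels, 1, 1, bias=True)
        self.down = nn.Conv2d(channels, cb, 1, bias=False)
        self.norm = nn.ChannelLayerNorm(cb)
        self.up = nn.Conv2d(cb, channels, 1, bias=False)

    def pool_weights(self, x: Tensor) -> Tensor:
        """Softmax attention weights over the H*W positions, shape (B, 1, H*W)."""
        if x.shape[1] != self.channels:
            raise ValueError(
                f"GCBlock configured for {self.channels} channels, got {x.shape[1]}"
            )
        B, _, H, W = x.shape
        logits = self.context(x).reshape(B, 1, H * W)
        return softmax(logits, axis=2)

    def pool(self, x: Tensor) -> Tensor:
        """Attention-pooled context vector, shape (B, C, 1, 1)."""
        B, C, H, W = x.shape
        alpha = self.pool_weights(x)  # (B, 1, HW)
        xf = x.reshape(B, C, H * W)
        ctx = matmul(xf, alpha.transpose(0, 2, 1))  # (B, C, 1)
        return ctx.reshape(B, C, 1, 1)

    def forward(self, x: Tensor) -> Tensor:
        ctx = self.pool(x)
        t = self.up(self.norm(self.down(ctx)).relu())
        return x + t  # broadcast over H, W


def global_attention_pool(x: Tensor, block: GCBlock) -> Tensor:
    """Functional alias for :meth:`GCBlock.pool`."""
    return block.pool(x)


def make_attention(channels: int, ratio: int = 8, enabled: bool = True) -> nn.Module:
    """A GC block, or the identity when attention is ablated."""
    return GCBlock(channels, ratio) if enabled else nn.Identity()


# ---------------------------------------------------------------------------
# Brute-force non-local reference (test oracle only; O((HW)^2))


def nonlocal_oracle(
    x: np.ndarray, w_z: np.ndarray, w_v: np.ndarray, f: str | float = "gaussian"
) -> np.ndarray:
    """Exact double-loop non-local block on one (C, H, W) map.

    out_i = x_i + W_z . sum_j [ f(x_i, x_j) / N(x_i) ] . W_v . x_j

    with the embedded-Gaussian pairwise function f = exp(x_i . x_j) and
    softmax normalisation over j.  Passing a float for ``f`` uses that
    constant pairwise affinity instead (normalisation then yields uniform
    weights, i.e. a plain mean over positions).
    """
    C, H, W = x.shape
    if w_v.shape[1] != C or w_z.shape[1] != w_v.shape[0] or w_z.shape[0] != C:
        raise ValueError("nonlocal transform shapes must compose to C -> C")
    pos = x.reshape(C, H * W).T  # (N, C)
    n = pos.shape[0]
    out = np.empty_like(pos)
    for i in range(n):
        if isinstance(f, str) and f == "gaussian":
            logits = np.array([pos[i] @ pos[j] for j in range(n)], dtype=np.float64)
            logits -= logits.max()
            weights = np.exp(logits)
        else:
            weights = np.full(n, float(f))
        weights = weights / weights.sum()
        ctx = np.zeros(w_v.shape[0])
        for j in range(n):
            ctx += weights[j] * (w_v @ pos[j])
        out[i] = pos[i] + w_z @ ctx
    return out.T.reshape(C, H, W)
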