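"""Global-context attention: oracles, invariants, parameter arithmetic."""

import numpy as np
import pytest

from bfnet import nn
from bfnet.autodiff import Tensor, no_grad
from bfnet.gc_attention import (
    GCBlock,
    bottleneck_width,
    gc_param_count,
    global_attention_pool,
    make_attention,
    nonlocal_oracle,
)


def loop_attention_pool(x: np.ndarray, wk: np.ndarray, bk: float) -> np.ndarray:
    """Explicit double-loop oracle for softmax attention pooling on (C, H, W)."""
    C, H, W = x.shape
    logits = np.empty((H, W))
    for i in range(H):
        for j in range(W):
            logits[i, j] = float(wk @ x[:, i, j]) + bk
    weights = np.exp(logits - logits.max())
    weights /= weights.sum()
    ctx = np.zeros(C)
    for i in range(H):
        for j in range(W):
            ctx += weights[i, j] * x[:, i, j]
    return ctx


def make_block(channels, ratio=8, seed=0):
    nn.seed_all(seed)
    return GCBlock(channels, ratio)


def test_pool_uniform_input_returns_common_position():
    """Spatially uniform input: convex softmax pooling returns that value."""
    blk = make_block(3)
    col = np.array([0.3, -1.2, 2.0], dtype=np.float32)
    x = Tensor(np.tile(col[None, :, None, None], (1, 1, 4, 5)))
    ctx = global_attention_pool(x, blk).data[0, :, 0, 0]
    assert np.allclose(ctx, col, atol=1e-6)


def test_pool_single_position_identity():
    blk = make_block(4)
    x = Tensor(np.random.default_rng(0).standard_normal((2, 4, 1, 1)))
    ctx = global_attention_pool(x, blk).data
    assert np.allclose(ctx, x.data, atol=1e-7)


def test_pool_matches_loop_oracle_on_random_inputs(rng):
    """Vectorized pooling equals the double-loop oracle on 50 random inputs."""
    for k in range(50):
        C = int(rng.integers(1, 5))
        H, W = int(rng.integers(1, 6)), int(rng.integers(1, 6))
        blk = make_block(C, ratio=2, seed=k)
        x = rng.standard_normal((1, C, H, W)).astype(np.float32)
        expected = loop_attention_pool(
            x[0], blk.context.weight.data.reshape(-1), float(blk.context.bias.data[0])
        )
        got = global_attention_pool(Tensor(x), blk).data[0, :, 0, 0]
        assert np.allclose(got, expected, atol=1e-5)


def test_pool_weights_are_probability_distribution(rng):
    blk = make_block(2)
    x = Tensor(rng.standard_normal((3, 2, 3, 3)).astype(np.float32))
    w = blk.pool_weights(x).data
    assert (w >= 0).all()
    assert np.allclose(w.sum(axis=2), 1.0, atol=1e-6)


def test_gc_block_residual_identity_when_up_projection_zero(rng):
    blk = make_block(6)
    blk.up.weight.data[:] = 0.0
    x = Tensor(rng.standard_normal((2, 6, 5, 5)).astype(np.float32))
    with no_grad():
        out = blk(x)
    assert np.array_equal(out.data, x.data)


def test_gc_block_context_term_spatially_constant(rng):
    """(output - input) has zero variance across positions within a channel."""
    blk = make_block(8)
    x = Tensor(rng.standard_normal((2, 8, 7, 7)).astype(np.float32))
    with no_grad():
        delta = (blk(x).data - x.data).reshape(2, 8, -1)
    assert (delta.max(axis=2) - delta.min(axis=2) < 1e-6).all()


def test_gc_block_matches_scripted_composition(rng):
    """Step-by-step composition: pool, down, norm+relu, up, residual add."""
    blk = make_block(4, ratio=2)
    x = rng.standard_normal((1, 4, 5, 5)).astype(np.float32)
    ctx = loop_attention_pool(
        x[0], blk.context.weight.data.reshape(-1), float(blk.context.bias.data[0])
    )
    down = blk.down.weight.data.reshape(2, 4) @ ctx
    mu, var = down.mean(), down.var()
    normed = (down - mu) / np.sqrt(var + blk.norm.eps)
    normed = normed * blk.norm.gamma.data.reshape(-1) + blk.norm.beta.data.reshape(-1)
    up = blk.up.weight.data.reshape(4, 2) @ np.maximum(normed, 0.0)
    expected = x + up[None, :, None, None]
    with no_grad():
        got = blk(Tensor(x)).data
    assert np.allclose(got, expected, atol=1e-5)


def test_channel_mismatch_raises(rng):
    blk = make_block(4)
    with pytest.raises(ValueError, match="channels"):
        blk(Tensor(rng.standard_normal((1, 3, 4, 4)).astype(np.float32)))


@pytest.mark.parametrize("channels", [3, 8, 64, 257])
def test_parameter_count_closed_form(channels):
    blk = make_block(channels)
    cb = bottleneck_width(channels, 8)
    assert cb == max(1, channels // 8)
    assert blk.num_parameters() == gc_param_count(channels, 8)
    assert (
        gc_param_count(channels, 8)
        == channels + 1 + channels * cb + cb * channels + 2 * cb
    )


def test_make_attention_disabled_is_identity(rng):
    m = make_attention(5, enabled=False)
    x = Tensor(rng.standard_normal((1, 5, 3, 3)))
    assert m(x) is x


# -- brute-force non-local oracle ------------------------------------------


def test_nonlocal_zero_projection_is_identity(rng):
    x = rng.standard_normal((3, 2, 2))
    out = nonlocal_oracle(x, np.zeros((3, 2)), rng.standard_normal((2, 3)))
    assert np.allclose(out, x)


def test_nonlocal_single_position(rng):
    x = rng.standard_normal((3, 1, 1))
    wz = rng.standard_normal((3, 2))
    wv = rng.standard_normal((2, 3))
    out = nonlocal_oracle(x, wz, wv)
    expected = x[:, 0, 0] + wz @ (wv @ x[:, 0, 0])
    assert np.allclose(out[:, 0, 0], expected)


def test_nonlocal_constant_affinity_is_mean_context(rng):
    """f == const: the context term is Wz Wv (mean of positions) everywhere."""
    x = rng.standard_normal((2, 2, 2))
    wz = rng.standard_normal((2, 2))
    wv = rng.standard_normal((2, 2))
    out = nonlocal_oracle(x, wz, wv, f=0.7)
    mean_pos = x.reshape(2, 4).mean(axis=1)
    ctx = wz @ (wv @ mean_pos)
    for i in range(2):
        for j in range(2):
            assert np.allclose(out[:, i, j], x[:, i, j] + ctx)


def test_nonlocal_context_nearly_query_independent(rng):
    """The aggregated non-local context varies little across query positions,
    motivating the single-context simplification of the GC block."""
    x = (0.1 * rng.standard_normal((4, 3, 3))).astype(np.float64)
    wz = np.eye(4)
    wv = rng.standard_normal((4, 4))
    ctx = (nonlocal_oracle(x, wz, wv) - x).reshape(4, -1)
    spread = np.ptp(ctx, axis=1).max()
    scale = np.abs(ctx).max() + 1e-12
    assert spread / scale < 0.25
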