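"""Residual dense block (RDB) and low-level feature extraction (LLFE).

The RDB is a DenseNet-style unit: three convolutional blocks (conv + leaky
ReLU) where block *j* sees the concatenation of the block input and every
previous block's output, followed by a 1x1 fusion convolution back to the
input channel count and a residual connection.  Zeroing all parameters
therefore makes the block an exact identity.

The LLFE stem shared by both branches is: stem conv (+LReLU) -> RDB ->
2x2 max pool -> RDB -> 2x2 max pool, shrinking the image by 4x per side so
that patch tokenization operates on compact low-level feature maps rather
than raw pixels.
"""

from __future__ import annotations

import numpy as np

from ._tensor import Tensor, concat, leaky_relu, maxpool2d
from .config import LLFEConfig, RDBParams
from .nn import Conv2d, Module


class ResidualDenseBlock(Module):
    def __init__(self, channels: int, params: RDBParams, rng: np.random.Generator):
        self.channels = channels
        self.slope = params.lrelu_slope
        self.convs = []
        in_ch = channels
        for _ in range(params.n_blocks):
            self.convs.append(Conv2d(in_ch, params.growth, params.kernel, rng))
            in_ch += params.growth
        # 1x1 fusion maps the dense concatenation back to the input width so
        # the residual sum is shape-compatible
        self.fusion = Conv2d(in_ch, channels, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise ValueError(
                f"RDB configured for {self.channels} channels got {x.shape[1]} "
                f"(first dense conv would fail)"
            )
        feats = [x]
        for conv in self.convs:
            inp = feats[0] if len(feats) == 1 else concat(feats, axis=1)
            feats.append(leaky_relu(conv(inp), self.slope))
        fused = self.fusion(concat(feats, axis=1))
        return x + fused


class LLFE(Module):
    """One stem convolution, two residual dense blocks, two max poolings."""

    def __init__(self, cfg: LLFEConfig, rng: np.random.Generator, in_channels: int = 1):
        self.cfg = cfg
        self.stem = Conv2d(in_channels, cfg.stem_channels, cfg.rdb.kernel, rng)
        self.rdb1 = ResidualDenseBlock(cfg.stem_channels, cfg.rdb, rng)
        self.rdb2 = ResidualDenseBlock(cfg.stem_channels, cfg.rdb, rng)
        self.pool = cfg.pool

    def forward(self, x: Tensor) -> Tensor:
        _, _, h, w = x.shape
        factor = self.pool ** 2
        if h % factor or w % factor:
            raise ValueError(
                f"LLFE input spatial size ({h},{w}) must be divisible by {factor} "
                f"(two {self.pool}x{self.pool} poolings)"
            )
        z = self.stem(x)
        if self.cfg.stem_activation:
            z = leaky_relu(z, self.cfg.rdb.lrelu_slope)
        z = maxpool2d(self.rdb1(z), self.pool)
        z = maxpool2d(self.rdb2(z), self.pool)
        return z


# -- functional wrappers -------------------------------------------------------

def rdb_forward(x: np.ndarray | Tensor, block: ResidualDenseBlock) -> np.ndarray:
    """Run one residual dense block on a (B, C, H, W) array."""
    t = x if isinstance(x, Tensor) else Tensor(x)
    return block(t).data


def llfe_forward(x: np.ndarray | Tensor, module: LLFE) -> np.ndarray:
    """Run the LLFE stem on a (B, C, H, W) array; output is (B, stem, H/4, W/4)."""
    t = x if isinstance(x, Tensor) else Tensor(x)
    return module(t).data
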