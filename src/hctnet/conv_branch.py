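"""ConvNet branch: translation-tolerant high-level local features.

Three residual-dense-block + 2x2 max-pool stages (so the feature map shrinks
8x per side), then global average pooling and a single linear projection into
the shared D-dimensional fusion space.  The projection carries no activation;
it only aligns the convolutional representation with the transformer
branch's output dimension.
"""

from __future__ import annotations

import numpy as np

from ._tensor import Tensor, maxpool2d
from .blocks import ResidualDenseBlock
from .config import CBranchConfig
from .nn import Linear, Module


class ConvBranch(Module):
    def __init__(self, in_channels: int, D: int, cfg: CBranchConfig,
                 rng: np.random.Generator):
        if in_channels != cfg.channels:
            raise ValueError(
                f"C-branch configured for {cfg.channels} channels, LLFE emits {in_channels}"
            )
        self.stages = [
            ResidualDenseBlock(cfg.channels, cfg.rdb, rng) for _ in range(3)
        ]
        self.pool = cfg.pool
        self.fc = Linear(cfg.channels, D, rng)

    def forward(self, f: Tensor) -> Tensor:
        _, _, h, w = f.shape
        factor = self.pool ** 3
        if h % factor or w % factor:
            raise ValueError(
                f"C-branch input spatial size ({h},{w}) must be divisible by {factor} "
                f"(three {self.pool}x{self.pool} poolings)"
            )
        z = f
        for rdb in self.stages:
            z = maxpool2d(rdb(z), self.pool)
        pooled = z.mean(axis=(2, 3))  # global average pool -> (B, C)
        return self.fc(pooled)


def c_branch_forward(f: np.ndarray, branch: ConvBranch) -> np.ndarray:
    """Run the ConvNet branch on a (B, C, H, W) array; output is (B, D)."""
    return branch(Tensor(f)).data
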