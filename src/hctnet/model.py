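"""HCTNet model assembly, including the ablation variants.

Variants, from the pure-transformer baseline upward:

- ``vit_only``: patch tokenization of the raw image, encoder stack, linear head.
- ``llfe_vit``: LLFE stem feeding the transformer branch only.
- ``llfe_vit_cbranch_concat``: both branches, fused by plain concatenation + FC.
- ``full``: both branches with the adaptive re-weighting fusion module.
"""

from __future__ import annotations

import numpy as np

from ._tensor import Tensor, concat
from .blocks import LLFE
from .config import ABLATION_MODES, ArchConfig
from .conv_branch import ConvBranch
from .fusion import ClassifierHead, FeatureFusion
from .nn import Linear, Module
from .transformer import TransformerBranch


class HCTNet(Module):
    """Hybrid ConvNet-Transformer classifier over (B, 1, H, W) image batches."""

    def __init__(self, arch: ArchConfig, mode: str = "full",
                 rng: np.random.Generator | None = None, in_channels: int = 1):
        if mode not in ABLATION_MODES:
            raise ValueError(f"unknown ablation mode {mode!r}; valid: {ABLATION_MODES}")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.mode = mode
        self.arch = arch
        h, w = arch.input_hw
        enc = arch.encoder
        if mode == "vit_only":
            self.t_branch = TransformerBranch(
                in_channels, (h, w), arch.vit_patch, enc, rng
            )
            self.head = ClassifierHead(enc.D, arch.n_classes, rng)
            return
        self.llfe = LLFE(arch.llfe, rng, in_channels)
        feat_hw = (h // 4, w // 4)
        self.t_branch = TransformerBranch(
            arch.llfe.stem_channels, feat_hw, arch.patch.P, enc, rng
        )
        if mode == "llfe_vit":
            self.head = ClassifierHead(enc.D, arch.n_classes, rng)
            return
        self.c_branch = ConvBranch(arch.llfe.stem_channels, enc.D, arch.c_branch, rng)
        if mode == "llfe_vit_cbranch_concat":
            self.concat_fc = Linear(2 * enc.D, enc.D, rng)
            self.head = ClassifierHead(enc.D, arch.n_classes, rng)
        else:  # full
            self.fusion = FeatureFusion(enc.D, rng)
            self.head = ClassifierHead(enc.D, arch.n_classes, rng)

    def forward(self, x: Tensor) -> Tensor:
        if self.mode == "vit_only":
            return self.head(self.t_branch(x))
        f = self.llfe(x)
        t_feat = self.t_branch(f)
        if self.mode == "llfe_vit":
            return self.head(t_feat)
        c_feat = self.c_branch(f)
        if self.mode == "llfe_vit_cbranch_concat":
            return self.head(self.concat_fc(concat([t_feat, c_feat], axis=1)))
        return self.head(self.fusion(t_feat, c_feat))

    def logits(self, x: np.ndarray) -> np.ndarray:
        return self(Tensor(np.asarray(x, dtype=np.float32))).data

    def parameter_manifest(self) -> dict[str, tuple[int, ...]]:
        return {name: tuple(p.data.shape) for name, p in self.named_parameters()}


def assemble_model(arch: ArchConfig, mode: str = "full", seed: int = 0) -> HCTNet:
    """Build an HCTNet variant with Xavier-initialized weights."""
    return HCTNet(arch, mode=mode, rng=np.random.default_rng(seed))
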