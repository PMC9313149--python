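"""Architecture and training configuration.

All structural hyperparameters of the network live in :class:`ArchConfig`,
which round-trips through YAML so a single config file drives model assembly
(`hctnet train --config ...`).  Defaults target the full-size model
(224x224 input); :meth:`ArchConfig.reduced` is a small CPU-friendly variant
for 64x64 inputs used throughout the tests.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

ABLATION_MODES = ("vit_only", "llfe_vit", "llfe_vit_cbranch_concat", "full")


@dataclass
class RDBParams:
    """Residual dense block: three conv+LReLU blocks, dense connectivity,
    1x1 fusion back to the input width, residual sum."""

    n_blocks: int = 3
    growth: int = 32
    kernel: int = 3
    lrelu_slope: float = 0.2


@dataclass
class LLFEConfig:
    """Low-level feature extraction: stem conv, two RDBs, two 2x2 max pools
    (so the output is 1/4 of the input in each spatial dimension)."""

    stem_channels: int = 32
    rdb: RDBParams = field(default_factory=RDBParams)
    pool: int = 2
    stem_activation: bool = True


@dataclass
class EncoderConfig:
    """Transformer encoder stack: L pre-norm blocks of MSA + MLP."""

    L: int = 12
    D: int = 384
    h: int = 6
    k_mlp: int | None = None  # defaults to 4*D
    ln_eps: float = 1e-6

    @property
    def mlp_hidden(self) -> int:
        return 4 * self.D if self.k_mlp is None else self.k_mlp


@dataclass
class PatchConfig:
    P: int = 7  # patch side length on the LLFE feature map


@dataclass
class CBranchConfig:
    """ConvNet branch: three RDB + max-pool stages at constant width,
    global average pooling, then a linear projection to dimension D."""

    rdb: RDBParams = field(default_factory=RDBParams)
    pool: int = 2
    channels: int = 32


@dataclass
class ArchConfig:
    n_classes: int = 4
    input_hw: tuple[int, int] = (224, 224)
    llfe: LLFEConfig = field(default_factory=LLFEConfig)
    patch: PatchConfig = field(default_factory=PatchConfig)
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    c_branch: CBranchConfig = field(default_factory=CBranchConfig)
    vit_patch: int = 16  # patch size for the raw-image ablation (no LLFE)

    @classmethod
    def reduced(cls, n_classes: int = 4, input_hw: tuple[int, int] = (64, 64)) -> "ArchConfig":
        """Small configuration (L=4, D=128, 16-channel stem) for CPU-scale runs."""
        rdb = RDBParams(growth=8)
        return cls(
            n_classes=n_classes,
            input_hw=tuple(input_hw),
            llfe=LLFEConfig(stem_channels=16, rdb=rdb),
            patch=PatchConfig(P=4),
            encoder=EncoderConfig(L=4, D=128, h=4),
            c_branch=CBranchConfig(rdb=rdb, channels=16),
            vit_patch=8,
        )

    # -- YAML round trip ------------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ArchConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ArchConfig":
        def rdb(d):
            return RDBParams(**d)

        return cls(
            n_classes=raw.get("n_classes", 4),
            input_hw=tuple(raw.get("input_hw", (224, 224))),
            llfe=LLFEConfig(
                stem_channels=raw["llfe"]["stem_channels"],
                rdb=rdb(raw["llfe"]["rdb"]),
                pool=raw["llfe"].get("pool", 2),
                stem_activation=raw["llfe"].get("stem_activation", True),
            )
            if "llfe" in raw
            else LLFEConfig(),
            patch=PatchConfig(**raw.get("patch", {})),
            encoder=EncoderConfig(**raw.get("encoder", {})),
            c_branch=CBranchConfig(
                rdb=rdb(raw["c_branch"]["rdb"]),
                pool=raw["c_branch"].get("pool", 2),
                channels=raw["c_branch"].get("channels", 32),
            )
            if "c_branch" in raw
            else CBranchConfig(),
            vit_patch=raw.get("vit_patch", 16),
        )


@dataclass
class TrainConfig:
    """Optimization protocol: Adam, step-decayed learning rate, early stopping."""

    batch_size: int = 32
    weight_decay: float = 1e-4
    lr0: float = 3e-4
    lr_step: int = 10
    lr_gamma: float = 0.1
    patience: int = 10  # early-stopping patience on validation loss, epochs
    max_epochs: int = 50
    seed: int = 0
    ablation_mode: str = "full"

    def __post_init__(self):
        if self.ablation_mode not in ABLATION_MODES:
            raise ValueError(
                f"unknown ablation_mode {self.ablation_mode!r}; valid: {ABLATION_MODES}"
            )
        for name in ("batch_size", "lr0", "lr_step", "lr_gamma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
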