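"""Transformer branch: patch tokenization, multi-head self-attention,
encoder stack, and the class-token image representation.

Tokenization splits the (B, C, H, W) feature map into N = HW/P^2 ordered
P x P patches (row-major patch order, row-major within-patch flattening,
channels last), projects each flattened patch with a learned matrix E into a
D-dimensional embedding, prepends a learnable class token and adds a learned
position table, giving the length-(N+1) token sequence

    z0 = [Eclass; f_p1 E; ...; f_pN E] + Epos.

Each of the L encoder blocks applies pre-norm attention and a pre-norm MLP,
both with residual connections:

    z' = MSA(LN(z)) + z,   z_next = MLP(LN(z')) + z'.

Attention scales query-key dot products by sqrt(d_head) per head (identical
to a sqrt(D) scale when a single head is used).  The branch output is the
layer-normalized class token of the last block, y = LN(z_L[0]).
"""

from __future__ import annotations

import math

import numpy as np

from ._tensor import DTYPE, Tensor, gelu, matmul, softmax
from .config import EncoderConfig
from .nn import LayerNorm, Linear, Module, Parameter, truncated_normal


class PatchEmbedding(Module):
    """Learned linear projection of flattened patches, class token, position table."""

    def __init__(self, in_channels: int, hw: tuple[int, int], P: int, D: int,
                 rng: np.random.Generator):
        h, w = hw
        if h % P or w % P:
            raise ValueError(f"feature map ({h},{w}) not divisible by patch size {P}")
        self.P = P
        self.N = (h * w) // (P * P)
        self.in_channels = in_channels
        self.proj = Linear(P * P * in_channels, D, rng)
        self.cls_token = Parameter(truncated_normal(rng, (1, 1, D)))
        self.pos_table = Parameter(truncated_normal(rng, (1, self.N + 1, D)))

    def forward(self, f: Tensor) -> Tensor:
        b, c, h, w = f.shape
        p = self.P
        if h % p or w % p:
            raise ValueError(f"feature map ({h},{w}) not divisible by patch size {p}")
        n = (h * w) // (p * p)
        if n != self.N or c != self.in_channels:
            raise ValueError(
                f"embedding built for N={self.N}, C={self.in_channels}; got N={n}, C={c}"
            )
        # (B,C,H,W) -> (B, H/P, W/P, P, P, C) -> (B, N, P*P*C); channels last
        patches = (
            f.transpose(0, 2, 3, 1)
            .reshape(b, h // p, p, w // p, p, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(b, n, p * p * c)
        )
        tokens = self.proj(patches)  # (B, N, D)
        cls = self.cls_token + Tensor(np.zeros((b, 1, 1), dtype=DTYPE))  # broadcast copy
        z0 = _cat_tokens(cls, tokens)
        return z0 + self.pos_table


def _cat_tokens(cls: Tensor, tokens: Tensor) -> Tensor:
    from ._tensor import concat

    return concat([cls, tokens], axis=1)


class MultiHeadSelfAttention(Module):
    def __init__(self, D: int, h: int, rng: np.random.Generator):
        if D % h:
            raise ValueError(f"embedding dim D={D} not divisible by head count h={h}")
        self.h = h
        self.d_head = D // h
        self.wq = Linear(D, D, rng)
        self.wk = Linear(D, D, rng)
        self.wv = Linear(D, D, rng)
        self.wo = Linear(D, D, rng)

    def _heads(self, x: Tensor, b: int, t: int) -> Tensor:
        return x.reshape(b, t, self.h, self.d_head).transpose(0, 2, 1, 3)

    def forward(self, z: Tensor) -> Tensor:
        b, t, d = z.shape
        q = self._heads(self.wq(z), b, t)  # (B, h, T, d_head)
        k = self._heads(self.wk(z), b, t)
        v = self._heads(self.wv(z), b, t)
        scores = matmul(q, k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(self.d_head))
        attn = softmax(scores, axis=-1)  # rows sum to 1
        ctx = matmul(attn, v)  # (B, h, T, d_head)
        merged = ctx.transpose(0, 2, 1, 3).reshape(b, t, d)
        return self.wo(merged)

    def attention_weights(self, z: np.ndarray) -> np.ndarray:
        """Return the (B, h, T, T) softmax attention matrix for inspection."""
        t = z.shape[1]
        zt = Tensor(z)
        q = self._heads(self.wq(zt), z.shape[0], t)
        k = self._heads(self.wk(zt), z.shape[0], t)
        scores = matmul(q, k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(self.d_head))
        return softmax(scores, axis=-1).data


class MLP(Module):
    """Per-token two-layer perceptron with GELU: sigma(x W1 + b1) W2 + b2."""

    def __init__(self, D: int, hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(D, hidden, rng)
        self.fc2 = Linear(hidden, D, rng)

    def forward(self, z: Tensor) -> Tensor:
        return self.fc2(gelu(self.fc1(z)))


class EncoderBlock(Module):
    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        self.ln1 = LayerNorm(cfg.D, cfg.ln_eps)
        self.msa = MultiHeadSelfAttention(cfg.D, cfg.h, rng)
        self.ln2 = LayerNorm(cfg.D, cfg.ln_eps)
        self.mlp = MLP(cfg.D, cfg.mlp_hidden, rng)

    def forward(self, z: Tensor) -> Tensor:
        z = self.msa(self.ln1(z)) + z
        z = self.mlp(self.ln2(z)) + z
        return z


class TransformerBranch(Module):
    """tokenize -> L encoder blocks -> LN -> class-token slice."""

    def __init__(self, in_channels: int, hw: tuple[int, int], P: int,
                 cfg: EncoderConfig, rng: np.random.Generator):
        self.embed = PatchEmbedding(in_channels, hw, P, cfg.D, rng)
        self.blocks = [EncoderBlock(cfg, rng) for _ in range(cfg.L)]
        self.final_ln = LayerNorm(cfg.D, cfg.ln_eps)

    def forward(self, f: Tensor) -> Tensor:
        z = self.embed(f)
        for block in self.blocks:
            z = block(z)
        return self.final_ln(z[:, 0, :])  # (B, D)


# -- functional wrappers -------------------------------------------------------

def tokenize(f: np.ndarray, emb: PatchEmbedding) -> np.ndarray:
    """Token sequence z0 (B, N+1, D) for a feature-map batch."""
    return emb(Tensor(f)).data


def msa(z: np.ndarray, attn: MultiHeadSelfAttention) -> np.ndarray:
    return attn(Tensor(z)).data


def mlp(z: np.ndarray, block: MLP) -> np.ndarray:
    return block(Tensor(z)).data


def encoder_forward(z: np.ndarray, block: EncoderBlock) -> np.ndarray:
    return block(Tensor(z)).data


def t_branch_forward(f: np.ndarray, branch: TransformerBranch) -> np.ndarray:
    return branch(Tensor(f)).data
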