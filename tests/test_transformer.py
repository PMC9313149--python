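"""Tokenization, attention, MLP and encoder: oracles and structural contracts."""

import numpy as np
import pytest

from hctnet import (
    EncoderBlock,
    EncoderConfig,
    MLP,
    MultiHeadSelfAttention,
    PatchEmbedding,
    TransformerBranch,
    encoder_forward,
    mlp,
    msa,
    t_branch_forward,
    tokenize,
)
from hctnet._tensor import Tensor

from .helpers import brute_force_attention


# -- tokenization --------------------------------------------------------------

def test_token_count_is_patches_plus_class_token(rng):
    emb = PatchEmbedding(2, (56, 56), P=7, D=8, rng=rng)
    assert emb.N == 64
    z0 = tokenize(rng.normal(size=(1, 2, 56, 56)).astype(np.float32), emb)
    assert z0.shape == (1, 65, 8)


def test_zero_projection_leaves_only_class_token(rng):
    emb = PatchEmbedding(1, (4, 4), P=2, D=3, rng=rng)
    emb.proj.weight.data[...] = 0.0
    emb.proj.bias.data[...] = 0.0
    emb.pos_table.data[...] = 0.0
    z0 = tokenize(rng.normal(size=(2, 1, 4, 4)).astype(np.float32), emb)
    np.testing.assert_allclose(z0[:, 0, :], np.broadcast_to(emb.cls_token.data[0, 0], (2, 3)))
    np.testing.assert_array_equal(z0[:, 1:, :], 0.0)


def test_tokenize_matches_hand_projection(rng):
    """2x2 single-channel map with P=1: each pixel is one patch; tokens are
    pixel * E + position, in row-major patch order."""
    emb = PatchEmbedding(1, (2, 2), P=1, D=2, rng=rng)
    E = np.array([[1.5, -2.0]], dtype=np.float32)  # (P^2*C=1, D=2)
    emb.proj.weight.data[...] = E
    emb.proj.bias.data[...] = 0.0
    pos = rng.normal(size=(1, 5, 2)).astype(np.float32)
    emb.pos_table.data[...] = pos
    cls = rng.normal(size=2).astype(np.float32)
    emb.cls_token.data[...] = cls
    f = np.array([[[[1.0, 2.0], [3.0, 4.0]]]], dtype=np.float32)
    z0 = tokenize(f, emb)
    expected_patches = np.array([[1, 2, 3, 4]], dtype=np.float32).T @ E  # row-major
    np.testing.assert_allclose(z0[0, 0], cls + pos[0, 0], rtol=1e-6)
    np.testing.assert_allclose(z0[0, 1:], expected_patches + pos[0, 1:], rtol=1e-6)


def test_tokenize_rejects_indivisible_map(rng):
    with pytest.raises(ValueError, match="divisible"):
        PatchEmbedding(1, (5, 5), P=2, D=4, rng=rng)


# -- attention -----------------------------------------------------------------

def test_single_head_attention_matches_brute_force(rng):
    attn = MultiHeadSelfAttention(D=4, h=1, rng=rng)
    z = rng.normal(size=(1, 3, 4)).astype(np.float32)
    expected = brute_force_attention(
        z[0],
        attn.wq.weight.data, attn.wq.bias.data,
        attn.wk.weight.data, attn.wk.bias.data,
        attn.wv.weight.data, attn.wv.bias.data,
        attn.wo.weight.data, attn.wo.bias.data,
    )
    np.testing.assert_allclose(msa(z, attn)[0], expected, atol=1e-5)


def test_identical_tokens_give_uniform_attention(rng):
    attn = MultiHeadSelfAttention(D=8, h=2, rng=rng)
    z = np.tile(rng.normal(size=(1, 1, 8)).astype(np.float32), (1, 5, 1))
    w = attn.attention_weights(z)
    np.testing.assert_allclose(w, 1.0 / 5.0, atol=1e-6)


def test_attention_rows_sum_to_one(rng):
    attn = MultiHeadSelfAttention(D=12, h=3, rng=rng)
    z = rng.normal(size=(2, 7, 12)).astype(np.float32)
    w = attn.attention_weights(z)
    assert (w >= 0).all()
    np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-6)


def test_head_count_must_divide_dimension(rng):
    with pytest.raises(ValueError, match="divisible"):
        MultiHeadSelfAttention(D=10, h=3, rng=rng)


# -- MLP -----------------------------------------------------------------------

def test_mlp_zero_params_gives_zero(rng):
    block = MLP(D=4, hidden=8, rng=rng)
    block.zero_()
    z = rng.normal(size=(1, 3, 4)).astype(np.float32)
    np.testing.assert_array_equal(mlp(z, block), 0.0)


def test_mlp_scalar_identity_weights_reduce_to_gelu(rng):
    from scipy.special import erf

    block = MLP(D=1, hidden=1, rng=rng)
    block.fc1.weight.data[...] = 1.0
    block.fc1.bias.data[...] = 0.0
    block.fc2.weight.data[...] = 1.0
    block.fc2.bias.data[...] = 0.0
    z = rng.normal(size=(1, 4, 1)).astype(np.float32)
    expected = z * 0.5 * (1 + erf(z / np.sqrt(2)))
    np.testing.assert_allclose(mlp(z, block), expected, atol=1e-6)


def test_mlp_matches_direct_matrix_arithmetic(rng):
    from scipy.special import erf

    block = MLP(D=3, hidden=5, rng=rng)
    z = rng.normal(size=(2, 4, 3)).astype(np.float32)
    h = z @ block.fc1.weight.data + block.fc1.bias.data
    h = h * 0.5 * (1 + erf(h / np.sqrt(2)))
    expected = h @ block.fc2.weight.data + block.fc2.bias.data
    np.testing.assert_allclose(mlp(z, block), expected, atol=1e-5)


# -- encoder -------------------------------------------------------------------

def test_encoder_zeroed_weights_is_identity(rng):
    cfg = EncoderConfig(L=1, D=6, h=2, k_mlp=12)
    block = EncoderBlock(cfg, rng)
    block.zero_()
    z = rng.normal(size=(2, 4, 6)).astype(np.float32)
    np.testing.assert_array_equal(encoder_forward(z, block), z)


def test_encoder_stack_preserves_shape(rng):
    cfg = EncoderConfig(L=12, D=16, h=4, k_mlp=32)
    blocks = [EncoderBlock(cfg, rng) for _ in range(cfg.L)]
    z = rng.normal(size=(2, 9, 16)).astype(np.float32)
    for block in blocks:
        z_next = encoder_forward(z, block)
        assert z_next.shape == z.shape
        z = z_next


def test_branch_output_is_batch_by_dim_and_composes(rng):
    """L=1 branch equals explicit tokenize -> encoder -> LN -> class slice."""
    cfg = EncoderConfig(L=1, D=8, h=2, k_mlp=16)
    branch = TransformerBranch(1, (8, 8), P=4, cfg=cfg, rng=rng)
    f = rng.normal(size=(3, 1, 8, 8)).astype(np.float32)
    out = t_branch_forward(f, branch)
    assert out.shape == (3, 8)
    z = branch.embed(Tensor(f))
    z = branch.blocks[0](z)
    expected = branch.final_ln(z[:, 0, :]).data
    np.testing.assert_allclose(out, expected, atol=1e-6)


def test_position_table_carries_order_information(rng):
    """Permuting patches changes the representation unless positions are zeroed
    and all patches identical."""
    cfg = EncoderConfig(L=1, D=8, h=2, k_mlp=16)
    branch = TransformerBranch(1, (4, 4), P=2, cfg=cfg, rng=rng)
    f = rng.normal(size=(1, 1, 4, 4)).astype(np.float32)
    # swap the two left patches with the two right patches
    f_perm = f[:, :, :, [2, 3, 0, 1]].copy()
    assert not np.allclose(t_branch_forward(f, branch), t_branch_forward(f_perm, branch))

    branch.embed.pos_table.data[...] = 0.0
    f_const = np.tile(f[:, :, :2, :2], (1, 1, 2, 2))
    np.testing.assert_allclose(
        t_branch_forward(f_const, branch),
        t_branch_forward(f_const[:, :, :, [2, 3, 0, 1]].copy(), branch),
        atol=1e-5,
    )
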