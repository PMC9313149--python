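"""Adaptive fusion, classifier head and cross-entropy loss."""

import math

import numpy as np
import pytest

from hctnet import (
    ArchConfig,
    CBranchConfig,
    ClassifierHead,
    EncoderConfig,
    FeatureFusion,
    LLFEConfig,
    PatchConfig,
    RDBParams,
    assemble_model,
    classify,
    cross_entropy_loss,
    fuse,
)
from hctnet._tensor import Tensor
from hctnet.nn import Adam
from hctnet.training import one_hot


def tiny_arch(n_classes=3):
    rdb = RDBParams(growth=4)
    return ArchConfig(
        n_classes=n_classes, input_hw=(32, 32),
        llfe=LLFEConfig(stem_channels=4, rdb=rdb),
        patch=PatchConfig(P=2),
        encoder=EncoderConfig(L=1, D=8, h=2, k_mlp=16),
        c_branch=CBranchConfig(rdb=rdb, channels=4),
        vit_patch=8,
    )


# -- fuse ----------------------------------------------------------------------

def test_zero_scores_average_the_branches(rng):
    fusion = FeatureFusion(D=5, rng=rng)
    fusion.zero_()
    t = rng.normal(size=(2, 5)).astype(np.float32)
    c = rng.normal(size=(2, 5)).astype(np.float32)
    np.testing.assert_allclose(fuse(t, c, fusion), (t + c) / 2, atol=1e-6)


def test_saturated_scores_select_one_branch(rng):
    fusion = FeatureFusion(D=4, rng=rng)
    fusion.zero_()
    fusion.score_t.bias.data[...] = 50.0  # softmax saturates toward the T-branch
    t = rng.normal(size=(3, 4)).astype(np.float32)
    c = rng.normal(size=(3, 4)).astype(np.float32)
    np.testing.assert_allclose(fuse(t, c, fusion), t, atol=1e-5)


def test_two_dim_fusion_matches_hand_softmax(rng):
    fusion = FeatureFusion(D=2, rng=rng)
    fusion.score_t.weight.data[...] = np.array([[1.0, 0.0], [0.0, -1.0]], np.float32)
    fusion.score_t.bias.data[...] = np.array([0.1, 0.2], np.float32)
    fusion.score_c.weight.data[...] = np.array([[0.5, 0.3], [-0.2, 0.4]], np.float32)
    fusion.score_c.bias.data[...] = 0.0
    t = np.array([[0.4, -0.7]], np.float32)
    c = np.array([[1.2, 0.3]], np.float32)
    st = t @ fusion.score_t.weight.data + fusion.score_t.bias.data
    sc = c @ fusion.score_c.weight.data
    wt = np.exp(st) / (np.exp(st) + np.exp(sc))
    expected = wt * t + (1 - wt) * c
    np.testing.assert_allclose(fuse(t, c, fusion), expected, rtol=1e-5)


def test_fusion_weights_are_convex(rng):
    fusion = FeatureFusion(D=6, rng=rng)
    t = rng.normal(size=(4, 6)).astype(np.float32)
    c = rng.normal(size=(4, 6)).astype(np.float32)
    w = fusion.weights(t, c)
    assert (w >= 0).all() and (w <= 1).all()
    np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-6)
    fused = fuse(t, c, fusion)
    lo, hi = np.minimum(t, c), np.maximum(t, c)
    assert (fused >= lo - 1e-5).all() and (fused <= hi + 1e-5).all()


def test_fusion_rejects_dimension_mismatch(rng):
    fusion = FeatureFusion(D=4, rng=rng)
    with pytest.raises(ValueError, match="dimension"):
        fusion(Tensor(np.zeros((1, 3), np.float32)), Tensor(np.zeros((1, 4), np.float32)))


# -- classify ------------------------------------------------------------------

def test_zero_head_gives_uniform_probabilities(rng):
    head = ClassifierHead(D=5, n_classes=4, rng=rng)
    head.zero_()
    _, proba, labels = classify(rng.normal(size=(3, 5)).astype(np.float32), head)
    np.testing.assert_allclose(proba, 0.25, atol=1e-7)
    assert (labels == 0).all()  # lowest-index tie break


def test_probabilities_match_softmax_closed_form(rng):
    from hctnet.fusion import predict_proba_from_logits

    logits = np.array([[2.0, 0.0, 0.0, 0.0]])
    p = predict_proba_from_logits(logits)
    assert p.argmax() == 0
    np.testing.assert_allclose(p[0, 0], math.exp(2) / (math.exp(2) + 3), rtol=1e-9)

    random_logits = rng.normal(size=(10, 4))
    np.testing.assert_allclose(predict_proba_from_logits(random_logits).sum(axis=1), 1.0,
                               atol=1e-6)


# -- loss ----------------------------------------------------------------------

def test_cross_entropy_examples():
    # perfect prediction -> ~0
    logits = Tensor(np.array([[50.0, 0.0, 0.0, 0.0]], np.float32))
    assert float(cross_entropy_loss(logits, one_hot(np.array([0]), 4)).data) < 1e-6
    # uniform prediction -> ln 4
    logits = Tensor(np.zeros((1, 4), np.float32))
    np.testing.assert_allclose(
        float(cross_entropy_loss(logits, one_hot(np.array([2]), 4)).data),
        math.log(4), rtol=1e-6,
    )
    # p_true = 0.5 and 0.25 -> (ln2 + ln4)/2
    logits = Tensor(np.array([[0.0, 0.0], [0.0, math.log(3)]], np.float32))
    np.testing.assert_allclose(
        float(cross_entropy_loss(logits, one_hot(np.array([0, 0]), 2)).data),
        (math.log(2) + math.log(4)) / 2, rtol=1e-5,
    )


def test_cross_entropy_rejects_non_one_hot():
    logits = Tensor(np.zeros((2, 3), np.float32))
    bad = np.array([[0.5, 0.5, 0.0], [1.0, 0.0, 0.0]], np.float32)
    with pytest.raises(ValueError, match="one-hot"):
        cross_entropy_loss(logits, bad)


# -- end-to-end differentiability ---------------------------------------------

def test_every_parameter_group_receives_gradient(rng):
    model = assemble_model(tiny_arch(), "full", seed=0)
    x = Tensor(rng.normal(size=(2, 1, 32, 32)).astype(np.float32))
    loss = cross_entropy_loss(model(x), one_hot(np.array([0, 2]), 3))
    model.zero_grad()
    loss.backward()
    groups = {}
    for name, p in model.named_parameters():
        top = name.split(".")[0]
        groups.setdefault(top, 0.0)
        if p.grad is not None:
            groups[top] += float(np.abs(p.grad).sum())
    assert set(groups) == {"llfe", "t_branch", "c_branch", "fusion", "head"}
    for top, total in groups.items():
        assert total > 0, f"no gradient reached {top}"


def test_single_adam_step_decreases_loss_on_fixed_batch(rng):
    model = assemble_model(tiny_arch(), "full", seed=1)
    x = Tensor(rng.normal(size=(4, 1, 32, 32)).astype(np.float32))
    y = one_hot(np.array([0, 1, 2, 0]), 3)
    opt = Adam(model.parameters(), lr=1e-3)
    first = cross_entropy_loss(model(x), y)
    model.zero_grad()
    first.backward()
    opt.step()
    second = cross_entropy_loss(model(x), y)
    assert float(second.data) < float(first.data)
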