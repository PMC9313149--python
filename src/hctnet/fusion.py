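"""Adaptive re-weighting feature fusion, classifier head, and the loss.

The fusion module scores each branch feature with its own linear map, stacks
the two score vectors and applies a softmax across the branch axis, giving a
per-coordinate convex weighting w_t[d] + w_c[d] = 1.  The fused feature is
the elementwise convex combination of the *original* branch features:

    fused[d] = w_t[d] * t[d] + w_c[d] * c[d]

so every coordinate lies between min(t[d], c[d]) and max(t[d], c[d]).
The classifier is a single fully connected layer producing I logits; training
minimizes the mean multi-class cross-entropy -sum_l g_l(x) log p_l(x).
"""

from __future__ import annotations

import numpy as np

from ._tensor import DTYPE, Tensor, concat, log, softmax
from .nn import Linear, Module

LOG_FLOOR = 1e-12  # probability floor inside the loss log


class FeatureFusion(Module):
    """Softmax-weighted elementwise combination of two (B, D) branch features."""

    def __init__(self, D: int, rng: np.random.Generator):
        self.D = D
        self.score_t = Linear(D, D, rng)
        self.score_c = Linear(D, D, rng)

    def weights(self, t_feat: np.ndarray, c_feat: np.ndarray) -> np.ndarray:
        """The (B, 2, D) feature aggregating matrix (softmax over branch axis)."""
        st = self.score_t(Tensor(t_feat)).reshape(-1, 1, self.D)
        sc = self.score_c(Tensor(c_feat)).reshape(-1, 1, self.D)
        return softmax(concat([st, sc], axis=1), axis=1).data

    def forward(self, t_feat: Tensor, c_feat: Tensor) -> Tensor:
        if t_feat.shape[-1] != self.D or c_feat.shape[-1] != self.D:
            raise ValueError(
                f"fusion expects dimension {self.D}; got T-branch {t_feat.shape[-1]}, "
                f"C-branch {c_feat.shape[-1]}"
            )
        b = t_feat.shape[0]
        st = self.score_t(t_feat).reshape(b, 1, self.D)
        sc = self.score_c(c_feat).reshape(b, 1, self.D)
        w = softmax(concat([st, sc], axis=1), axis=1)  # (B, 2, D)
        stacked = concat(
            [t_feat.reshape(b, 1, self.D), c_feat.reshape(b, 1, self.D)], axis=1
        )
        return (w * stacked).sum(axis=1)  # rowwise summation over the branch axis


class ClassifierHead(Module):
    """Final fully connected layer mapping the fused feature to class logits."""

    def __init__(self, D: int, n_classes: int, rng: np.random.Generator):
        self.fc = Linear(D, n_classes, rng)
        self.n_classes = n_classes

    def forward(self, fused: Tensor) -> Tensor:
        return self.fc(fused)


def predict_proba_from_logits(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def predict_label_from_logits(logits: np.ndarray) -> np.ndarray:
    """Argmax with lowest-index tie-break."""
    return logits.argmax(axis=-1)


def cross_entropy_loss(logits: Tensor, one_hot: np.ndarray) -> Tensor:
    """Mean over the batch of -sum_l g_l(x) log p_l(x).

    ``one_hot`` rows must be exactly one-hot; the log is floored at
    ``LOG_FLOOR`` so a zero predicted probability yields a large finite loss.
    """
    one_hot = np.asarray(one_hot, dtype=DTYPE)
    if one_hot.ndim != 2 or one_hot.shape != tuple(logits.shape):
        raise ValueError(f"one-hot labels shape {one_hot.shape} != logits {logits.shape}")
    rows_ok = np.all(np.isin(one_hot, (0.0, 1.0))) and np.all(one_hot.sum(axis=1) == 1.0)
    if not rows_ok:
        raise ValueError("truth rows must be one-hot (exactly one 1, rest 0)")
    p = softmax(logits, axis=-1)
    picked = (log(p, floor=LOG_FLOOR) * Tensor(one_hot)).sum(axis=1)
    return -picked.mean()


# -- functional wrappers -------------------------------------------------------

def fuse(t_feat: np.ndarray, c_feat: np.ndarray, module: FeatureFusion) -> np.ndarray:
    return module(Tensor(t_feat), Tensor(c_feat)).data


def classify(fused: np.ndarray, head: ClassifierHead):
    """Return (logits, probabilities, predicted labels) for a fused batch."""
    logits = head(Tensor(fused)).data
    return logits, predict_proba_from_logits(logits), predict_label_from_logits(logits)
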