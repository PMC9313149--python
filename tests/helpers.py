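"""Independent oracles used by the test suite (kept free of package internals)."""

import numpy as np


def brute_force_attention(z, wq, bq, wk, bk, wv, bv, wo, bo):
    """Single-head scaled dot-product attention on one (T, D) token matrix,
    written directly from the definition with plain NumPy."""
    q = z @ wq + bq
    k = z @ wk + bk
    v = z @ wv + bv
    d = z.shape[-1]
    scores = q @ k.T / np.sqrt(d)
    scores = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(scores)
    attn = e / e.sum(axis=-1, keepdims=True)
    return attn @ v @ wo + bo


def closed_form_paired_t(a, b):
    """t = mean(d) / (sd(d)/sqrt(k)) with the two-sided Student-t p-value."""
    from scipy import stats

    d = np.asarray(a, float) - np.asarray(b, float)
    k = d.size
    t = d.mean() / (d.std(ddof=1) / np.sqrt(k))
    p = 2 * stats.t.sf(abs(t), df=k - 1)
    return t, p
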