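"""Confusion-matrix metrics, macro averaging, t-tests, noise and PSNR."""

import math

import numpy as np
import pytest

from hctnet import (
    add_gaussian_noise,
    aggregate_folds,
    confusion_matrix,
    macro_mean,
    metrics_report,
    overall_metrics,
    paired_ttest,
    per_class_metrics,
    psnr,
)
from hctnet.metrics import PSNR_INF_SENTINEL

from .helpers import closed_form_paired_t


# -- confusion matrix ----------------------------------------------------------

def test_perfect_predictions_are_diagonal():
    y = np.array([0] * 5 + [1] * 3 + [2] * 2)
    cm = confusion_matrix(y, y, 3)
    np.testing.assert_array_equal(np.diag(cm.counts), [5, 3, 2])
    assert cm.counts.sum() == np.trace(cm.counts) == 10


def test_one_vs_rest_counts_enumerated_by_hand():
    """Everything predicted class 0 on a balanced 2-class set of 10."""
    y_true = np.array([0] * 5 + [1] * 5)
    y_pred = np.zeros(10, dtype=int)
    cm = confusion_matrix(y_true, y_pred, 2)
    assert cm.per_class_counts(0) == (5, 5, 0, 0)  # TP, FP, FN, TN
    assert cm.per_class_counts(1) == (0, 0, 5, 5)


def test_counts_always_sum_to_n(rng):
    y_true = rng.integers(0, 4, 100)
    y_pred = rng.integers(0, 4, 100)
    cm = confusion_matrix(y_true, y_pred, 4)
    assert cm.counts.sum() == 100
    for i in range(4):
        assert sum(cm.per_class_counts(i)) == 100


def test_out_of_range_label_is_reported_with_index():
    with pytest.raises(ValueError, match="index 2"):
        confusion_matrix([0, 1, 5], [0, 1, 2], 3)


# -- per-class / overall metrics ----------------------------------------------

def test_diagonal_matrix_scores_100_percent_everywhere():
    cm = confusion_matrix([0, 1, 2], [0, 1, 2], 3)
    acc, sens, prec = per_class_metrics(cm)
    np.testing.assert_allclose([acc, sens, prec], 100.0)


def test_two_class_metrics_by_hand_arithmetic():
    # [[8, 2], [1, 9]]
    y_true = [0] * 10 + [1] * 10
    y_pred = [0] * 8 + [1] * 2 + [0] * 1 + [1] * 9
    cm = confusion_matrix(y_true, y_pred, 2)
    _, sens, prec = per_class_metrics(cm)
    np.testing.assert_allclose(sens[0], 80.0)
    np.testing.assert_allclose(prec[0], 100.0 * 8 / 9)


def test_absent_class_yields_sentinel_but_accuracy_remains():
    cm = confusion_matrix([0, 0, 1], [0, 0, 1], 3)  # class 2 never appears
    acc, sens, prec = per_class_metrics(cm)
    assert math.isnan(sens[2]) and math.isnan(prec[2])
    np.testing.assert_allclose(acc[2], 100.0)  # all its TNs
    with pytest.warns(UserWarning, match="undefined"):
        os_ = macro_mean(sens)
    np.testing.assert_allclose(os_, 100.0)


def test_overall_metrics_agree_with_sklearn(rng):
    from sklearn.metrics import accuracy_score, precision_score, recall_score

    y_true = rng.integers(0, 4, 200)
    y_pred = rng.integers(0, 4, 200)
    cm = confusion_matrix(y_true, y_pred, 4)
    oa, os_, op = overall_metrics(cm)
    np.testing.assert_allclose(oa, 100 * accuracy_score(y_true, y_pred))
    np.testing.assert_allclose(os_, 100 * recall_score(y_true, y_pred, average="macro"))
    np.testing.assert_allclose(op, 100 * precision_score(y_true, y_pred, average="macro"))


def test_fold_aggregation_is_unweighted_mean_and_pooled_mode_differs(rng):
    reports, matrices = [], []
    for _ in range(3):
        n = int(rng.integers(20, 60))
        cm = confusion_matrix(rng.integers(0, 3, n), rng.integers(0, 3, n), 3)
        matrices.append(cm)
        reports.append(metrics_report(cm))
    mean_report = aggregate_folds(reports)
    np.testing.assert_allclose(mean_report.oa, np.mean([r.oa for r in reports]))
    pooled = aggregate_folds(reports, pooled=True, matrices=matrices)
    total = sum(m.counts for m in matrices)
    np.testing.assert_allclose(pooled.oa, 100 * np.trace(total) / total.sum())


# -- paired t-test -------------------------------------------------------------

def test_paired_ttest_matches_closed_form(rng):
    a = rng.normal(90, 2, 10)
    b = a - rng.normal(1.0, 0.5, 10)
    res = paired_ttest(a, b)
    t_ref, p_ref = closed_form_paired_t(a, b)
    assert abs(res.t - t_ref) < 1e-10
    assert abs(res.p_value - p_ref) < 1e-10


def test_identical_samples_flagged_degenerate():
    res = paired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.degenerate and math.isnan(res.t)


def test_constant_shift_with_jitter_is_highly_significant(rng):
    b = rng.normal(85, 3, 10)
    a = b + 1.0 + rng.uniform(-0.01, 0.01, 10)
    assert paired_ttest(a, b).p_value < 1e-4


def test_unequal_lengths_rejected():
    with pytest.raises(ValueError):
        paired_ttest([1.0, 2.0], [1.0, 2.0, 3.0])


# -- noise & PSNR --------------------------------------------------------------

def test_zero_sigma_is_identity_and_seed_is_deterministic(rng):
    img = rng.uniform(size=(32, 32))
    np.testing.assert_array_equal(add_gaussian_noise(img, 0.0, seed=1), img)
    a = add_gaussian_noise(img, 0.1, seed=7)
    b = add_gaussian_noise(img, 0.1, seed=7)
    np.testing.assert_array_equal(a, b)
    assert not np.array_equal(a, add_gaussian_noise(img, 0.1, seed=8))


def test_noise_standard_deviation_matches_sigma():
    img = np.full((256, 256), 0.5)
    noisy = add_gaussian_noise(img, 0.05, seed=0)
    assert abs((noisy - img).std() - 0.05) / 0.05 < 0.02


def test_negative_sigma_rejected():
    with pytest.raises(ValueError):
        add_gaussian_noise(np.zeros((8, 8)), -0.1, seed=0)


def test_psnr_closed_form_and_sentinel(rng):
    img = rng.integers(0, 240, (32, 32)).astype(np.uint8)
    assert psnr(img, img) == PSNR_INF_SENTINEL
    shifted = (img.astype(float) + 16).astype(np.uint8)
    np.testing.assert_allclose(
        psnr(img, shifted, peak=255), 10 * math.log10(255**2 / 256), atol=1e-9
    )


def test_psnr_agrees_with_skimage(rng):
    from skimage.metrics import peak_signal_noise_ratio

    a = rng.uniform(size=(64, 64))
    b = np.clip(a + rng.normal(0, 0.05, a.shape), 0, 1)
    np.testing.assert_allclose(
        psnr(a, b, peak=1.0), peak_signal_noise_ratio(a, b, data_range=1.0), rtol=1e-10
    )


def test_psnr_decreases_with_noise_level(rng):
    img = rng.uniform(size=(64, 64))
    values = [
        psnr(img, add_gaussian_noise(img, s, seed=3), peak=1.0)
        for s in (0.01, 0.03, 0.1, 0.3)
    ]
    assert all(x > y for x, y in zip(values, values[1:]))


def test_psnr_shape_mismatch_rejected():
    with pytest.raises(ValueError, match="shape"):
        psnr(np.zeros((4, 4)), np.zeros((5, 5)))
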