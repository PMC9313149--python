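"""Multi-class evaluation: confusion matrix, per-class and overall metrics,
cross-fold aggregation, paired t-tests, and the noise-robustness harness.

For class i with one-vs-rest counts TP_i, FP_i, FN_i, TN_i:

    Accuracy_i    = (TP_i + TN_i) / N
    Sensitivity_i = TP_i / (TP_i + FN_i)
    Precision_i   = TP_i / (TP_i + FP_i)

Overall accuracy (OA) is micro accuracy, trace(CM)/N; overall sensitivity
(OS) and overall precision (OP) are the unweighted (macro) means of the
per-class values.  All metrics are reported as percentages.  A class with a
zero denominator (e.g. never predicted) yields NaN for that metric and is
excluded from the macro mean with a warning, rather than silently counting
as 0 or 100.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _st

PSNR_INF_SENTINEL = math.inf


# -- confusion matrix ----------------------------------------------------------

@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (I, I), rows = true class, cols = predicted

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_test(self) -> int:
        return int(self.counts.sum())

    def per_class_counts(self, i: int) -> tuple[int, int, int, int]:
        """(TP, FP, FN, TN) of class i; the four always sum to N."""
        tp = int(self.counts[i, i])
        fp = int(self.counts[:, i].sum() - tp)
        fn = int(self.counts[i, :].sum() - tp)
        tn = self.n_test - tp - fp - fn
        return tp, fp, fn, tn


def confusion_matrix(y_true, y_pred, n_classes: int) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")
    for name, v in (("true", y_true), ("predicted", y_pred)):
        bad = np.where((v < 0) | (v >= n_classes))[0]
        if bad.size:
            raise ValueError(
                f"{name} label {v[bad[0]]} at index {bad[0]} outside [0, {n_classes})"
            )
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return ConfusionMatrix(cm)


# -- Eq.-style metrics ---------------------------------------------------------

@dataclass
class MetricsReport:
    accuracy: np.ndarray  # per-class, %
    sensitivity: np.ndarray
    precision: np.ndarray
    oa: float
    os_: float
    op: float
    class_names: list[str] | None = None

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy.tolist(),
            "sensitivity": self.sensitivity.tolist(),
            "precision": self.precision.tolist(),
            "OA": self.oa,
            "OS": self.os_,
            "OP": self.op,
        }

    def to_frame(self):
        import pandas as pd

        names = self.class_names or [str(i) for i in range(len(self.accuracy))]
        return pd.DataFrame(
            {
                "class": names,
                "accuracy_pct": self.accuracy,
                "sensitivity_pct": self.sensitivity,
                "precision_pct": self.precision,
            }
        )


def _safe_ratio(num: float, den: float) -> float:
    return 100.0 * num / den if den > 0 else math.nan


def per_class_metrics(cm: ConfusionMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-class (accuracy, sensitivity, precision) in percent; NaN sentinels."""
    n = cm.n_classes
    acc = np.empty(n)
    sens = np.empty(n)
    prec = np.empty(n)
    for i in range(n):
        tp, fp, fn, tn = cm.per_class_counts(i)
        acc[i] = _safe_ratio(tp + tn, tp + tn + fp + fn)
        sens[i] = _safe_ratio(tp, tp + fn)
        prec[i] = _safe_ratio(tp, tp + fp)
    return acc, sens, prec


def macro_mean(values) -> float:
    """Unweighted mean across classes, excluding NaN sentinels (with a warning)."""
    values = np.asarray(values, dtype=float)
    bad = np.isnan(values)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} class(es) undefined (zero denominator); "
            "excluded from the macro mean",
            stacklevel=2,
        )
    valid = values[~bad]
    return float(valid.mean()) if valid.size else math.nan


def overall_metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(OA, OS, OP) in percent: micro accuracy, macro sensitivity/precision."""
    _, sens, prec = per_class_metrics(cm)
    oa = 100.0 * float(np.trace(cm.counts)) / cm.n_test
    return oa, macro_mean(sens), macro_mean(prec)


def metrics_report(cm: ConfusionMatrix, class_names: list[str] | None = None) -> MetricsReport:
    acc, sens, prec = per_class_metrics(cm)
    oa, os_, op = overall_metrics(cm)
    return MetricsReport(acc, sens, prec, oa, os_, op, class_names)


def aggregate_folds(reports: list[MetricsReport], pooled: bool = False,
                    matrices: list[ConfusionMatrix] | None = None) -> MetricsReport:
    """Cross-validation aggregate: unweighted mean of per-repetition metrics
    (default), or metrics of the pooled confusion matrix when ``pooled``."""
    if pooled:
        if not matrices:
            raise ValueError("pooled aggregation needs the per-fold matrices")
        total = ConfusionMatrix(sum(m.counts for m in matrices))
        return metrics_report(total, reports[0].class_names if reports else None)
    return MetricsReport(
        accuracy=np.mean([r.accuracy for r in reports], axis=0),
        sensitivity=np.mean([r.sensitivity for r in reports], axis=0),
        precision=np.mean([r.precision for r in reports], axis=0),
        oa=float(np.mean([r.oa for r in reports])),
        os_=float(np.mean([r.os_ for r in reports])),
        op=float(np.mean([r.op for r in reports])),
        class_names=reports[0].class_names if reports else None,
    )


# -- paired t-test -------------------------------------------------------------

@dataclass
class PairedComparison:
    t: float
    p_value: float
    degenerate: bool = False
    differences: np.ndarray = field(default_factory=lambda: np.empty(0))


def paired_ttest(values_a, values_b) -> PairedComparison:
    """Two-sided paired t-test on per-fold metric values of two methods."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("paired t-test needs two equal-length 1-D samples, k >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        return PairedComparison(math.nan, math.nan, degenerate=True, differences=d)
    res = _st.ttest_rel(a, b)
    return PairedComparison(float(res.statistic), float(res.pvalue), differences=d)


# -- noise robustness ----------------------------------------------------------

def add_gaussian_noise(image: np.ndarray, sigma: float, seed: int,
                       peak: float | None = None) -> np.ndarray:
    """Add i.i.d. zero-mean Gaussian noise of std ``sigma`` in the original
    intensity domain, clipped to [0, peak].  Deterministic given ``seed``."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    image = np.asarray(image)
    if peak is None:
        peak = 255.0 if image.dtype == np.uint8 else 1.0
    if sigma == 0:
        return image.copy()
    rng = np.random.default_rng(seed)
    noisy = image.astype(np.float64) + rng.normal(0.0, sigma, image.shape)
    noisy = np.clip(noisy, 0.0, peak)
    return noisy.astype(np.uint8) if image.dtype == np.uint8 else noisy


def psnr(reference: np.ndarray, test: np.ndarray, peak: float | None = None) -> float:
    """10 log10(peak^2 / MSE) in dB; identical images return math.inf."""
    reference = np.asarray(reference, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if reference.shape != test.shape:
        raise ValueError(f"shape mismatch {reference.shape} vs {test.shape}")
    if peak is None:
        peak = 255.0 if np.asarray(reference).max() > 1.5 else 1.0
    mse = float(((reference - test) ** 2).mean())
    if mse == 0:
        return PSNR_INF_SENTINEL
    return 10.0 * math.log10(peak * peak / mse)


def mean_psnr_at_sigma(images: np.ndarray, sigma: float, seed: int,
                       peak: float = 1.0) -> float:
    vals = [
        psnr(img, add_gaussian_noise(img, sigma, seed + i, peak), peak)
        for i, img in enumerate(images)
    ]
    return float(np.mean(vals))


def calibrate_noise_sigma(images: np.ndarray, target_psnr: float, seed: int = 0,
                          peak: float = 1.0, tol: float = 0.05,
                          max_iter: int = 60) -> float:
    """Bisect the noise std so the mean PSNR over ``images`` hits the target.

    PSNR decreases monotonically in sigma (clipping only flattens the curve),
    so bisection on [0, peak] converges; ``tol`` is in dB.
    """
    lo, hi = 1e-6, peak
    if mean_psnr_at_sigma(images, hi, seed, peak) > target_psnr:
        raise ValueError("target PSNR unreachable: even maximal noise is too faint")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        got = mean_psnr_at_sigma(images, mid, seed, peak)
        if abs(got - target_psnr) < tol:
            return mid
        if got > target_psnr:  # too little noise
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
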