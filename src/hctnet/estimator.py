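"""scikit-learn estimator interface to HCTNet.

``HCTNetClassifier`` wraps model assembly, preprocessing and the training
loop behind the usual fit/predict/predict_proba contract, so the network
composes with sklearn model selection and pipelines.  ``X`` is a stack of
grayscale images ``(n, H, W)`` (or flattened ``(n, H*W)``); images are
resized to ``image_size`` and standardized with statistics computed on the
training data passed to ``fit``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split

from .config import ArchConfig, TrainConfig
from .fusion import predict_proba_from_logits
from .preprocess import norm_stats, preprocess_stack
from .training import predict_logits, train_arrays


class HCTNetClassifier(ClassifierMixin, BaseEstimator):
    """Hybrid ConvNet-Transformer image classifier.

    Parameters
    ----------
    image_size : side length images are resized to before entering the network.
    ablation : one of ``"full"``, ``"vit_only"``, ``"llfe_vit"``,
        ``"llfe_vit_cbranch_concat"`` — which sub-architecture to assemble.
    arch : optional explicit :class:`ArchConfig`; by default a reduced
        configuration is built for ``image_size`` <= 96 and the full-size one
        otherwise.
    epochs, batch_size, lr0, lr_step, lr_gamma, weight_decay, patience :
        optimization protocol (Adam, step-decayed learning rate, early
        stopping on validation loss).
    validation_fraction : if > 0, a stratified fraction of the training data
        is held out for early stopping.
    stop_at_train_acc : optionally halt once training accuracy reaches this
        level (capability checks).
    random_state : seed for initialization, shuffling and the validation split.
    """

    def __init__(self, image_size: int = 64, ablation: str = "full",
                 arch: ArchConfig | None = None, epochs: int = 30,
                 batch_size: int = 32, lr0: float = 3e-4, lr_step: int = 10,
                 lr_gamma: float = 0.1, weight_decay: float = 1e-4,
                 patience: int = 10, validation_fraction: float = 0.0,
                 stop_at_train_acc: float | None = None, random_state: int = 0):
        self.image_size = image_size
        self.ablation = ablation
        self.arch = arch
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr0 = lr0
        self.lr_step = lr_step
        self.lr_gamma = lr_gamma
        self.weight_decay = weight_decay
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.stop_at_train_acc = stop_at_train_acc
        self.random_state = random_state

    # -- internals ------------------------------------------------------------
    def _images(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2:  # flattened rows
            side = int(round(np.sqrt(X.shape[1])))
            if side * side != X.shape[1]:
                raise ValueError(f"cannot reshape {X.shape[1]} features to a square image")
            X = X.reshape(len(X), side, side)
        if X.ndim != 3:
            raise ValueError(f"X must be (n, H, W) or (n, H*W); got shape {X.shape}")
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite values")
        return X

    def _build_arch(self, n_classes: int) -> ArchConfig:
        if self.arch is not None:
            return self.arch
        hw = (self.image_size, self.image_size)
        if self.image_size <= 96:
            return ArchConfig.reduced(n_classes=n_classes, input_hw=hw)
        arch = ArchConfig(n_classes=n_classes, input_hw=hw)
        return arch

    # -- sklearn API ----------------------------------------------------------
    def fit(self, X, y):
        images = self._images(X)
        y = np.asarray(y)
        if len(images) != len(y):
            raise ValueError("X and y length mismatch")
        self.classes_, y_ix = np.unique(y, return_inverse=True)
        arch = self._build_arch(len(self.classes_))
        self.arch_ = arch
        size = arch.input_hw
        self.norm_mean_, self.norm_std_ = norm_stats(images)
        if self.norm_std_ <= 0:
            raise ValueError("degenerate training data: zero intensity std")
        xp = preprocess_stack(images, self.norm_mean_, self.norm_std_, size)
        x_val = y_val = None
        if self.validation_fraction > 0:
            xp, x_val, y_ix, y_val = train_test_split(
                xp, y_ix, test_size=self.validation_fraction,
                stratify=y_ix, random_state=self.random_state,
            )
        cfg = TrainConfig(
            batch_size=self.batch_size, weight_decay=self.weight_decay,
            lr0=self.lr0, lr_step=self.lr_step, lr_gamma=self.lr_gamma,
            patience=self.patience, max_epochs=self.epochs,
            seed=self.random_state, ablation_mode=self.ablation,
        )
        result = train_arrays(xp, y_ix, arch, cfg, x_val, y_val,
                              stop_at_train_acc=self.stop_at_train_acc)
        self.model_ = result.model
        self.history_ = result.log
        self.n_features_in_ = int(np.prod(np.asarray(X).shape[1:]))
        return self

    def decision_function(self, X) -> np.ndarray:
        images = self._images(X)
        xp = preprocess_stack(images, self.norm_mean_, self.norm_std_, self.arch_.input_hw)
        return predict_logits(self.model_, xp, self.batch_size)

    def predict_proba(self, X) -> np.ndarray:
        return predict_proba_from_logits(self.decision_function(X))

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.decision_function(X).argmax(axis=1)]
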