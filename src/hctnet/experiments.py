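"""Scaled-down experiment harnesses: capability and ablation checks.

These drive the full pipeline (synthetic data -> patient-level split ->
training -> evaluation) at CPU-friendly sizes, and back both the test suite
and the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ArchConfig, TrainConfig
from .preprocess import norm_stats, preprocess_stack
from .splits import make_splits
from .synth import SynthDataset, SynthSpec, generate_dataset
from .training import FitResult, predict_logits, train_arrays


def small_dataset(seed: int = 0, n_patients: int = 10, scans_per_patient: int = 5,
                  image_size: int = 64) -> SynthDataset:
    """The 200-image, 4-class synthetic dataset used by the capability checks."""
    return generate_dataset(
        SynthSpec(n_patients=n_patients, scans_per_patient=scans_per_patient,
                  image_size=image_size, seed=seed)
    )


def overfit_check(ds: SynthDataset, seed: int = 1, max_epochs: int = 30,
                  target: float = 0.95) -> FitResult:
    """Train the full reduced model on the whole dataset; verifies the network
    has the capacity/optimizability to reach ``target`` training accuracy."""
    size = ds.images.shape[1]
    arch = ArchConfig.reduced(len(ds.class_names), (size, size))
    mean, std = norm_stats(ds.images)
    x = preprocess_stack(ds.images, mean, std, (size, size))
    cfg = TrainConfig(seed=seed, max_epochs=max_epochs)
    return train_arrays(x, ds.labels, arch, cfg, stop_at_train_acc=target)


@dataclass
class AblationOutcome:
    seed: int
    val_acc: dict[str, float]  # mode -> best validation accuracy


def ablation_comparison(ds: SynthDataset, seeds: tuple[int, ...] = (0, 1, 2, 3, 4),
                        modes: tuple[str, ...] = ("full", "vit_only"),
                        max_epochs: int = 12) -> list[AblationOutcome]:
    """Train each ablation variant per seed on a patient-level split and
    record the best validation accuracy (the directional module comparison)."""
    size = ds.images.shape[1]
    arch = ArchConfig.reduced(len(ds.class_names), (size, size))
    outcomes = []
    for seed in seeds:
        plan = make_splits(ds.records, k=5, scheme="3:1:1", seed=seed)
        idx = plan.record_indices(ds.records, rep=0)
        tr, va = idx["train"], idx["val"] + idx["test"]  # small data: pool val+test
        mean, std = norm_stats(ds.images[tr])
        x_tr = preprocess_stack(ds.images[tr], mean, std, (size, size))
        x_va = preprocess_stack(ds.images[va], mean, std, (size, size))
        y_tr, y_va = ds.labels[tr], ds.labels[va]
        accs = {}
        for mode in modes:
            cfg = TrainConfig(seed=seed, max_epochs=max_epochs, ablation_mode=mode,
                              patience=max_epochs)
            res = train_arrays(x_tr, y_tr, arch, cfg, x_va, y_va)
            logits = predict_logits(res.model, x_va)
            accs[mode] = float((logits.argmax(axis=1) == y_va).mean())
        outcomes.append(AblationOutcome(seed=seed, val_acc=accs))
    return outcomes
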