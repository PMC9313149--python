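"""Training loop: Adam with step-decayed learning rate and early stopping.

``train_arrays`` is the core loop over preprocessed (n, 1, H, W) batches;
``train_records`` drives it from SampleRecords and a SplitPlan (loading,
resizing and normalizing images with training-split statistics).  Per-epoch
train/validation loss and accuracy and the learning rate actually used are
logged; the checkpoint returned is the best-validation-loss epoch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from ._tensor import Tensor
from .config import ArchConfig, TrainConfig
from .fusion import cross_entropy_loss, predict_proba_from_logits
from .model import HCTNet, assemble_model
from .nn import Adam, step_lr
from .preprocess import norm_stats, preprocess_stack, resize_image
from .splits import SampleRecord, SplitPlan


class TrainingDiverged(RuntimeError):
    def __init__(self, epoch: int, batch: int, loss: float):
        super().__init__(f"non-finite loss {loss} at epoch {epoch}, batch {batch}")
        self.epoch, self.batch = epoch, batch


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError(f"label out of range [0, {n_classes})")
    out = np.zeros((labels.size, n_classes), dtype=np.float32)
    out[np.arange(labels.size), labels] = 1.0
    return out


def predict_logits(model: HCTNet, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
    chunks = [
        model.logits(x[i : i + batch_size]) for i in range(0, len(x), batch_size)
    ]
    return np.concatenate(chunks, axis=0)


def _eval(model: HCTNet, x: np.ndarray, y: np.ndarray, batch_size: int) -> tuple[float, float]:
    logits = predict_logits(model, x, batch_size)
    p = predict_proba_from_logits(logits)
    n = len(y)
    nll = float(-np.log(np.maximum(p[np.arange(n), y], 1e-12)).mean())
    acc = float((logits.argmax(axis=1) == y).mean())
    return nll, acc


@dataclass
class FitResult:
    model: HCTNet
    log: list[dict] = field(default_factory=list)
    best_epoch: int = -1

    def write_log(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for row in self.log:
                fh.write(json.dumps(row) + "\n")


def train_arrays(x_train: np.ndarray, y_train: np.ndarray, arch: ArchConfig,
                 cfg: TrainConfig, x_val: np.ndarray | None = None,
                 y_val: np.ndarray | None = None,
                 stop_at_train_acc: float | None = None) -> FitResult:
    """Fit an HCTNet variant on preprocessed arrays.

    ``x_*`` are (n, 1, H, W) float32; ``y_*`` integer class indices.  With
    ``max_epochs=0`` the Xavier-initialized model is returned untrained with
    an empty log.  ``stop_at_train_acc`` optionally halts once the running
    training accuracy reaches the threshold (used by capability checks).
    """
    rng = np.random.default_rng(cfg.seed)
    model = assemble_model(arch, mode=cfg.ablation_mode, seed=cfg.seed)
    result = FitResult(model=model)
    if cfg.max_epochs == 0:
        return result

    opt = Adam(model.parameters(), lr=cfg.lr0, weight_decay=cfg.weight_decay)
    n = len(x_train)
    has_val = x_val is not None and len(x_val) > 0
    best_val = np.inf
    best_state = None
    stale = 0
    for epoch in range(cfg.max_epochs):
        lr = step_lr(cfg.lr0, epoch, cfg.lr_step, cfg.lr_gamma)
        opt.lr = lr
        order = rng.permutation(n)
        losses, correct = [], 0
        for b, start in enumerate(range(0, n, cfg.batch_size)):
            idx = order[start : start + cfg.batch_size]
            xb = Tensor(x_train[idx])
            logits = model(xb)
            loss = cross_entropy_loss(logits, one_hot(y_train[idx], arch.n_classes))
            if not np.isfinite(loss.data):
                raise TrainingDiverged(epoch, b, float(loss.data))
            model.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            correct += int((logits.data.argmax(axis=1) == y_train[idx]).sum())
        train_acc = correct / n
        row = {
            "epoch": epoch,
            "lr": lr,
            "train_loss": float(np.mean(losses)),
            "train_acc": train_acc,
        }
        if has_val:
            val_loss, val_acc = _eval(model, x_val, y_val, cfg.batch_size)
            row.update(val_loss=val_loss, val_acc=val_acc)
            if val_loss < best_val - 1e-6:
                best_val, stale = val_loss, 0
                best_state = model.state_dict()
                result.best_epoch = epoch
            else:
                stale += 1
        result.log.append(row)
        if stop_at_train_acc is not None and train_acc >= stop_at_train_acc:
            break
        if has_val and stale >= cfg.patience:
            break
    if best_state is not None:
        model.load_state_dict(best_state)
    return result


# -- record-level driver -------------------------------------------------------

def load_images(records: list[SampleRecord], size: tuple[int, int]) -> np.ndarray:
    """Resolve image_refs (arrays or paths) into a resized (n, H, W) stack."""
    from .data import load_image

    out = np.empty((len(records), *size), dtype=np.float64)
    for i, rec in enumerate(records):
        img = rec.image_ref if isinstance(rec.image_ref, np.ndarray) else load_image(rec.image_ref)
        out[i] = resize_image(img, size)
    return out


def train_records(records: list[SampleRecord], plan: SplitPlan, cfg: TrainConfig,
                  arch: ArchConfig, rep: int = 0, class_names: list[str] | None = None):
    """Train one cross-validation repetition from labeled records.

    Returns (FitResult, normalization stats, class-name order, test indices).
    """
    classes = class_names or sorted({r.label for r in records})
    label_ix = {c: i for i, c in enumerate(classes)}
    idx = plan.record_indices(records, rep)
    if not idx["train"] or not idx["val"]:
        raise ValueError("empty train or validation set for this repetition")
    size = arch.input_hw
    stacks = {}
    for role in ("train", "val", "test"):
        recs = [records[i] for i in idx[role]]
        stacks[role] = (
            load_images(recs, size),
            np.array([label_ix[r.label] for r in recs], dtype=int),
        )
    mean, std = norm_stats(stacks["train"][0])
    if std <= 0:
        raise ValueError("degenerate training split: zero intensity std")

    def prep(stack):
        return preprocess_stack(stack, mean, std, size)

    result = train_arrays(
        prep(stacks["train"][0]), stacks["train"][1], arch, cfg,
        prep(stacks["val"][0]), stacks["val"][1],
    )
    return result, (mean, std), classes, idx["test"]


# -- checkpointing -------------------------------------------------------------

def save_checkpoint(path: str | Path, model: HCTNet, arch: ArchConfig,
                    stats: tuple[float, float], classes: list[str]) -> None:
    """Write weights (npz + JSON shape manifest) and a YAML metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    model.save(path)
    meta = {
        "mode": model.mode,
        "classes": list(classes),
        "norm_mean": float(stats[0]),
        "norm_std": float(stats[1]),
        "arch": yaml.safe_load(yaml.safe_dump(_arch_dict(arch))),
    }
    Path(str(path) + ".meta.yaml").write_text(yaml.safe_dump(meta))


def load_checkpoint(path: str | Path):
    from dataclasses import asdict  # noqa: F401

    path = Path(path)
    meta = yaml.safe_load(Path(str(path) + ".meta.yaml").read_text())
    arch = ArchConfig.from_dict(meta["arch"])
    model = assemble_model(arch, mode=meta["mode"], seed=0)
    model.load(path)
    return model, arch, (meta["norm_mean"], meta["norm_std"]), meta["classes"]


def _arch_dict(arch: ArchConfig) -> dict:
    from dataclasses import asdict

    d = asdict(arch)
    d["input_hw"] = list(arch.input_hw)
    return d
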