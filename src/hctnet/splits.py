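"""Patient-level k-fold splitting.

Every B-scan belongs to a patient, and scans of one patient are strongly
correlated; splitting at the image level would leak patient identity across
train and test.  Patients are therefore shuffled (deterministically, from the
seed) and dealt into k near-equal folds, and fold roles rotate across the k
repetitions.  Two role schemes are supported:

- ``"3:1:1"`` — k-2 folds train, one validates, one tests (the small-dataset
  protocol, used with k=5);
- ``"one-train"`` — one fold trains and the remainder is split 1 : (k-2)
  between validation and test by fold index (the large-dataset protocol,
  used with k=10).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

SCHEMES = ("3:1:1", "one-train")


@dataclass
class SampleRecord:
    """One labeled B-scan: the unit of evaluation; the patient is the unit of splitting."""

    image_ref: object  # path or in-memory array
    patient_id: str
    label: str
    source_resolution: tuple[int, int] | None = None


@dataclass
class SplitPlan:
    k: int
    scheme: str
    fold_of_patient: dict[str, int]
    repetitions: list[dict[str, set[int]]] = field(default_factory=list)

    def patient_roles(self, rep: int) -> dict[str, set[str]]:
        roles = self.repetitions[rep]
        out: dict[str, set[str]] = {}
        for role, folds in roles.items():
            out[role] = {p for p, f in self.fold_of_patient.items() if f in folds}
        return out

    def record_indices(self, records: Sequence[SampleRecord], rep: int) -> dict[str, list[int]]:
        """Indices of ``records`` assigned to train/val/test in repetition ``rep``."""
        roles = self.patient_roles(rep)
        out = {role: [] for role in roles}
        for i, rec in enumerate(records):
            for role, patients in roles.items():
                if rec.patient_id in patients:
                    out[role].append(i)
        return out

    def check_disjoint(self) -> None:
        for rep in range(len(self.repetitions)):
            roles = self.patient_roles(rep)
            names = list(roles)
            for i, a in enumerate(names):
                for b in names[i + 1 :]:
                    overlap = roles[a] & roles[b]
                    if overlap:
                        raise AssertionError(
                            f"repetition {rep}: {a}/{b} share patients {sorted(overlap)[:5]}"
                        )


def make_splits(records: Sequence[SampleRecord], k: int, scheme: str = "3:1:1",
                seed: int = 0) -> SplitPlan:
    """Deal patients into k folds and rotate train/val/test roles k times."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; valid: {SCHEMES}")
    patients = sorted({r.patient_id for r in records})
    if len(patients) < k:
        raise ValueError(f"{len(patients)} distinct patients < k={k}")
    if scheme == "3:1:1" and k < 3:
        raise ValueError("3:1:1 scheme needs k >= 3 (train folds = k-2)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    fold_of_patient = {patients[j]: int(i % k) for i, j in enumerate(order)}

    reps: list[dict[str, set[int]]] = []
    all_folds = set(range(k))
    for r in range(k):
        test = {r}
        val = {(r + 1) % k}
        if scheme == "3:1:1":
            train = all_folds - test - val
        else:  # one-train: fold r trains, next fold validates, the rest test
            train = {r}
            test = all_folds - train - val
        reps.append({"train": train, "val": val, "test": test})
    plan = SplitPlan(k=k, scheme=scheme, fold_of_patient=fold_of_patient, repetitions=reps)
    plan.check_disjoint()
    return plan
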