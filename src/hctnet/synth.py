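"""Synthetic retinal-OCT-like B-scan generator.

Emulates the structure of patient-grouped OCT classification datasets so
that splitting, training, evaluation and the noise harness are exercisable
without downloads: each image is a stack of 4-8 smooth bright horizontal
bands (retinal layers) over a dark background with multiplicative
Rayleigh-like speckle, and class-conditional lesions:

- NORMAL: bands only;
- DRUSEN / AMD: small dome-shaped bumps sitting on one of the lower bands
  (subretinal deposits);
- DME: dark elliptical hypo-reflective pockets inside the band region
  (intraretinal fluid);
- CNV: a bright irregular blob beneath the bands with local band disruption
  (neovascular lesion).

Per-patient geometry (layer count, curvature, tilt, band depths) is shared
across that patient's scans, making the patient - not the scan - the unit
whose leakage across splits would inflate scores.  Everything is
deterministic in the spec's seed.  Ground-truth lesion and band masks are
returned so tests can audit the generator against its own geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .splits import SampleRecord

CLASS_SETS = {
    "oct2017": ("CNV", "DME", "DRUSEN", "NORMAL"),
    "srinivasan": ("AMD", "DME", "NORMAL"),
}


@dataclass
class SynthSpec:
    n_patients: int = 15  # per class
    scans_per_patient: int = 20
    image_size: int = 224
    class_set: str = "oct2017"
    layer_count_range: tuple[int, int] = (4, 8)
    thickness_range: tuple[float, float] = (0.018, 0.04)  # fraction of height
    lesion_contrast: float = 0.35
    lesions_per_scan: tuple[int, int] = (1, 3)
    speckle_strength: float = 0.25
    seed: int = 0

    @property
    def classes(self) -> tuple[str, ...]:
        return CLASS_SETS[self.class_set]

    def validate(self) -> None:
        if self.class_set not in CLASS_SETS:
            raise ValueError(f"class_set must be one of {sorted(CLASS_SETS)}")
        if self.image_size < 32:
            raise ValueError("image_size too small for the configured lesion radii")


@dataclass
class SynthDataset:
    images: np.ndarray  # (n, S, S) float64 in [0, 1]
    labels: np.ndarray  # (n,) int
    class_names: tuple[str, ...]
    patient_ids: list[str]
    lesion_masks: np.ndarray  # (n, S, S) bool
    band_masks: np.ndarray
    records: list[SampleRecord] = field(default_factory=list)


@dataclass
class _PatientGeometry:
    n_layers: int
    centers: np.ndarray  # fractional row of each band
    thickness: np.ndarray
    brightness: np.ndarray
    curvature: float
    tilt: float


def _patient_geometry(rng: np.random.Generator, spec: SynthSpec) -> _PatientGeometry:
    lo, hi = spec.layer_count_range
    n_layers = int(rng.integers(lo, hi + 1))
    centers = np.linspace(0.28, 0.72, n_layers)
    centers = centers + rng.normal(0, 0.012, n_layers)
    return _PatientGeometry(
        n_layers=n_layers,
        centers=centers,
        thickness=rng.uniform(*spec.thickness_range, n_layers),
        brightness=rng.uniform(0.45, 0.85, n_layers),
        curvature=float(rng.uniform(-0.12, 0.12)),
        tilt=float(rng.uniform(-0.08, 0.08)),
    )


def _render_bands(geom: _PatientGeometry, s: int, jitter: float):
    x = (np.arange(s) + 0.5) / s
    offset = geom.curvature * 4.0 * (x - 0.5) ** 2 + geom.tilt * (x - 0.5) + jitter
    rows = np.arange(s)[:, None]
    img = np.full((s, s), 0.08)
    band_mask = np.zeros((s, s), dtype=bool)
    center_rows = []
    for c, th, br in zip(geom.centers, geom.thickness, geom.brightness):
        r = (c + offset) * s  # (s,) fractional center row per column
        half = max(th * s / 2.0, 1.0)
        dist = (rows - r[None, :]) / half
        profile = br * np.exp(-dist * dist)
        img = np.maximum(img, profile)
        band_mask |= np.abs(dist) < 1.0
        center_rows.append(r)
    return img, band_mask, np.array(center_rows), offset


def _ellipse_mask(s: int, cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    rows = np.arange(s)[:, None]
    cols = np.arange(s)[None, :]
    return ((rows - cy) / ry) ** 2 + ((cols - cx) / rx) ** 2 < 1.0


def _add_lesions(img, band_mask, center_rows, label: str, rng, spec: SynthSpec):
    s = img.shape[0]
    contrast = spec.lesion_contrast
    lesion = np.zeros((s, s), dtype=bool)
    if label == "NORMAL" or contrast == 0.0:
        return img, lesion
    n_lesions = int(rng.integers(spec.lesions_per_scan[0], spec.lesions_per_scan[1] + 1))
    scale = 0.55 + 0.9 * contrast  # stronger lesions are also larger
    for _ in range(n_lesions):
        cx = float(rng.uniform(0.15 * s, 0.85 * s))
        if label in ("DRUSEN", "AMD"):
            # dome-shaped bump deforming one of the lower bands
            layer = int(rng.integers(max(1, len(center_rows) // 2), len(center_rows)))
            cy = float(np.interp(cx, np.arange(s), center_rows[layer]))
            rx = float(rng.uniform(0.035, 0.07) * s * scale)
            ry = float(rng.uniform(0.5, 0.9) * rx)
            mask = _ellipse_mask(s, cy, cx, ry, rx)
            mask &= np.arange(s)[:, None] <= cy  # upper half: a dome on the band
            img[mask] = np.maximum(img[mask], 0.45 + 0.9 * contrast)
        elif label == "DME":
            # dark fluid pocket inside the band region
            cy = float(rng.uniform(0.34 * s, 0.66 * s))
            rx = float(rng.uniform(0.05, 0.11) * s * scale)
            ry = float(rng.uniform(0.4, 0.8) * rx)
            mask = _ellipse_mask(s, cy, cx, ry, rx)
            img[mask] *= 1.0 - 0.9 * contrast
        else:  # CNV: bright irregular blob beneath the bands + band disruption
            cy = float(rng.uniform(0.74 * s, 0.86 * s))
            base_r = float(rng.uniform(0.06, 0.12) * s * scale)
            rows = np.arange(s)[:, None] - cy
            cols = np.arange(s)[None, :] - cx
            angle = np.arctan2(rows, cols)
            wobble = 1.0 + 0.35 * np.sin(3 * angle + rng.uniform(0, 2 * math.pi))
            mask = rows**2 + cols**2 < (base_r * wobble) ** 2
            img[mask] = np.minimum(img[mask] + (0.35 + 0.8 * contrast), 1.0)
            # disrupt the band directly above the blob
            col_lo, col_hi = int(max(cx - base_r, 0)), int(min(cx + base_r, s))
            strip = band_mask[:, col_lo:col_hi]
            img[:, col_lo:col_hi][strip] *= rng.uniform(0.55, 1.1, size=int(strip.sum()))
        lesion |= mask
    return img, lesion


def generate_dataset(spec: SynthSpec) -> SynthDataset:
    """Render the full labeled, patient-grouped dataset described by ``spec``."""
    spec.validate()
    classes = spec.classes
    s = spec.image_size
    n_total = len(classes) * spec.n_patients * spec.scans_per_patient
    images = np.empty((n_total, s, s))
    lesions = np.zeros((n_total, s, s), dtype=bool)
    bands = np.zeros((n_total, s, s), dtype=bool)
    labels = np.empty(n_total, dtype=int)
    patient_ids: list[str] = []
    records: list[SampleRecord] = []
    i = 0
    for ci, label in enumerate(classes):
        for p in range(spec.n_patients):
            pid = f"{label}-{p:03d}"
            geom = _patient_geometry(np.random.default_rng([spec.seed, ci, p]), spec)
            for sc in range(spec.scans_per_patient):
                rng = np.random.default_rng([spec.seed, ci, p, sc])
                jitter = float(rng.normal(0, 0.008))
                img, band_mask, center_rows, _ = _render_bands(geom, s, jitter)
                img, lesion = _add_lesions(img, band_mask, center_rows, label, rng, spec)
                if spec.speckle_strength > 0:
                    ray = rng.rayleigh(scale=1.0, size=(s, s)) / math.sqrt(math.pi / 2.0)
                    img = img * (1.0 + spec.speckle_strength * (ray - 1.0))
                img = np.clip(img, 0.0, 1.0)
                images[i] = img
                lesions[i] = lesion
                bands[i] = band_mask
                labels[i] = ci
                patient_ids.append(pid)
                records.append(
                    SampleRecord(image_ref=img, patient_id=pid, label=label,
                                 source_resolution=(s, s))
                )
                i += 1
    return SynthDataset(images, labels, classes, patient_ids, lesions, bands, records)


def class_separability_audit(ds: SynthDataset, grid: int = 8) -> float:
    """Accuracy of a nearest-centroid baseline on ``grid x grid`` block means.

    Certifies that the generated task is learnable (above chance) without
    being degenerate (below perfect) at the configured lesion contrast.
    The split is patient-disjoint (first half of each class's patients fit
    the centroids, the rest score them) — an image-level split would leak
    shared per-patient geometry and inflate the baseline.
    """
    images, labels = ds.images, ds.labels
    n_classes = len(ds.class_names)
    n, s, _ = images.shape
    if s % grid:
        raise ValueError(f"image size {s} not divisible by audit grid {grid}")
    if np.bincount(labels, minlength=n_classes).min() < 20:
        raise ValueError("audit needs at least 20 images per class")
    block = s // grid
    feats = images.reshape(n, grid, block, grid, block).mean(axis=(2, 4)).reshape(n, -1)
    pids = np.asarray(ds.patient_ids)
    train = np.zeros(n, dtype=bool)
    for c in range(n_classes):
        cls_patients = sorted(set(pids[labels == c]))
        keep = set(cls_patients[: len(cls_patients) // 2])
        train |= (labels == c) & np.isin(pids, list(keep))
    test = ~train
    centroids = np.stack([feats[train][labels[train] == c].mean(axis=0)
                          for c in range(n_classes)])
    d = ((feats[test][:, None, :] - centroids[None]) ** 2).sum(axis=2)
    pred = d.argmin(axis=1)
    return float((pred == labels[test]).mean())


def save_dataset(ds: SynthDataset, out_dir: str | Path) -> Path:
    """Write the PNG tree (class-per-folder) and manifest.csv; returns manifest path."""
    from .data import save_image, write_manifest

    out_dir = Path(out_dir)
    rows = []
    counter: dict[str, int] = {}
    for img, label_ix, pid in zip(ds.images, ds.labels, ds.patient_ids):
        label = ds.class_names[label_ix]
        k = counter.get(pid, 0)
        counter[pid] = k + 1
        rel = Path(label) / f"{pid}-{k:03d}.png"
        save_image(out_dir / rel, img)
        rows.append(SampleRecord(image_ref=str(rel), patient_id=pid, label=label))
    return write_manifest(rows, out_dir / "manifest.csv")
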