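"""Dataset IO: grayscale PNG/JPEG loading, manifest CSV, directory discovery.

The manifest convention is a CSV with columns ``image_path,patient_id,label``
(paths relative to the manifest's directory).  Directory-tree discovery
handles the common class-per-folder layout, extracting the patient from the
filename with a configurable regex (default matches names like
``CNV-81630-1.jpeg`` where the middle token is the patient).
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .splits import SampleRecord

DEFAULT_PATIENT_REGEX = r"^[A-Za-z]+-?(\d+)"


def load_image(path: str | Path) -> np.ndarray:
    """Load an image as grayscale float64 in [0, 1]."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"), dtype=np.float64)
    return arr / 255.0


def save_image(path: str | Path, image: np.ndarray) -> None:
    """Serialize a float [0,1] (or uint8) grayscale array as 8-bit PNG."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if image.dtype != np.uint8:
        image = np.clip(np.round(image * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(image, mode="L").save(path)


def write_manifest(records: Sequence[SampleRecord], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "image_path": [str(r.image_ref) for r in records],
            "patient_id": [r.patient_id for r in records],
            "label": [r.label for r in records],
        }
    ).to_csv(path, index=False)
    return path


def load_manifest(path: str | Path) -> list[SampleRecord]:
    path = Path(path)
    df = pd.read_csv(path)
    required = {"image_path", "patient_id", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    root = path.parent
    return [
        SampleRecord(
            image_ref=str(root / row.image_path),
            patient_id=str(row.patient_id),
            label=str(row.label),
        )
        for row in df.itertuples()
    ]


def discover_tree(root: str | Path,
                  patient_regex: str = DEFAULT_PATIENT_REGEX) -> list[SampleRecord]:
    """Build records from a class-per-folder image tree."""
    root = Path(root)
    pattern = re.compile(patient_regex)
    records = []
    for class_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        for img in sorted(class_dir.glob("*")):
            if img.suffix.lower() not in {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}:
                continue
            m = pattern.match(img.stem)
            pid = m.group(1) if m else img.stem
            records.append(
                SampleRecord(image_ref=str(img), patient_id=f"{class_dir.name}-{pid}",
                             label=class_dir.name)
            )
    if not records:
        raise ValueError(f"no images discovered under {root}")
    return records
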