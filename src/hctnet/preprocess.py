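"""Image preprocessing: resize to the network input size and standardize.

Resizing is bilinear with anti-aliasing (values change with the
interpolation choice, so it is fixed and documented here).  Normalization
statistics are computed on the training split only and frozen for
validation and test, to avoid information leakage.
"""

from __future__ import annotations

import numpy as np
from PIL import Image


def resize_image(image: np.ndarray, size: tuple[int, int] = (224, 224)) -> np.ndarray:
    """Bilinear resize of a single grayscale image (anti-aliased when
    downsampling), sampling at half-pixel centers with edge clamping."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {img.shape}")
    if img.shape[0] < 8 or img.shape[1] < 8:
        raise ValueError(f"image {img.shape} smaller than the 8x8 minimum")
    if img.shape == tuple(size):
        return img
    # PIL size is (width, height)
    out = Image.fromarray(img.astype(np.float32), mode="F").resize(
        (size[1], size[0]), Image.Resampling.BILINEAR
    )
    return np.asarray(out, dtype=np.float64)


def norm_stats(images: np.ndarray) -> tuple[float, float]:
    """Mean/std over a (n, H, W) training stack (frozen for val/test)."""
    images = np.asarray(images, dtype=np.float64)
    return float(images.mean()), float(images.std())


def preprocess(image: np.ndarray, mean: float, std: float,
               size: tuple[int, int] = (224, 224)) -> np.ndarray:
    """Resize then apply (x - mean) / std; returns a (1, 1, H, W) float32 array."""
    if std <= 0:
        raise ValueError(
            "zero/negative normalization std — the split statistics are degenerate "
            "(constant images?)"
        )
    out = (resize_image(image, size) - mean) / std
    return out[None, None].astype(np.float32)


def preprocess_stack(images: np.ndarray, mean: float, std: float,
                     size: tuple[int, int]) -> np.ndarray:
    """Vectorized preprocess for a (n, H, W) stack -> (n, 1, h, w) float32."""
    return np.concatenate([preprocess(im, mean, std, size) for im in images], axis=0)
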