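"""Per-pixel kymogram features: red intensity, green intensity, gradient.

The glottal gap appears darker than the surrounding tissue in a kymogram, so
raw red and green channel intensities are two of the three features.  The
blue channel is never read: on color high-speed sensors it is dominated by
noise.  Intensity alone cannot separate the glottis from other dark pixels,
so the third feature is an image gradient computed on the red/green mean
with a configurable pixel step along both axes (default 8), which responds
to the strong contrast at the glottal edges.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "intensity_features",
    "gradient_components",
    "gradient_feature",
    "build_feature_matrix",
]

#: Column order of the feature matrix, fixed across poolings.
FEATURE_COLUMNS = ("red", "green", "gradient")


def _check_kymogram(kym: np.ndarray) -> np.ndarray:
    kym = np.asarray(kym)
    if kym.ndim != 3 or kym.shape[2] < 3:
        have = kym.shape[2] if kym.ndim == 3 else 1
        missing = [name for i, name in enumerate(("red", "green", "blue")) if i >= have]
        raise ValueError(
            f"kymogram must have 3 channels (missing: {', '.join(missing)})"
        )
    if kym.shape[1] < 2:
        raise ValueError("kymogram needs at least 2 time columns")
    return kym


def intensity_features(kym: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Red and green channel intensity maps (float64, kymogram shape).

    The blue channel is excluded from all feature computation.
    """
    kym = _check_kymogram(kym)
    red = kym[:, :, 0].astype(np.float64)
    green = kym[:, :, 1].astype(np.float64)
    return red, green


def gradient_components(
    kym: np.ndarray, step: int = 8
) -> tuple[np.ndarray, np.ndarray]:
    """Signed gradients of the red/green mean image at a pixel step.

    For the mean image ``I = (red + green) / 2`` the components at pixel
    ``(r, c)`` are central differences at distance ``step`` with edge
    replication::

        gx(r, c) = I(r, c + step) - I(r, c - step)
        gy(r, c) = I(r + step, c) - I(r - step, c)

    Both positive and negative gradients are preserved in the signed maps.
    """
    kym = _check_kymogram(kym)
    if step <= 0:
        raise ValueError("step must be positive")
    h, w = kym.shape[:2]
    if h <= step or w <= step:
        raise ValueError(f"kymogram {h}x{w} smaller than gradient step {step}")
    red, green = intensity_features(kym)
    img = 0.5 * (red + green)
    rows = np.arange(h)
    cols = np.arange(w)
    up = np.clip(rows - step, 0, h - 1)
    down = np.clip(rows + step, 0, h - 1)
    left = np.clip(cols - step, 0, w - 1)
    right = np.clip(cols + step, 0, w - 1)
    gx = img[:, right] - img[:, left]
    gy = img[down, :] - img[up, :]
    return gx, gy


def gradient_feature(kym: np.ndarray, step: int = 8) -> np.ndarray:
    """Gradient magnitude map ``sqrt(gx**2 + gy**2)`` of the red/green mean."""
    gx, gy = gradient_components(kym, step)
    return np.hypot(gx, gy)


def build_feature_matrix(
    kym: np.ndarray, pooling: str = "per_pixel", step: int = 8
) -> pd.DataFrame:
    """Assemble the (red, green, gradient) feature matrix from a kymogram.

    ``pooling="per_pixel"`` yields one row per pixel in row-major order
    (space-major, then time); ``pooling="per_column"`` averages each feature
    over the spatial rows, one row per time column.  Columns are always
    ``red, green, gradient`` in that order.
    """
    kym = _check_kymogram(kym)
    red, green = intensity_features(kym)
    grad = gradient_feature(kym, step)
    if pooling == "per_pixel":
        data = {
            "red": red.ravel(),
            "green": green.ravel(),
            "gradient": grad.ravel(),
        }
    elif pooling == "per_column":
        data = {
            "red": red.mean(axis=0),
            "green": green.mean(axis=0),
            "gradient": grad.mean(axis=0),
        }
    else:
        raise ValueError(f"unknown pooling {pooling!r}; use 'per_pixel' or 'per_column'")
    return pd.DataFrame(data, columns=list(FEATURE_COLUMNS))
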