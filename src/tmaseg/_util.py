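"""Shared numeric helpers and validation."""

from __future__ import annotations

import numpy as np

#: tissue-class codes used throughout the package (label code 1 is deliberately
#: unused; the three-code scheme {0 background, 2 tumor, 3 non-tumor} is the
#: convention of the annotated TMA data this package models).
LABEL_CODES = (0, 2, 3)

#: code -> RGB color for colorized label images (white / red / green).
CLASS_COLORS = {0: (255, 255, 255), 2: (255, 0, 0), 3: (0, 255, 0)}
COLOR_CLASSES = {v: k for k, v in CLASS_COLORS.items()}


def round_half_up(x):
    """Round to nearest integer with ties going away from zero-half upward.

    numpy's ``round`` uses banker's rounding; every rounding step in this
    package uses half-up instead, so it is defined once here.
    """
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(np.int64)


def as_rgb_image(pixels) -> np.ndarray:
    """Validate and coerce an array to an H×W×3 uint8 RGB image."""
    arr = np.asarray(pixels)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an H×W×3 RGB array, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError("empty image")
    if np.issubdtype(arr.dtype, np.floating):
        if np.nanmin(arr) < 0 or np.nanmax(arr) > 255:
            raise ValueError("intensities outside [0, 255]")
        arr = round_half_up(arr)
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("intensities outside [0, 255]")
    return arr.astype(np.uint8)


def as_label_image(labels) -> np.ndarray:
    """Validate an array as an H×W label raster over the codes {0, 2, 3}."""
    arr = np.asarray(labels)
    if arr.ndim != 2:
        raise ValueError(f"expected an H×W label raster, got shape {arr.shape}")
    bad = np.setdiff1d(np.unique(arr), LABEL_CODES)
    if bad.size:
        raise ValueError(f"label image contains codes outside {LABEL_CODES}: {bad.tolist()}")
    return arr.astype(np.uint8)


def check_same_shape(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape[:2] != b.shape[:2]:
        raise ValueError(f"dimension mismatch: {a.shape[:2]} vs {b.shape[:2]}")
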