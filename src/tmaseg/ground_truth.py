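"""Ground-truth construction and superpixel class assignment.

A label image assigns each pixel one of three codes: 0 background (white),
2 tumor (red), 3 non-tumor (green). Expert markings arrive as polygon ROIs
over the tumor area only; the rest of the label image is derived from the
image itself: light-gray low-chroma pixels are background, remaining tissue
is non-tumor. Superpixels receive a class by majority vote of their member
pixels.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw
from skimage.filters import threshold_otsu

from ._util import as_label_image, as_rgb_image, check_same_shape
from .dataio import RoiPolygon

log = logging.getLogger(__name__)

#: channel spread (max − min) below which a bright pixel counts as
#: achromatic light-gray background
BACKGROUND_CHROMA_SPREAD = 20

#: class priority used to break majority-vote ties: tumor first, biasing the
#: assignment toward sensitivity in a diagnostic-support setting
TIE_PRIORITY = (2, 3, 0)


def polygon_mask(shape: tuple[int, int], polygons: list[RoiPolygon]) -> np.ndarray:
    """Boolean mask of pixels inside (or on the boundary of) any polygon."""
    img = Image.new("1", (shape[1], shape[0]), 0)
    draw = ImageDraw.Draw(img)
    for poly in polygons:
        draw.polygon([tuple(map(int, v)) for v in poly.vertices], fill=1, outline=1)
    return np.asarray(img, dtype=bool)


def rasterize_labels(image, tumor_rois: list[RoiPolygon]) -> np.ndarray:
    """Build a three-code label image from an RGB image and tumor polygons.

    Background is detected from the image: pixels brighter than the Otsu
    threshold of the grayscale mean AND with channel spread < 20 (light
    gray). Tumor is any non-background pixel inside a polygon; everything
    else is non-tumor. Background takes precedence over the polygons.
    """
    image = as_rgb_image(image)
    gray = image.astype(float).mean(axis=-1)
    thr = threshold_otsu(gray)
    spread = image.max(axis=-1).astype(int) - image.min(axis=-1).astype(int)
    background = (gray > thr) & (spread < BACKGROUND_CHROMA_SPREAD)
    log.debug("rasterize_labels: otsu threshold %.2f, background fraction %.3f",
              thr, background.mean())
    labels = np.full(image.shape[:2], 3, dtype=np.uint8)
    if tumor_rois:
        tumor = polygon_mask(image.shape[:2], tumor_rois)
        labels[tumor] = 2
    labels[background] = 0
    return labels


def assign_classes(assignment, labels, tie_priority: tuple[int, ...] = TIE_PRIORITY
                   ) -> pd.DataFrame:
    """Majority-vote class per superpixel, with per-class vote fractions.

    Ties are broken by ``tie_priority`` (default tumor > non-tumor >
    background). Returns a DataFrame with columns superpixel_id, class and
    frac_0 / frac_2 / frac_3 summing to 1 per row.
    """
    assignment = np.asarray(assignment)
    labels = as_label_image(labels)
    check_same_shape(assignment, labels)
    k = int(assignment.max()) + 1
    counts = np.zeros((k, 4), dtype=np.int64)  # columns indexed by code 0..3
    flat = assignment.ravel()
    for code in (0, 2, 3):
        counts[:, code] = np.bincount(flat[labels.ravel() == code], minlength=k)
    totals = counts.sum(axis=1)
    # argmax in tie-priority order: scan priority list, keep the first code
    # achieving the maximum count
    best = np.full(k, -1, dtype=np.int64)
    best_count = np.full(k, -1, dtype=np.int64)
    for code in tie_priority:
        better = counts[:, code] > best_count
        best[better] = code
        best_count[better] = counts[better, code]
    frame = {"superpixel_id": np.arange(k), "class": best}
    for code in (0, 2, 3):
        frame[f"frac_{code}"] = counts[:, code] / totals
    return pd.DataFrame(frame)


def quantized_label_image(assignment, labels) -> np.ndarray:
    """Replace every pixel by its superpixel's majority class.

    This is the superpixel-resolution ground truth the evaluation scores
    against; quantizing an already-quantized raster with the same map is the
    identity.
    """
    assignment = np.asarray(assignment)
    votes = assign_classes(assignment, labels)
    lut = votes["class"].to_numpy().astype(np.uint8)
    return lut[assignment]
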