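"""Reassembly of classified superpixels into segmented label images."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._util import CLASS_COLORS, LABEL_CODES, as_label_image, as_rgb_image, check_same_shape
from .learning import MetricsReport, compute_metrics


def reconstruct(assignment, classes) -> np.ndarray:
    """Paint every pixel with its superpixel's class.

    ``classes`` is a table with columns superpixel_id and class (the output
    of :func:`tmaseg.ground_truth.assign_classes` or a model's predictions);
    every id present in the map must have a class.
    """
    assignment = np.asarray(assignment)
    if isinstance(classes, pd.DataFrame):
        mapping = dict(zip(classes["superpixel_id"].astype(int), classes["class"].astype(int)))
    else:
        mapping = {int(k): int(v) for k, v in classes}
    k = int(assignment.max()) + 1
    lut = np.full(k, -1, dtype=np.int64)
    for sp, cls in mapping.items():
        if 0 <= sp < k:
            lut[sp] = cls
    missing = np.nonzero(lut < 0)[0]
    if missing.size:
        raise ValueError(f"no class for superpixel id(s) {missing.tolist()[:10]}")
    return as_label_image(lut[assignment])


def colorize(labels) -> np.ndarray:
    """Color a label image: background white, tumor red, non-tumor green."""
    labels = np.asarray(labels)
    bad = np.setdiff1d(np.unique(labels), LABEL_CODES)
    if bad.size:
        raise ValueError(f"label image contains invalid codes {bad.tolist()}")
    out = np.zeros((*labels.shape, 3), dtype=np.uint8)
    for code, color in CLASS_COLORS.items():
        out[labels == code] = color
    return out


def pixel_score(predicted, truth) -> MetricsReport:
    """Pixel-level multiclass metrics of a segmentation against ground truth."""
    predicted = as_label_image(predicted)
    truth = as_label_image(truth)
    check_same_shape(predicted, truth)
    _, report = compute_metrics(truth.ravel(), predicted.ravel())
    return report
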