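"""Per-superpixel texture descriptors.

Each superpixel is described by 69 features: 23 per RGB channel, namely 17
first-order histogram statistics and the 6 Tamura perceptual texture features
(coarseness, contrast, directionality, line-likeness, regularity, roughness).
First-order statistics depend only on the multiset of member intensities;
Tamura features are spatial and are computed on the superpixel's bounding-box
crop with non-member pixels filled by the member mean, so that neighboring
superpixels cannot leak texture into the descriptor.

The feature-name registry below is frozen: tables produced by different runs
are column-compatible by construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from ._util import as_rgb_image, check_same_shape
from .dataio import CLASS_COLUMN, KEY_COLUMNS

FIRST_ORDER_NAMES = [
    "mean", "variance", "std", "skewness", "kurtosis", "energy", "rms",
    "entropy", "min", "max", "median", "range", "mad", "p25", "p75", "iqr", "cv",
]
TAMURA_NAMES = [
    "coarseness", "contrast", "directionality", "linelikeness", "regularity", "roughness",
]
CHANNELS = ("R", "G", "B")

#: co-occurrence displacement (pixels) for the line-likeness feature
LINELIKENESS_DISTANCE = 4
_N_ORIENT_BINS = 16


def feature_names(tamura: tuple[str, ...] | list[str] | None = None) -> list[str]:
    """The frozen, ordered 69-name registry: R features, then G, then B."""
    tam = list(tamura) if tamura is not None else TAMURA_NAMES
    return [f"{ch}_{name}" for ch in CHANNELS for name in FIRST_ORDER_NAMES + tam]


def split_channels(image) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Decompose an RGB image into its three single-channel rasters."""
    image = as_rgb_image(image)
    return image[..., 0], image[..., 1], image[..., 2]


def first_order_stats(values) -> np.ndarray:
    """The 17 first-order statistics of an intensity multiset, in registry order.

    Variance and higher moments are population moments; entropy is Shannon
    entropy in bits over 256 intensity bins; skewness and excess kurtosis are
    defined as 0 for a constant region; cv = std/mean with 0 when mean = 0.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("first_order_stats requires at least one pixel")
    mean = v.mean()
    var = v.var()
    std = np.sqrt(var)
    centered = v - mean
    if var > 0:
        skew = np.mean(centered ** 3) / std ** 3
        kurt = np.mean(centered ** 4) / var ** 2 - 3.0
    else:
        skew = kurt = 0.0
    energy = np.mean(v ** 2)
    rms = np.sqrt(energy)
    hist = np.bincount(np.clip(v, 0, 255).astype(np.intp), minlength=256)
    p = hist[hist > 0] / v.size
    entropy = float(-(p * np.log2(p)).sum())
    vmin, vmax = v.min(), v.max()
    median = np.median(v)
    mad = np.mean(np.abs(centered))
    p25, p75 = np.percentile(v, [25, 75])
    cv = std / mean if mean != 0 else 0.0
    return np.array([
        mean, var, std, skew, kurt, energy, rms, entropy,
        vmin, vmax, median, vmax - vmin, mad, p25, p75, p75 - p25, cv,
    ])


# ---------------------------------------------------------------------------
# Tamura features
# ---------------------------------------------------------------------------

def _coarseness(crop: np.ndarray, mask: np.ndarray) -> float:
    """Mean over the mask of the best averaging-window size 2^k.

    k* maximizes, per pixel, the absolute difference of 2^k-window averages
    taken 2^(k-1) apart horizontally or vertically. Window sizes are limited
    to 2^k ≤ min(crop dims)/2; a crop too small for any window scores 1.
    """
    h, w = crop.shape
    kmax = int(np.floor(np.log2(max(min(h, w) / 2.0, 1.0))))
    if kmax < 1:
        return 1.0
    best_e = np.full(crop.shape, -1.0)
    best_s = np.ones(crop.shape)
    rows = np.arange(h)
    cols = np.arange(w)
    for k in range(1, kmax + 1):
        size = 2 ** k
        shift = 2 ** (k - 1)
        a = ndimage.uniform_filter(crop, size=size, mode="nearest")
        eh = np.abs(a[:, np.clip(cols + shift, 0, w - 1)]
                    - a[:, np.clip(cols - shift, 0, w - 1)])
        ev = np.abs(a[np.clip(rows + shift, 0, h - 1), :]
                    - a[np.clip(rows - shift, 0, h - 1), :])
        e = np.maximum(eh, ev)
        better = e > best_e  # strict: ties keep the smaller window
        best_e[better] = e[better]
        best_s[better] = size
    return float(best_s[mask].mean())


def _contrast(values: np.ndarray) -> float:
    """Tamura contrast σ/α₄^¼ with α₄ = μ₄/σ⁴ the kurtosis; 0 for σ = 0."""
    std = values.std()
    if std == 0:
        return 0.0
    alpha4 = np.mean((values - values.mean()) ** 4) / std ** 4
    return float(std / alpha4 ** 0.25)


def _orientation_field(crop: np.ndarray):
    gx = ndimage.sobel(crop, axis=1, mode="nearest")
    gy = ndimage.sobel(crop, axis=0, mode="nearest")
    mag = np.hypot(gx, gy)
    theta = np.mod(np.arctan2(gy, gx), np.pi)
    return theta, mag


def _directionality(theta: np.ndarray, mag: np.ndarray, mask: np.ndarray):
    """1 − normalized entropy of the 16-bin orientation histogram over
    strong-gradient mask pixels (magnitude above the mask median)."""
    thr = np.median(mag[mask])
    strong = mask & (mag > thr)
    if not strong.any():
        return 0.0, strong
    bins = np.minimum((theta[strong] / (np.pi / _N_ORIENT_BINS)).astype(int),
                      _N_ORIENT_BINS - 1)
    hist = np.bincount(bins, minlength=_N_ORIENT_BINS)
    p = hist[hist > 0] / hist.sum()
    ent = -(p * np.log(p)).sum() / np.log(_N_ORIENT_BINS)
    return float(1.0 - ent), strong


def _line_likeness(theta: np.ndarray, strong: np.ndarray,
                   distance: int = LINELIKENESS_DISTANCE) -> float:
    """Mean cosine of the orientation difference between strong-gradient
    pixels and the pixel ``distance`` steps along their gradient direction."""
    ys, xs = np.nonzero(strong)
    if ys.size == 0:
        return 0.0
    t = theta[ys, xs]
    qy = np.rint(ys + distance * np.sin(t)).astype(int)
    qx = np.rint(xs + distance * np.cos(t)).astype(int)
    h, w = theta.shape
    inside = (qy >= 0) & (qy < h) & (qx >= 0) & (qx < w)
    if not inside.any():
        return 0.0
    qy, qx, t = qy[inside], qx[inside], t[inside]
    paired = strong[qy, qx]
    if not paired.any():
        return 0.0
    return float(np.cos(t[paired] - theta[qy[paired], qx[paired]]).mean())


def _tamura_base(crop: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """(coarseness, contrast, directionality, line-likeness) on one crop."""
    crs = _coarseness(crop, mask)
    con = _contrast(crop[mask])
    theta, mag = _orientation_field(crop)
    dirn, strong = _directionality(theta, mag, mask)
    lin = _line_likeness(theta, strong)
    return np.array([crs, con, dirn, lin])


def _regularity(crop: np.ndarray) -> float:
    """1 − mean normalized spread of the first four Tamura features over a
    2×2 sub-block partition; 0 when the crop is smaller than 8×8."""
    h, w = crop.shape
    if min(h, w) < 8:
        return 0.0
    h2, w2 = h // 2, w // 2
    blocks = [crop[:h2, :w2], crop[:h2, w2:], crop[h2:, :w2], crop[h2:, w2:]]
    feats = np.stack([
        _tamura_base(b, np.ones(b.shape, dtype=bool)) for b in blocks
    ])
    std = feats.std(axis=0)
    mean = np.abs(feats.mean(axis=0))
    nstd = std / (std + mean + 1e-12)  # in [0, 1) per feature
    return float(1.0 - nstd.mean())


def tamura_features(channel, mask) -> np.ndarray:
    """The 6 Tamura features of a masked region of a single-channel raster.

    Computed on the mask's bounding-box crop with non-mask pixels filled by
    the mask mean. Roughness = coarseness + contrast.
    """
    channel = np.asarray(channel, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if channel.shape != mask.shape:
        raise ValueError("channel and mask shapes differ")
    if not mask.any():
        raise ValueError("tamura_features requires a non-empty mask")
    ys, xs = np.nonzero(mask)
    crop = channel[ys.min():ys.max() + 1, xs.min():xs.max() + 1].copy()
    mcrop = mask[ys.min():ys.max() + 1, xs.min():xs.max() + 1]
    crop[~mcrop] = channel[mask].mean()
    crs, con, dirn, lin = _tamura_base(crop, mcrop)
    reg = _regularity(crop)
    return np.array([crs, con, dirn, lin, reg, crs + con])


def extract_feature_table(image, assignment, image_id=0, labels=None) -> pd.DataFrame:
    """One 69-feature row per superpixel of ``assignment``.

    Row keys: image_id, superpixel_id and the superpixel centroid (row, col).
    When ``labels`` is given, a class column with the majority-vote class of
    each superpixel is appended (see :mod:`tmaseg.ground_truth`).
    """
    image = as_rgb_image(image)
    assignment = np.asarray(assignment)
    check_same_shape(image, assignment)
    channels = split_channels(image)
    k = int(assignment.max()) + 1
    slices = ndimage.find_objects(assignment + 1)
    rows = []
    for sp in range(k):
        sl = slices[sp]
        local = assignment[sl] == sp
        ys, xs = np.nonzero(local)
        feats = np.empty(69)
        for c, chan in enumerate(channels):
            sub = chan[sl]
            vals = sub[local]
            feats[c * 23:c * 23 + 17] = first_order_stats(vals)
            feats[c * 23 + 17:(c + 1) * 23] = tamura_features(sub, local)
        rows.append((
            image_id, sp,
            float(ys.mean() + sl[0].start), float(xs.mean() + sl[1].start),
            *feats,
        ))
    table = pd.DataFrame(rows, columns=KEY_COLUMNS + feature_names())
    if labels is not None:
        from .ground_truth import assign_classes
        votes = assign_classes(assignment, labels)
        table[CLASS_COLUMN] = votes["class"].to_numpy()
    return table
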