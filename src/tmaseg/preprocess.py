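"""Image rescaling and the three enhancement transforms compared in the study.

The pipeline compares normalization (quantile-based linear contrast stretch),
per-channel histogram equalization and histogram matching against a reference
image. All transforms preserve image dimensions and the 8-bit range, and every
rounding step is half-up (see :func:`tmaseg._util.round_half_up`).
"""

from __future__ import annotations

import enum
import logging

import numpy as np
from skimage.transform import resize

from ._util import as_rgb_image, round_half_up

log = logging.getLogger(__name__)

#: default saturation fraction for the contrast stretch; the ImageJ
#: enhance-contrast convention (0.35% of pixels saturated at each end).
DEFAULT_SATURATION = 0.0035


class EnhancementKind(str, enum.Enum):
    NONE = "none"
    NORMALIZE = "normalize"
    EQUALIZE = "equalize"
    MATCH = "match"


def rescale(image, factor: float) -> np.ndarray:
    """Bilinear rescale by ``factor`` ∈ (0, 1]; output dims = max(1, round(d·factor)).

    TMA cores are digitized at roughly 6000×6000; the pipeline works at 25%
    (≈1500×1500), which preserves tissue-level texture at a fraction of the
    computational load.
    """
    if not 0 < factor <= 1:
        raise ValueError(f"rescale factor must be in (0, 1], got {factor}")
    image = as_rgb_image(image)
    if factor == 1.0:
        return image
    h, w = image.shape[:2]
    out_h = max(1, int(round_half_up(h * factor)))
    out_w = max(1, int(round_half_up(w * factor)))
    resized = resize(
        image.astype(float), (out_h, out_w), order=1,
        mode="edge", anti_aliasing=False, preserve_range=True,
    )
    return as_rgb_image(np.clip(round_half_up(resized), 0, 255))


def normalize(image, saturation: float = DEFAULT_SATURATION, per_channel: bool = True) -> np.ndarray:
    """Linear contrast stretch mapping the (s, 1−s) quantiles to (0, 255).

    Values outside the quantile window are clipped. With ``per_channel`` the
    stretch is fitted independently per RGB channel, otherwise on the joint
    histogram of all three channels. A constant channel is returned unchanged
    with a warning.
    """
    if not 0 <= saturation < 0.5:
        raise ValueError(f"saturation must be in [0, 0.5), got {saturation}")
    image = as_rgb_image(image)
    out = image.copy()
    if per_channel:
        for c in range(3):
            out[..., c] = _stretch_channel(image[..., c], saturation)
    else:
        lo, hi = _quantile_window(image, saturation)
        if hi <= lo:
            log.warning("normalize: constant image left unchanged")
            return out
        for c in range(3):
            out[..., c] = _apply_stretch(image[..., c], lo, hi)
    return out


def _quantile_window(values: np.ndarray, saturation: float) -> tuple[float, float]:
    lo = float(np.quantile(values, saturation))
    hi = float(np.quantile(values, 1.0 - saturation))
    return lo, hi


def _apply_stretch(channel: np.ndarray, lo: float, hi: float) -> np.ndarray:
    stretched = (channel.astype(float) - lo) / (hi - lo) * 255.0
    return np.clip(round_half_up(stretched), 0, 255).astype(np.uint8)


def _stretch_channel(channel: np.ndarray, saturation: float) -> np.ndarray:
    lo, hi = _quantile_window(channel, saturation)
    if hi <= lo:
        log.warning("normalize: constant channel left unchanged")
        return channel
    return _apply_stretch(channel, lo, hi)


def equalize_histogram(image) -> np.ndarray:
    """Per-channel 256-bin histogram equalization.

    Mapping: out(v) = round((cdf(v) − cdf_min) / (N − cdf_min) · 255) with N
    the pixel count and cdf_min the smallest nonzero cumulative count. A
    constant channel is returned unchanged.
    """
    image = as_rgb_image(image)
    out = image.copy()
    for c in range(3):
        out[..., c] = _equalize_channel(image[..., c])
    return out


def _equalize_channel(channel: np.ndarray) -> np.ndarray:
    hist = np.bincount(channel.ravel(), minlength=256)
    cdf = np.cumsum(hist)
    n = channel.size
    cdf_min = cdf[np.nonzero(hist)[0][0]]
    if n == cdf_min:  # constant channel
        return channel
    lut = np.clip(round_half_up((cdf - cdf_min) / (n - cdf_min) * 255.0), 0, 255).astype(np.uint8)
    return lut[channel]


def match_histogram(source, reference) -> np.ndarray:
    """Per-channel histogram specification: m(v) = G⁻¹(F(v)).

    F and G are the source and reference empirical CDFs; G⁻¹ picks the
    smallest intensity whose CDF reaches the target mass. The mapping is
    monotone and matching an image to itself is the identity.
    """
    source = as_rgb_image(source)
    reference = as_rgb_image(reference)
    out = source.copy()
    for c in range(3):
        out[..., c] = _match_channel(source[..., c], reference[..., c])
    return out


def _match_channel(src: np.ndarray, ref: np.ndarray) -> np.ndarray:
    f = np.cumsum(np.bincount(src.ravel(), minlength=256)) / src.size
    g = np.cumsum(np.bincount(ref.ravel(), minlength=256)) / ref.size
    # smallest intensity u with G(u) >= F(v); searchsorted('left') on the
    # nondecreasing G gives exactly that index
    lut = np.searchsorted(g, f, side="left").clip(0, 255).astype(np.uint8)
    return lut[src]


def enhance(image, kind: EnhancementKind | str, reference=None, *,
            saturation: float = DEFAULT_SATURATION) -> np.ndarray:
    """Dispatch to the requested enhancement; ``none`` returns the input."""
    kind = EnhancementKind(kind)
    if kind is EnhancementKind.NONE:
        return as_rgb_image(image)
    if kind is EnhancementKind.NORMALIZE:
        return normalize(image, saturation=saturation)
    if kind is EnhancementKind.EQUALIZE:
        return equalize_histogram(image)
    if kind is EnhancementKind.MATCH:
        if reference is None:
            raise ValueError("histogram matching requires a reference image")
        return match_histogram(image, reference)
    raise ValueError(f"unknown enhancement kind {kind!r}")  # pragma: no cover
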