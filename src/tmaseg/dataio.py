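"""Reading and writing of external artifacts.

Covers raster images (JPEG/PNG/TIFF, 8-bit), three-code label images, ImageJ
polygon ``.roi`` files, CSV feature tables and flat TOML run configuration.
Label rasters are always written as lossless PNG so class codes survive
round trips bit-exactly; JPEG is accepted on input only.
"""

from __future__ import annotations

import logging
import struct
import tomllib
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from ._util import COLOR_CLASSES, LABEL_CODES, as_label_image, as_rgb_image

log = logging.getLogger(__name__)

# identifier / position columns of a feature table, in stable order
KEY_COLUMNS = ["image_id", "superpixel_id", "row", "col"]
CLASS_COLUMN = "class"


@dataclass(frozen=True)
class RoiPolygon:
    """Closed polygon in (x, y) pixel coordinates (x = column, y = row)."""

    vertices: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if len(self.vertices) < 3:
            raise ValueError("a polygon ROI needs at least 3 vertices")


def read_image(path) -> np.ndarray:
    """Read an 8-bit raster as an H×W×3 uint8 array.

    Grayscale inputs are replicated to three channels; an alpha channel, if
    present, is dropped.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - normalize decoder errors
        raise OSError(f"cannot read image file {path}: {exc}") from exc
    if arr.dtype != np.uint8:
        raise ValueError(f"{path}: only 8-bit rasters are supported, got dtype {arr.dtype}")
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return as_rgb_image(arr)


def write_image(image, path) -> None:
    image = as_rgb_image(image)
    iio.imwrite(Path(path), image)


def read_label_image(path, strict: bool = True) -> np.ndarray:
    """Read an 8-bit label raster restricted to the codes {0, 2, 3}.

    Accepts either a single-channel code raster or a color-coded RGB raster
    (white→0, red→2, green→3, exact match). In non-strict mode an off-code
    pixel in a single-channel raster is remapped to the nearest allowed code
    (ties toward the smaller code) with a warning; in strict mode it is an
    error.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001
        raise OSError(f"cannot read label file {path}: {exc}") from exc
    if arr.dtype != np.uint8:
        raise ValueError(f"{path}: label images must be 8-bit, got {arr.dtype}")
    if arr.ndim == 3:
        arr = _decode_color_labels(arr, path)
    if arr.ndim != 2:
        raise ValueError(f"{path}: unsupported label raster shape {arr.shape}")
    values = np.unique(arr)
    bad = np.setdiff1d(values, LABEL_CODES)
    if bad.size:
        if strict:
            raise ValueError(
                f"{path}: label image contains values outside {LABEL_CODES}: {bad.tolist()}"
            )
        log.warning(
            "%s: remapping %d off-code values %s to nearest allowed code",
            path, bad.size, bad.tolist(),
        )
        arr = _remap_to_nearest_code(arr)
    return as_label_image(arr)


def _decode_color_labels(arr: np.ndarray, path) -> np.ndarray:
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.shape[2] != 3:
        raise ValueError(f"{path}: unsupported channel count {arr.shape[2]}")
    if np.array_equal(arr[..., 0], arr[..., 1]) and np.array_equal(arr[..., 0], arr[..., 2]):
        return arr[..., 0]  # gray stored as RGB: treat as a code raster
    out = np.full(arr.shape[:2], 255, dtype=np.uint8)
    matched = np.zeros(arr.shape[:2], dtype=bool)
    for color, code in COLOR_CLASSES.items():
        hit = np.all(arr == np.array(color, dtype=np.uint8), axis=-1)
        out[hit] = code
        matched |= hit
    if not matched.all():
        raise ValueError(
            f"{path}: multi-channel label image is not a pure white/red/green color coding"
        )
    return out


def _remap_to_nearest_code(arr: np.ndarray) -> np.ndarray:
    codes = np.array(LABEL_CODES)
    # 256-entry LUT: nearest allowed code, ties toward the smaller code
    lut = np.empty(256, dtype=np.uint8)
    for v in range(256):
        d = np.abs(codes - v)
        lut[v] = codes[np.argmin(d)]  # argmin takes the first (smaller) code on ties
    return lut[arr]


def write_label_image(labels, path) -> None:
    """Write a label raster as single-channel 8-bit PNG (lossless)."""
    labels = as_label_image(labels)
    path = Path(path)
    if path.suffix.lower() not in {".png", ".tif", ".tiff"}:
        raise ValueError(f"label images must use a lossless format, got {path.suffix!r}")
    iio.imwrite(path, labels)


# ---------------------------------------------------------------------------
# ImageJ .roi binary format (big-endian, magic "Iout"); polygon subtype only.
# Layout: bytes 0-3 magic, 4-5 version, 6 roi type (0 = polygon), 8-9 top,
# 10-11 left, 12-13 bottom, 14-15 right, 16-17 n_coordinates; the 64-byte
# header is followed by n x-offsets then n y-offsets as signed 16-bit
# integers relative to (left, top).
# ---------------------------------------------------------------------------

_ROI_MAGIC = b"Iout"
_ROI_TYPE_POLYGON = 0
_ROI_HEADER_SIZE = 64


def read_imagej_roi(path) -> RoiPolygon:
    """Parse an ImageJ ``.roi`` file into an absolute-coordinate polygon."""
    data = Path(path).read_bytes()
    if len(data) < _ROI_HEADER_SIZE or data[:4] != _ROI_MAGIC:
        raise ValueError(f"{path}: not an ImageJ ROI file (magic {data[:4]!r})")
    roi_type = data[6]
    if roi_type != _ROI_TYPE_POLYGON:
        raise ValueError(f"{path}: unsupported ROI type {roi_type}; only polygon ROIs are read")
    top, left, _bottom, _right, n = struct.unpack(">hhhhH", data[8:18])
    need = _ROI_HEADER_SIZE + 4 * n
    if len(data) < need:
        raise ValueError(f"{path}: truncated ROI file ({len(data)} < {need} bytes)")
    xs = struct.unpack(f">{n}h", data[_ROI_HEADER_SIZE:_ROI_HEADER_SIZE + 2 * n])
    ys = struct.unpack(f">{n}h", data[_ROI_HEADER_SIZE + 2 * n:need])
    vertices = tuple((left + x, top + y) for x, y in zip(xs, ys))
    return RoiPolygon(vertices=vertices)


def read_roi_dir(directory) -> list[RoiPolygon]:
    """Read every ``.roi`` file in a directory; the union marks the tumor area."""
    directory = Path(directory)
    rois = [read_imagej_roi(p) for p in sorted(directory.glob("*.roi"))]
    return rois


# ---------------------------------------------------------------------------
# CSV feature tables
# ---------------------------------------------------------------------------

def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write a feature table as CSV with a header row (17 significant digits)."""
    table.to_csv(Path(path), index=False, float_format="%.17g")


def read_feature_table(path, feature_names: list[str] | None = None) -> pd.DataFrame:
    """Read a feature table, validating schema when ``feature_names`` is given.

    The class column is optional; its absence marks an unlabeled table.
    """
    table = pd.read_csv(Path(path))
    expected = None
    if feature_names is not None:
        expected = KEY_COLUMNS + list(feature_names)
        got = [c for c in table.columns if c != CLASS_COLUMN]
        if got != expected:
            raise ValueError(f"{path}: feature-table header mismatch (got {got[:6]}...)")
    check_cols = feature_names if feature_names is not None else [
        c for c in table.columns if c not in KEY_COLUMNS + [CLASS_COLUMN]
    ]
    for col in check_cols:
        if not np.issubdtype(table[col].dtype, np.number):
            raise ValueError(f"{path}: non-numeric values in feature column {col!r}")
    return table


def read_config(path) -> dict:
    """Read a flat TOML key/value run-configuration file."""
    with open(Path(path), "rb") as fh:
        return tomllib.load(fh)
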