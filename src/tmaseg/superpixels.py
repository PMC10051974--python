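"""SLIC superpixel partitioning.

Localized k-means over combined color + position, governed by the two
parameters of the jSLIC-style interface: the initial grid size S (average
superpixel side, default 30 px) and a regularization r ∈ [0, 1] running from
very elastic (r = 0, color dominates) to almost square (r = 1, position
dominates). Internally r is mapped to the SLIC compactness m = 40·r, which on
8-bit intensities spans that perceptual range.

Color distance is computed in an opponent color space derived from RGB by the
fixed orthonormal transform

    O1 = (R + G + B)/√3   (intensity)
    O2 = (R − G)/√2       (red–green opponency)
    O3 = (R + G − 2B)/√6  (yellow–blue opponency)

a config flag (``color_space='rgb'``) switches to plain RGB distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._util import as_rgb_image, check_same_shape

log = logging.getLogger(__name__)

#: compactness reached at r = 1 ("almost square") on 0–255 intensities
M_MAX = 40.0

_OPPONENT = np.array([
    [1 / np.sqrt(3), 1 / np.sqrt(3), 1 / np.sqrt(3)],
    [1 / np.sqrt(2), -1 / np.sqrt(2), 0.0],
    [1 / np.sqrt(6), 1 / np.sqrt(6), -2 / np.sqrt(6)],
])


@dataclass(frozen=True)
class SlicParams:
    grid_size: int = 30
    regularization: float = 0.20
    max_iterations: int = 10
    enforce_connectivity: bool = True
    color_space: str = "opponent"  # 'opponent' or 'rgb'

    def __post_init__(self):
        if self.grid_size < 2:
            raise ValueError("grid_size must be >= 2")
        if not 0.0 <= self.regularization <= 1.0:
            raise ValueError("regularization must be in [0, 1]")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.color_space not in ("opponent", "rgb"):
            raise ValueError(f"unknown color_space {self.color_space!r}")


def _color_features(image: np.ndarray, color_space: str) -> np.ndarray:
    rgb = image.astype(float)
    if color_space == "rgb":
        return rgb
    return rgb @ _OPPONENT.T


def slic(image, params: SlicParams | None = None) -> np.ndarray:
    """Partition an image into SLIC superpixels; returns an H×W id raster.

    Cluster centers start on the centroids of a regular ceil(H/S)×ceil(W/S)
    grid; each pixel is assigned to the nearest center within its 2S×2S
    search window under D = d_color + (m/S)·d_xy; centers move to the mean of
    their members for ``max_iterations`` rounds. With connectivity enforced,
    stray 4-connected fragments smaller than S²/4 are merged into the largest
    adjacent superpixel and ids are compacted to 0..K−1.
    """
    params = params or SlicParams()
    image = as_rgb_image(image)
    h, w = image.shape[:2]
    if min(h, w) < 2:
        raise ValueError("image must be at least 2×2")
    s = params.grid_size
    if s > min(h, w):
        log.warning("grid size %d exceeds min image dimension %d: single superpixel", s, min(h, w))
        return np.zeros((h, w), dtype=np.int32)

    color = _color_features(image, params.color_space)
    ny, nx = -(-h // s), -(-w // s)  # ceil division
    step_y, step_x = h / ny, w / nx
    # center = centroid of its grid cell; for exact division this is
    # (i + 0.5)·S − 0.5 so assignments tile exactly on uniform images
    cy0 = (np.arange(ny) + 0.5) * step_y - 0.5
    cx0 = (np.arange(nx) + 0.5) * step_x - 0.5
    centers_pos = np.array([(y, x) for y in cy0 for x in cx0])
    yy = np.clip(np.rint(centers_pos[:, 0]).astype(int), 0, h - 1)
    xx = np.clip(np.rint(centers_pos[:, 1]).astype(int), 0, w - 1)
    centers_col = color[yy, xx].astype(float)

    m = M_MAX * params.regularization
    spatial_w = m / s
    rows = np.arange(h)
    cols = np.arange(w)
    # initial assignment: grid blocks (also the fallback for pixels that a
    # later iteration's drifted search windows fail to cover)
    assignment = ((np.minimum((rows / step_y).astype(int), ny - 1)[:, None]) * nx
                  + np.minimum((cols / step_x).astype(int), nx - 1)[None, :]).astype(np.int32)

    for _ in range(params.max_iterations):
        dist = np.full((h, w), np.inf)
        new_assignment = np.full((h, w), -1, dtype=np.int32)
        for k in range(len(centers_pos)):
            cy, cx = centers_pos[k]
            r0, r1 = max(0, int(cy) - s), min(h, int(cy) + s + 1)
            c0, c1 = max(0, int(cx) - s), min(w, int(cx) + s + 1)
            sub_col = color[r0:r1, c0:c1]
            d_color = np.sqrt(((sub_col - centers_col[k]) ** 2).sum(axis=-1))
            dy = rows[r0:r1, None] - cy
            dx = cols[None, c0:c1] - cx
            d_xy = np.sqrt(dy * dy + dx * dx)
            d = d_color + spatial_w * d_xy
            better = d < dist[r0:r1, c0:c1]
            dist[r0:r1, c0:c1][better] = d[better]
            new_assignment[r0:r1, c0:c1][better] = k
        uncovered = new_assignment < 0
        if uncovered.any():
            new_assignment[uncovered] = assignment[uncovered]
        assignment = new_assignment
        flat = assignment.ravel()
        counts = np.bincount(flat, minlength=len(centers_pos)).astype(float)
        nonempty = counts > 0
        sum_y = np.bincount(flat, weights=np.repeat(rows, w), minlength=len(centers_pos))
        sum_x = np.bincount(flat, weights=np.tile(cols, h), minlength=len(centers_pos))
        new_pos = centers_pos.copy()
        new_pos[nonempty, 0] = sum_y[nonempty] / counts[nonempty]
        new_pos[nonempty, 1] = sum_x[nonempty] / counts[nonempty]
        new_col = centers_col.copy()
        for c in range(3):
            sc = np.bincount(flat, weights=color[..., c].ravel(), minlength=len(centers_pos))
            new_col[nonempty, c] = sc[nonempty] / counts[nonempty]
        centers_pos, centers_col = new_pos, new_col

    if params.enforce_connectivity:
        assignment = _enforce_connectivity(assignment, min_size=max(1, (s * s) // 4))
    return _compact_ids(assignment)


def _enforce_connectivity(assignment: np.ndarray, min_size: int) -> np.ndarray:
    """Split disconnected ids, then merge fragments < min_size into the
    largest 4-adjacent superpixel (smallest fragments first)."""
    from skimage import measure

    comp = measure.label(assignment + 1, connectivity=1) - 1  # +1: no 0 = background
    n = int(comp.max()) + 1
    sizes = np.bincount(comp.ravel(), minlength=n).astype(np.int64)

    # 4-adjacency between components from horizontal/vertical neighbor pairs
    a = np.concatenate([comp[:-1, :].ravel(), comp[:, :-1].ravel()])
    b = np.concatenate([comp[1:, :].ravel(), comp[:, 1:].ravel()])
    touch = a != b
    pairs = np.unique(
        np.stack([np.minimum(a[touch], b[touch]), np.maximum(a[touch], b[touch])]),
        axis=1)
    adj: list[set] = [set() for _ in range(n)]
    for u, v in pairs.T:
        adj[u].add(int(v))
        adj[v].add(int(u))

    parent = np.arange(n)

    def find(x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    for frag in np.argsort(sizes, kind="stable"):
        frag = int(frag)
        if parent[frag] != frag or sizes[frag] >= min_size:
            continue
        neighbors = {find(v) for v in adj[frag]} - {frag}
        if not neighbors:
            continue
        target = max(neighbors, key=lambda v: (sizes[v], -v))
        parent[frag] = target
        sizes[target] += sizes[frag]
        adj[target] |= adj[frag]

    roots = np.array([find(i) for i in range(n)])
    return roots[comp]


def _compact_ids(assignment: np.ndarray) -> np.ndarray:
    _, compact = np.unique(assignment, return_inverse=True)
    return compact.reshape(assignment.shape).astype(np.int32)


def superpixel_sizes(assignment: np.ndarray) -> np.ndarray:
    """Pixel count per superpixel id; counts sum to H·W."""
    assignment = np.asarray(assignment)
    k = int(assignment.max()) + 1
    counts = np.bincount(assignment.ravel(), minlength=k)
    return np.stack([np.arange(k), counts], axis=1)


def boundary_overlay(image, assignment) -> np.ndarray:
    """Paint pixels adjacent to a differing superpixel id yellow (255,255,0)."""
    image = as_rgb_image(image)
    assignment = np.asarray(assignment)
    check_same_shape(image, assignment)
    boundary = np.zeros(assignment.shape, dtype=bool)
    boundary[:-1, :] |= assignment[:-1, :] != assignment[1:, :]
    boundary[1:, :] |= assignment[1:, :] != assignment[:-1, :]
    boundary[:, :-1] |= assignment[:, :-1] != assignment[:, 1:]
    boundary[:, 1:] |= assignment[:, 1:] != assignment[:, :-1]
    out = image.copy()
    out[boundary] = (255, 255, 0)
    return out
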