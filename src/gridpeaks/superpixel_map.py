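"""Pixel-level label maps, boundary extraction and rendering.

Feature-point cluster labels are lifted to full resolution by giving every
pixel the label of its nearest feature point (Euclidean distance, ties to
the lower raster index).  Because points sit at cell centres this assigns
each R x R cell to its own point and folds the right/bottom remainder
strips into the adjacent cells.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .clustering import ClusterModel
from .grid_features import FeaturePointSet


def _nearest_axis_index(size: int, centers: np.ndarray) -> np.ndarray:
    """Per pixel coordinate, the index of the nearest 1-D centre (first wins)."""
    coords = np.arange(size)[:, None]
    return np.abs(coords - centers[None, :]).argmin(axis=1)


def build_label_map(
    points: FeaturePointSet,
    model: ClusterModel,
    height: int | None = None,
    width: int | None = None,
) -> np.ndarray:
    """Per-pixel cluster labels by nearest feature point.

    The Euclidean nearest point factorises into the nearest grid row and the
    nearest grid column; ties resolve to the smaller index on each axis,
    which is the lower raster index overall.
    """
    height = points.height if height is None else height
    width = points.width if width is None else width
    if height != points.height or width != points.width:
        raise ValueError("label-map dimensions must match the feature grid source")
    if len(model.labels) != len(points):
        raise ValueError("cluster model does not cover the feature-point set")
    R = points.R
    row_centers = np.arange(points.grid_rows) * R + R // 2
    col_centers = np.arange(points.grid_cols) * R + R // 2
    r_idx = _nearest_axis_index(height, row_centers)
    c_idx = _nearest_axis_index(width, col_centers)
    point_labels = model.labels.reshape(points.grid_rows, points.grid_cols)
    return point_labels[np.ix_(r_idx, c_idx)]


def extract_boundaries(labels: np.ndarray) -> np.ndarray:
    """Flag every pixel with a differently-labeled 4-neighbor (both sides)."""
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValueError("label map must be 2-D")
    boundary = np.zeros(labels.shape, dtype=bool)
    dv = labels[:-1, :] != labels[1:, :]
    dh = labels[:, :-1] != labels[:, 1:]
    boundary[:-1, :] |= dv
    boundary[1:, :] |= dv
    boundary[:, :-1] |= dh
    boundary[:, 1:] |= dh
    return boundary


def interface_boundaries(labels: np.ndarray) -> np.ndarray:
    """One-sided boundary mask: each 4-neighbor interface is counted once,
    on its lexicographically first (top/left) pixel.  Used by the metrics so
    interfaces are not double-counted."""
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValueError("label map must be 2-D")
    boundary = np.zeros(labels.shape, dtype=bool)
    boundary[:-1, :] |= labels[:-1, :] != labels[1:, :]
    boundary[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    return boundary


def split_disconnected(labels: np.ndarray) -> np.ndarray:
    """Relabel so every spatially connected component (4-connectivity) gets
    its own label.  Optional post-processing; label ids are renumbered
    consecutively in scan order."""
    labels = np.asarray(labels)
    out = np.full(labels.shape, -1, dtype=np.int64)
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    next_id = 0
    for lab in np.unique(labels):
        comp, ncomp = ndimage.label(labels == lab, structure=structure)
        for k in range(1, ncomp + 1):
            out[comp == k] = next_id
            next_id += 1
    # renumber in first-appearance (scan) order for determinism
    _, first = np.unique(out, return_index=True)
    remap = np.empty(next_id, dtype=np.int64)
    remap[out.ravel()[np.sort(first)]] = np.arange(next_id)
    return remap[out]


def render_superpixel_image(
    rgb: np.ndarray,
    labels: np.ndarray,
    mode: str = "mean_fill",
    boundary_color: tuple[int, int, int] = (255, 0, 0),
) -> np.ndarray:
    """Render a superpixel view of the source image.

    ``mean_fill`` paints every superpixel with its mean RGB value;
    ``boundary_overlay`` draws the boundary pixels in ``boundary_color``
    over the source.
    """
    rgb = np.asarray(rgb)
    labels = np.asarray(labels)
    if rgb.shape[:2] != labels.shape:
        raise ValueError("image and label map dimensions differ")
    if mode == "mean_fill":
        flat = labels.ravel()
        nlab = flat.max() + 1
        counts = np.bincount(flat, minlength=nlab)
        out = np.empty_like(rgb, dtype=np.uint8)
        for ch in range(3):
            sums = np.bincount(flat, weights=rgb[..., ch].ravel(), minlength=nlab)
            means = np.rint(sums / counts)
            out[..., ch] = means[labels]
        return out
    if mode == "boundary_overlay":
        out = rgb.astype(np.uint8).copy()
        out[extract_boundaries(labels)] = boundary_color
        return out
    raise ValueError(f"unknown render mode {mode!r}")


def write_label_map_png(labels: np.ndarray, path) -> None:
    """Write labels as a 16-bit single-channel PNG (lossless round-trip)."""
    import imageio.v3 as iio

    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("labels out of uint16 range")
    iio.imwrite(path, labels.astype(np.uint16), extension=".png")


def write_label_map_csv(labels: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(labels), delimiter=",", fmt="%d")


def read_label_map(path) -> np.ndarray:
    """Read a label map from 16-bit PNG or CSV matrix."""
    path = str(path)
    if path.endswith(".csv"):
        return np.loadtxt(path, delimiter=",", dtype=np.int64, ndmin=2)
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim != 2:
        raise ValueError("label-map PNG must be single-channel")
    return arr.astype(np.int64)
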