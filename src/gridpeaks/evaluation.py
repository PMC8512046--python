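"""Boundary Recall and Achievable Segmentation Accuracy.

Standard superpixel-benchmark definitions: BR is the fraction of
ground-truth boundary pixels within Chebyshev distance ``epsilon``
(default 2) of a predicted boundary pixel; ASA sums, per superpixel, the
largest overlap with any single ground-truth region and divides by the
pixel count.  Ground-truth boundaries are one-sided (each interface counted
once) so the BR denominator is well defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import ndimage, sparse

from .superpixel_map import interface_boundaries


@dataclass
class SegmentationMetrics:
    br: float
    asa: float
    n_superpixels: int


def _check_2d(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be a 2-D array")
    return arr


def boundary_recall(
    pred_boundary: np.ndarray, gt_labels: np.ndarray, epsilon: float = 2.0
) -> float:
    """Fraction of ground-truth boundary pixels near a predicted boundary.

    ``pred_boundary`` is a boolean mask; ``gt_labels`` an integer region
    map from which the (one-sided) reference boundary is derived.  Returns
    1.0 when the ground truth has no boundary at all.
    """
    pred_boundary = _check_2d(pred_boundary, "pred_boundary").astype(bool)
    gt_labels = _check_2d(gt_labels, "gt_labels")
    if pred_boundary.shape != gt_labels.shape:
        raise ValueError("prediction and ground truth dimensions differ")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    gt_boundary = interface_boundaries(gt_labels)
    n_gt = int(gt_boundary.sum())
    if n_gt == 0:
        return 1.0
    size = 2 * int(np.floor(epsilon)) + 1
    near_pred = ndimage.maximum_filter(pred_boundary, size=size, mode="constant")
    return float(near_pred[gt_boundary].sum() / n_gt)


def achievable_segmentation_accuracy(
    labels: np.ndarray, gt_labels: np.ndarray
) -> float:
    """Best-case accuracy when each superpixel takes its dominant gt region."""
    labels = _check_2d(labels, "labels")
    gt_labels = _check_2d(gt_labels, "gt_labels")
    if labels.shape != gt_labels.shape:
        raise ValueError("prediction and ground truth dimensions differ")
    _, pred = np.unique(labels.ravel(), return_inverse=True)
    _, gt = np.unique(gt_labels.ravel(), return_inverse=True)
    contingency = sparse.coo_matrix(
        (np.ones(pred.size), (pred, gt)),
        shape=(pred.max() + 1, gt.max() + 1),
    ).tocsr()
    return float(contingency.max(axis=1).toarray().sum() / pred.size)


def segmentation_metrics(
    labels: np.ndarray,
    ground_truths: np.ndarray | Iterable[np.ndarray],
    epsilon: float = 2.0,
    mode: str = "average",
) -> SegmentationMetrics:
    """BR/ASA against one or several ground-truth annotations.

    With several annotations the metrics are averaged (``mode='average'``)
    or the best annotation is taken (``mode='max'``).
    """
    if isinstance(ground_truths, np.ndarray) and ground_truths.ndim == 2:
        gts = [ground_truths]
    else:
        gts = [np.asarray(g) for g in ground_truths]
    if mode not in ("average", "max"):
        raise ValueError("mode must be 'average' or 'max'")
    labels = _check_2d(labels, "labels")
    pred_boundary = interface_boundaries(labels)
    brs = [boundary_recall(pred_boundary, gt, epsilon) for gt in gts]
    asas = [achievable_segmentation_accuracy(labels, gt) for gt in gts]
    agg = np.mean if mode == "average" else np.max
    return SegmentationMetrics(
        br=float(agg(brs)),
        asa=float(agg(asas)),
        n_superpixels=int(len(np.unique(labels))),
    )


def quantize_to_grid(labels: np.ndarray, R: int) -> np.ndarray:
    """Snap a label map to the R-grid by majority vote per cell.

    Remainder strips at the right/bottom edges are folded into the last full
    cell, mirroring the feature-grid geometry.  Useful for comparing
    cell-resolution segmentations against pixel-resolution ground truth.
    """
    labels = _check_2d(labels, "labels")
    height, width = labels.shape
    gr, gc = height // R, width // R
    if gr < 1 or gc < 1:
        raise ValueError("R exceeds the label-map dimensions")
    row_cell = np.minimum(np.arange(height) // R, gr - 1)
    col_cell = np.minimum(np.arange(width) // R, gc - 1)
    cell_id = row_cell[:, None] * gc + col_cell[None, :]
    _, gt = np.unique(labels.ravel(), return_inverse=True)
    uniq = np.unique(labels)
    counts = sparse.coo_matrix(
        (np.ones(labels.size), (cell_id.ravel(), gt)),
        shape=(gr * gc, len(uniq)),
    ).toarray()
    majority = uniq[counts.argmax(axis=1)]
    return majority[cell_id]


def load_ground_truth(path) -> np.ndarray:
    """Read an integer-labeled ground truth from PNG or CSV."""
    from .superpixel_map import read_label_map

    return read_label_map(path)


def load_bsds_annotations(path) -> list[np.ndarray]:
    """Load the per-annotator segmentations from a BSDS500 ``.mat`` file.

    Only useful for users who downloaded the dataset themselves.
    """
    from scipy.io import loadmat

    mat = loadmat(str(path))
    gts = mat["groundTruth"]
    return [
        np.asarray(gts[0, i]["Segmentation"][0, 0], dtype=np.int64)
        for i in range(gts.shape[1])
    ]
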