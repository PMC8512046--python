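"""End-to-end segmentation convenience wrapper."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import clustering, superpixel_map
from .color_space import rgb_to_lab
from .density import DensityTable, build_density_table
from .grid_features import FeaturePointSet, GridParams, extract_feature_points


@dataclass
class SegmentationResult:
    points: FeaturePointSet
    table: DensityTable | None  # None for the degenerate 1-point grid
    model: clustering.ClusterModel
    label_map: np.ndarray

    @property
    def n_superpixels(self) -> int:
        return int(len(np.unique(self.label_map)))


def segment_image(
    rgb: np.ndarray,
    params: GridParams,
    *,
    linearize: bool = False,
    enforce_connectivity: bool = False,
) -> SegmentationResult:
    """Run the full pipeline on an 8-bit RGB image.

    Conversion to Lab, grid feature extraction, color-gated density,
    centre selection per ``params.strategy`` and chain assignment, then the
    pixel-level label map.
    """
    lab = rgb_to_lab(rgb, linearize=linearize)
    points = extract_feature_points(lab, params)
    if len(points) == 1:
        # a 1-point grid has no defined delta: single-cluster result
        model = clustering.ClusterModel(
            centers=np.array([0]), labels=np.zeros(1, dtype=np.int64), M=1
        )
        label_map = np.zeros((points.height, points.width), dtype=np.int64)
        return SegmentationResult(points, None, model, label_map)
    table = build_density_table(points, params.k_eff, params.psi)
    if params.strategy == "curve":
        centers = clustering.select_centers_curve(table, params.a)
    elif params.strategy == "lambda":
        centers = clustering.select_centers_lambda(table, params.lambda_thresh)
    else:
        centers = clustering.select_centers_top_m(table, params.M)
    model = clustering.assign_clusters(table, centers)
    label_map = superpixel_map.build_label_map(points, model)
    if enforce_connectivity:
        label_map = superpixel_map.split_disconnected(label_map)
    return SegmentationResult(points, table, model, label_map)
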