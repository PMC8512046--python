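"""Cluster-centre selection and chain assignment.

Centres are the points whose normalised density-delta product exceeds a
threshold (equivalently, the points above the separating curve
``delta' = a / rho'``), or the top-M points by that product.  The densest
point is always a centre.  Every remaining point follows its
nearest-denser-predecessor link until a centre is reached and inherits that
centre's cluster id.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .density import DensityTable


@dataclass
class ClusterModel:
    """Selected centres (raster indices) and per-point cluster labels."""

    centers: np.ndarray
    labels: np.ndarray
    M: int


def _order_by_lambda(table: DensityTable, idx: np.ndarray) -> np.ndarray:
    # descending lambda, ties by ascending raster index
    return idx[np.lexsort((idx, -table.lam[idx]))]


def select_centers_curve(table: DensityTable, a: float) -> np.ndarray:
    """Points strictly above the curve ``delta' = a / rho'`` plus the
    rank-0 point, ordered by descending lambda."""
    if a <= 0:
        raise ValueError("a must be positive")
    selected = np.flatnonzero(table.lam > a)
    rank0 = table.ranked[0]
    if rank0 not in selected:
        selected = np.append(selected, rank0)
    return _order_by_lambda(table, selected)


def select_centers_lambda(table: DensityTable, lambda_thresh: float) -> np.ndarray:
    """Points with ``lam > lambda_thresh`` plus the rank-0 point.

    Coincides with :func:`select_centers_curve` at ``a = lambda_thresh``;
    both entry points are kept because the two selection rules are stated
    separately.
    """
    if lambda_thresh <= 0:
        raise ValueError("lambda_thresh must be positive")
    return select_centers_curve(table, lambda_thresh)


def select_centers_top_m(table: DensityTable, M: int) -> np.ndarray:
    """The M points of largest lambda (ties by ascending raster index)."""
    n = len(table)
    if int(M) != M or not 1 <= M <= n:
        raise ValueError(f"M must be an integer in [1, {n}], got {M!r}")
    return _order_by_lambda(table, np.arange(n))[:M]


def assign_clusters(table: DensityTable, centers: np.ndarray) -> ClusterModel:
    """Label every point with the centre its parent chain reaches.

    ``centers`` must contain the rank-0 point (its chain has nowhere to go).
    Chains terminate because every parent has a strictly smaller rank.
    """
    centers = np.asarray(centers, dtype=np.int64)
    if centers.size == 0:
        raise ValueError("centers must be non-empty")
    rank0 = table.ranked[0]
    if rank0 not in centers:
        raise ValueError("centers must include the densest (rank-0) point")
    n = len(table)
    labels = np.full(n, -1, dtype=np.int64)
    cluster_id = {int(c): k for k, c in enumerate(centers)}
    for i in table.ranked:  # ascending rank: parents are labeled first
        cid = cluster_id.get(int(i))
        labels[i] = cid if cid is not None else labels[table.parent[i]]
    return ClusterModel(centers=centers, labels=labels, M=len(centers))


def clusters_to_csv(model: ClusterModel, path) -> None:
    """Write per-point assignments as CSV (m, label, is_center)."""
    n = len(model.labels)
    is_center = np.zeros(n, dtype=np.int64)
    is_center[model.centers] = 1
    table = np.column_stack([np.arange(n), model.labels, is_center])
    np.savetxt(
        path, table, delimiter=",", header="m,label,is_center", comments="", fmt="%d"
    )
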