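"""Color-gated density, nearest-denser links and normalisation.

The density ``rho`` of a feature point counts the feature points (itself
included) within spatial radius K whose squared Lab feature distance is at
most psi.  Points are then ranked by descending density (ties broken by
ascending raster index); ``delta`` of a ranked point is the distance to the
nearest earlier-ranked point and ``parent`` is that point.  The densest
point receives the maximum of the other deltas and no parent.

Normalised ``rho`` and ``delta`` and their product ``lam`` feed the
cluster-centre selection rules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .grid_features import FeaturePointSet


@dataclass
class DensityTable:
    """Per-feature-point density statistics, indexed by raster index.

    ``order[i]`` is the rank of point ``i`` in the descending-density
    ordering (0 = densest); ``ranked[r]`` is the raster index at rank ``r``.
    ``parent[i]`` is the raster index of the nearest earlier-ranked point
    (-1 for the rank-0 point).
    """

    rho: np.ndarray
    order: np.ndarray
    ranked: np.ndarray
    delta: np.ndarray
    parent: np.ndarray
    rho_norm: np.ndarray
    delta_norm: np.ndarray
    lam: np.ndarray
    positions: np.ndarray

    def __len__(self) -> int:
        return len(self.rho)

    def to_csv(self, path) -> None:
        n = len(self)
        table = np.column_stack(
            [
                np.arange(n),
                self.positions[:, 0],
                self.positions[:, 1],
                self.rho,
                self.order,
                self.delta,
                self.parent,
                self.rho_norm,
                self.delta_norm,
                self.lam,
            ]
        )
        np.savetxt(
            path,
            table,
            delimiter=",",
            header="m,h,w,rho,order,delta,parent,rho_norm,delta_norm,lam",
            comments="",
            fmt=["%d", "%.1f", "%.1f", "%d", "%d", "%.9f", "%d", "%.9f", "%.9f", "%.9f"],
        )


def compute_density(
    points: FeaturePointSet,
    K: float,
    psi: float,
    *,
    spatial_squared: bool = False,
) -> np.ndarray:
    """Count, per feature point, the spatially near and color-similar points.

    The spatial gate compares the Euclidean pixel distance with K (pass
    ``spatial_squared=True`` to compare the squared distance instead); the
    color gate compares the squared Lab feature distance with psi.  Both
    gates are inclusive and every point passes its own gates, so rho >= 1.
    """
    if K <= 0:
        raise ValueError("K must be positive")
    if psi <= 0:
        raise ValueError("psi must be positive")
    radius = np.sqrt(K) if spatial_squared else float(K)
    pos = points.positions
    tree = cKDTree(pos)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    rho = np.ones(len(points), dtype=np.int64)
    if len(pairs):
        diff = points.features[pairs[:, 0]] - points.features[pairs[:, 1]]
        similar = (diff**2).sum(axis=1) <= psi
        np.add.at(rho, pairs[similar, 0], 1)
        np.add.at(rho, pairs[similar, 1], 1)
    return rho


def rank_by_density(
    densities: np.ndarray,
    positions: np.ndarray,
    tie_radius: float | None = None,
    features: np.ndarray | None = None,
    psi: float | None = None,
) -> np.ndarray:
    """Descending-density ordering; returns raster indices rank by rank.

    Ties are broken by ascending raster index.  When ``tie_radius`` is
    given, equal-density points are additionally grouped into connected
    components (points within ``tie_radius`` of each other and, when
    ``features``/``psi`` are given, within the squared-feature color gate)
    and each component is enumerated breadth-first from its lowest-index
    point, components in order of their lowest index.  This guarantees that
    on a density plateau every point except the component's first has an
    earlier-ranked point within ``tie_radius``, so nearest-predecessor
    chains cannot leak across a plateau boundary; on inputs without exact
    density ties the ordering is the plain one.
    """
    rho = np.asarray(densities)
    pos = np.asarray(positions, dtype=np.float64)
    n = len(rho)
    idx = np.arange(n)
    if tie_radius is None:
        return np.lexsort((idx, -rho))
    ranked: list[int] = []
    for value in np.unique(rho)[::-1]:
        band = idx[rho == value]
        if len(band) == 1:
            ranked.append(int(band[0]))
            continue
        tree = cKDTree(pos[band])
        pairs = tree.query_pairs(tie_radius, output_type="ndarray")
        if len(pairs) and features is not None and psi is not None:
            diff = features[band[pairs[:, 0]]] - features[band[pairs[:, 1]]]
            pairs = pairs[(diff**2).sum(axis=1) <= psi]
        neighbors: dict[int, list[int]] = {int(b): [] for b in band}
        for u, v in pairs:
            neighbors[int(band[u])].append(int(band[v]))
            neighbors[int(band[v])].append(int(band[u]))
        seen: set[int] = set()
        for start in band:  # ascending raster index
            start = int(start)
            if start in seen:
                continue
            queue = [start]
            seen.add(start)
            while queue:
                nxt: list[int] = []
                for u in queue:
                    ranked.append(u)
                    for v in sorted(neighbors[u]):
                        if v not in seen:
                            seen.add(v)
                            nxt.append(v)
                queue = sorted(set(nxt))
        # BFS layers are sorted, so enumeration is deterministic
    return np.asarray(ranked, dtype=np.int64)


def compute_delta(
    densities: np.ndarray,
    positions: np.ndarray,
    tie_radius: float | None = None,
    features: np.ndarray | None = None,
    psi: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rank points by density and link each one to its nearest predecessor.

    Returns
    -------
    order, delta, parent
        All indexed by raster index.  ``order`` is the descending-density
        rank (ties per :func:`rank_by_density`).  For rank m > 0, ``delta``
        is the minimum Euclidean distance to any earlier-ranked point and
        ``parent`` the raster index of that point; distance ties are
        resolved towards the most color-similar candidate (when
        ``features`` are given), then the densest, then the lowest raster
        index.  The rank-0 point gets the maximum of the other deltas and
        parent -1.
    """
    rho = np.asarray(densities)
    pos = np.asarray(positions, dtype=np.float64)
    if features is not None:
        features = np.asarray(features, dtype=np.float64)
    n = len(rho)
    if n < 2:
        raise ValueError("delta requires at least 2 feature points")
    idx = np.arange(n)
    ranked = rank_by_density(rho, pos, tie_radius, features, psi)  # raster index per rank
    order = np.empty(n, dtype=np.int64)
    order[ranked] = idx

    pos_r = pos[ranked]
    rho_r = rho[ranked]
    feat_r = features[ranked] if features is not None else None
    delta_r = np.empty(n, dtype=np.float64)
    parent_r = np.empty(n, dtype=np.int64)
    parent_r[0] = -1
    for m in range(1, n):
        d = np.sqrt(((pos_r[:m] - pos_r[m]) ** 2).sum(axis=1))
        dmin = d.min()
        cand = np.flatnonzero(d == dmin)
        if len(cand) > 1:
            # prefer strictly denser candidates, then the most color-similar,
            # then the lower raster index
            denser = cand[rho_r[cand] > rho_r[m]]
            if len(denser):
                cand = denser
            if feat_r is not None:
                cdist = ((feat_r[cand] - feat_r[m]) ** 2).sum(axis=1)
            else:
                cdist = np.zeros(len(cand))
            best = cand[np.lexsort((ranked[cand], -rho_r[cand], cdist))[0]]
        else:
            best = cand[0]
        delta_r[m] = dmin
        parent_r[m] = ranked[best]
    delta_r[0] = delta_r[1:].max()

    delta = np.empty(n, dtype=np.float64)
    parent = np.empty(n, dtype=np.int64)
    delta[ranked] = delta_r
    parent[ranked] = parent_r
    return order, delta, parent


def normalize(values: np.ndarray) -> np.ndarray:
    """Min-max rescale to [0, 1]; an all-equal input maps to all zeros."""
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("cannot normalize an empty array")
    vmin, vmax = v.min(), v.max()
    if vmax == vmin:
        return np.zeros_like(v)
    return (v - vmin) / (vmax - vmin)


def build_density_table(
    points: FeaturePointSet,
    K: float,
    psi: float,
    *,
    spatial_squared: bool = False,
) -> DensityTable:
    """Full density / delta / lambda table for a feature-point set."""
    rho = compute_density(points, K, psi, spatial_squared=spatial_squared)
    order, delta, parent = compute_delta(
        rho, points.positions, tie_radius=K, features=points.features, psi=psi
    )
    rho_norm = normalize(rho)
    delta_norm = normalize(delta)
    return DensityTable(
        rho=rho,
        order=order,
        ranked=np.argsort(order),
        delta=delta,
        parent=parent,
        rho_norm=rho_norm,
        delta_norm=delta_norm,
        lam=rho_norm * delta_norm,
        positions=points.positions,
    )
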