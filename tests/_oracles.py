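"""Independent brute-force oracles used by the test suite.

Everything here is written as plain scalar/loop code, deliberately separate
from the vectorized implementations it checks.
"""

from __future__ import annotations

import math

import numpy as np

# --- color conversion -------------------------------------------------------

_M = [
    [0.4124, 0.3576, 0.1805],
    [0.2126, 0.7152, 0.0722],
    [0.0193, 0.1192, 0.9505],
]
_WHITE = (0.9505, 1.0, 1.089)


def _f_scalar(t: float) -> float:
    if t > (6.0 / 29.0) ** 3:
        return t ** (1.0 / 3.0)
    return t / (3.0 * (6.0 / 29.0) ** 2) + 4.0 / 29.0


def lab_pixel(r: int, g: int, b: int) -> tuple[float, float, float]:
    """Scalar per-pixel RGB->Lab conversion."""
    rgb = (r / 255.0, g / 255.0, b / 255.0)
    xyz = [sum(_M[i][j] * rgb[j] for j in range(3)) for i in range(3)]
    fx, fy, fz = (_f_scalar(xyz[i] / _WHITE[i]) for i in range(3))
    return 116.0 * fy - 16.0, 500.0 * (fx - fy), 200.0 * (fy - fz)


# --- grid features ----------------------------------------------------------

def block_mean_image(lab: np.ndarray, R: int) -> np.ndarray:
    """Nested-loop block mean with clipped border blocks."""
    h, w = lab.shape[:2]
    out = np.empty_like(lab, dtype=float)
    for i in range(h):
        for j in range(w):
            r0, c0 = (i // R) * R, (j // R) * R
            block = lab[r0 : min(r0 + R, h), c0 : min(c0 + R, w)]
            out[i, j] = block.reshape(-1, lab.shape[2]).mean(axis=0)
    return out


def cell_mean_features(lab: np.ndarray, R: int) -> np.ndarray:
    """Direct-summation per-cell means, row-major cell order."""
    h, w = lab.shape[:2]
    gr, gc = h // R, w // R
    feats = []
    for r in range(gr):
        for c in range(gc):
            total = [0.0, 0.0, 0.0]
            for i in range(r * R, r * R + R):
                for j in range(c * R, c * R + R):
                    for k in range(3):
                        total[k] += lab[i, j, k]
            feats.append([t / (R * R) for t in total])
    return np.array(feats)


# --- density / delta --------------------------------------------------------

def density_counts(
    positions: np.ndarray, features: np.ndarray, K: float, psi: float
) -> np.ndarray:
    """O(N^2) color-gated neighbour counts (self included)."""
    n = len(positions)
    rho = np.zeros(n, dtype=int)
    for p in range(n):
        for q in range(n):
            spatial = math.dist(positions[p], positions[q])
            color = sum((features[p][k] - features[q][k]) ** 2 for k in range(3))
            if spatial <= K and color <= psi:
                rho[p] += 1
    return rho


def plain_ranking(rho: np.ndarray) -> list[int]:
    return sorted(range(len(rho)), key=lambda i: (-rho[i], i))


def plateau_ranking(
    rho: np.ndarray,
    positions: np.ndarray,
    tie_radius: float,
    features: np.ndarray | None = None,
    psi: float | None = None,
) -> list[int]:
    """Band-by-band connected-component BFS ordering."""
    n = len(rho)
    ranked: list[int] = []
    for value in sorted(set(int(v) for v in rho), reverse=True):
        band = [i for i in range(n) if rho[i] == value]
        adj: dict[int, list[int]] = {i: [] for i in band}
        for a in band:
            for b in band:
                if a >= b:
                    continue
                if math.dist(positions[a], positions[b]) > tie_radius:
                    continue
                if features is not None and psi is not None:
                    color = sum(
                        (features[a][k] - features[b][k]) ** 2 for k in range(3)
                    )
                    if color > psi:
                        continue
                adj[a].append(b)
                adj[b].append(a)
        seen: set[int] = set()
        for start in band:
            if start in seen:
                continue
            layer = [start]
            seen.add(start)
            while layer:
                ranked.extend(layer)
                nxt = sorted(
                    {v for u in layer for v in adj[u] if v not in seen}
                )
                seen.update(nxt)
                layer = nxt
    return ranked


def delta_parent(
    rho: np.ndarray,
    positions: np.ndarray,
    ranked: list[int],
    features: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Exhaustive pairwise scan for delta and parent, given a ranking."""
    n = len(rho)
    delta = np.zeros(n)
    parent = np.full(n, -1)
    for m in range(1, n):
        i = ranked[m]
        dists = [(math.dist(positions[i], positions[ranked[k]]), k) for k in range(m)]
        dmin = min(d for d, _ in dists)
        cand = [ranked[k] for d, k in dists if d == dmin]
        denser = [j for j in cand if rho[j] > rho[i]]
        if denser:
            cand = denser
        if features is not None:
            cand.sort(
                key=lambda j: (
                    sum((features[i][k] - features[j][k]) ** 2 for k in range(3)),
                    -rho[j],
                    j,
                )
            )
        else:
            cand.sort(key=lambda j: (-rho[j], j))
        delta[i] = dmin
        parent[i] = cand[0]
    top = ranked[0]
    delta[top] = max(delta[i] for i in ranked[1:])
    return delta, parent


def chain_label(point: int, parent: np.ndarray, center_ids: dict[int, int]) -> int:
    """Recursive chain walk to the first centre."""
    if point in center_ids:
        return center_ids[point]
    return chain_label(int(parent[point]), parent, center_ids)


# --- label maps and metrics -------------------------------------------------

def nearest_point_labels(
    positions: np.ndarray, point_labels: np.ndarray, height: int, width: int
) -> np.ndarray:
    """Per-pixel nearest feature point (ties -> lowest point index)."""
    out = np.empty((height, width), dtype=int)
    for i in range(height):
        for j in range(width):
            best, best_d = -1, None
            for m, (h, w) in enumerate(positions):
                d = (i - h) ** 2 + (j - w) ** 2
                if best_d is None or d < best_d:
                    best, best_d = m, d
            out[i, j] = point_labels[best]
    return out


def boundary_scan(labels: np.ndarray) -> np.ndarray:
    """Per-pixel 4-neighbour difference scan (both sides)."""
    h, w = labels.shape
    out = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ni, nj = i + di, j + dj
                if 0 <= ni < h and 0 <= nj < w and labels[ni, nj] != labels[i, j]:
                    out[i, j] = True
    return out


def asa_contingency(labels: np.ndarray, gt: np.ndarray) -> float:
    """Max-overlap coverage from an explicit contingency table."""
    overlap: dict[tuple[int, int], int] = {}
    for a, b in zip(labels.ravel(), gt.ravel()):
        overlap[(int(a), int(b))] = overlap.get((int(a), int(b)), 0) + 1
    best: dict[int, int] = {}
    for (a, _), cnt in overlap.items():
        best[a] = max(best.get(a, 0), cnt)
    return sum(best.values()) / labels.size


def br_distance_scan(
    pred_boundary: np.ndarray, gt_boundary: np.ndarray, epsilon: float
) -> float:
    """Per-gt-pixel Chebyshev distance scan."""
    gt_pts = list(zip(*np.nonzero(gt_boundary)))
    if not gt_pts:
        return 1.0
    pred_pts = list(zip(*np.nonzero(pred_boundary)))
    hit = 0
    for gi, gj in gt_pts:
        for pi, pj in pred_pts:
            if max(abs(gi - pi), abs(gj - pj)) <= epsilon:
                hit += 1
                break
    return hit / len(gt_pts)
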