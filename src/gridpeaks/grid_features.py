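"""Grid feature-point extraction and block-mean smoothing.

Feature points sit at the centres of the regular R x R grid cells,
``h = R*r + R//2``, ``w = R*c + R//2`` for ``r < floor(H/R)`` and
``c < floor(W/R)``, so the point count is exactly
``floor(H/R) * floor(W/R)``.  Each point carries the arithmetic mean of the
Lab values over its own cell, which doubles as an R x R mean filter of the
image.  Remainder strips at the right/bottom edges (when H or W is not a
multiple of R) have no feature point of their own; pixels there are attached
to the nearest point at the label-map stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_STRATEGIES = ("curve", "lambda", "topM")


@dataclass(frozen=True)
class GridParams:
    """Parameters of the segmentation pipeline.

    Attributes
    ----------
    R
        Grid interval in pixels (integer >= 2).
    K
        Spatial neighbourhood radius in pixels; defaults to ``1.3 * R``.
    psi
        Color-similarity threshold applied to the squared Lab distance.
    a
        Separating-curve parameter of the ``curve`` strategy.
    lambda_thresh
        Threshold of the ``lambda`` strategy.
    M
        Requested superpixel count (``topM`` strategy only).
    strategy
        One of ``curve``, ``lambda``, ``topM``.
    """

    R: int = 8
    K: float | None = None
    psi: float = 13.0
    a: float = 0.005
    lambda_thresh: float = 0.005
    M: int | None = None
    strategy: str = "curve"

    def __post_init__(self) -> None:
        if int(self.R) != self.R or self.R < 2:
            raise ValueError(f"R must be an integer >= 2, got {self.R!r}")
        if self.K is not None and self.K <= 0:
            raise ValueError("K must be positive")
        if self.psi <= 0:
            raise ValueError("psi must be positive")
        if self.a <= 0:
            raise ValueError("a must be positive")
        if self.lambda_thresh <= 0:
            raise ValueError("lambda_thresh must be positive")
        if self.strategy not in _STRATEGIES:
            raise ValueError(f"strategy must be one of {_STRATEGIES}")
        if self.strategy == "topM" and self.M is None:
            raise ValueError("strategy 'topM' requires M")
        if self.M is not None and (int(self.M) != self.M or self.M < 1):
            raise ValueError("M must be an integer >= 1")

    @property
    def k_eff(self) -> float:
        """Effective neighbourhood radius (default 1.3 * R)."""
        return 1.3 * self.R if self.K is None else float(self.K)

    def validate_for_image(self, height: int, width: int) -> None:
        if self.R > min(height, width):
            raise ValueError(
                f"R={self.R} exceeds the smallest image dimension "
                f"({height}x{width})"
            )


@dataclass
class FeaturePointSet:
    """The regular grid of feature points of one image.

    Points are stored in row-major raster order; index ``m`` corresponds to
    grid cell ``(m // grid_cols, m % grid_cols)``.
    """

    rows: np.ndarray  # pixel row coordinate h, shape (N,)
    cols: np.ndarray  # pixel column coordinate w, shape (N,)
    features: np.ndarray  # mean (L, a, b) per point, shape (N, 3)
    grid_rows: int
    grid_cols: int
    height: int
    width: int
    R: int

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def positions(self) -> np.ndarray:
        """(N, 2) float array of (row, col) pixel coordinates."""
        return np.stack([self.rows, self.cols], axis=1).astype(np.float64)

    def to_csv(self, path) -> None:
        """Write the feature table (m, h, w, Lbar, abar, bbar)."""
        n = len(self)
        table = np.column_stack(
            [np.arange(n), self.rows, self.cols, self.features]
        )
        np.savetxt(
            path,
            table,
            delimiter=",",
            header="m,h,w,Lbar,abar,bbar",
            comments="",
            fmt=["%d", "%d", "%d", "%.9f", "%.9f", "%.9f"],
        )


def _check_lab(lab: np.ndarray) -> np.ndarray:
    lab = np.asarray(lab, dtype=np.float64)
    if lab.ndim != 3 or lab.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 Lab image, got shape {lab.shape!r}")
    return lab


def extract_feature_points(lab: np.ndarray, params: GridParams) -> FeaturePointSet:
    """Extract the grid feature points with cell-mean Lab features."""
    lab = _check_lab(lab)
    height, width = lab.shape[:2]
    params.validate_for_image(height, width)
    R = params.R
    gr, gc = height // R, width // R
    # full cells only; reshape to (gr, R, gc, R, 3) and average each cell
    core = lab[: gr * R, : gc * R]
    feats = core.reshape(gr, R, gc, R, 3).mean(axis=(1, 3))
    rr, cc = np.meshgrid(np.arange(gr), np.arange(gc), indexing="ij")
    return FeaturePointSet(
        rows=(rr * R + R // 2).ravel(),
        cols=(cc * R + R // 2).ravel(),
        features=feats.reshape(-1, 3),
        grid_rows=gr,
        grid_cols=gc,
        height=height,
        width=width,
        R=R,
    )


def smoothed_image(lab: np.ndarray, R: int) -> np.ndarray:
    """Replace every pixel by the mean of its R x R block.

    Partial blocks at the right/bottom borders are averaged over their true
    (clipped) size.
    """
    lab = _check_lab(lab)
    height, width = lab.shape[:2]
    if int(R) != R or R < 1:
        raise ValueError(f"R must be a positive integer, got {R!r}")
    if R > min(height, width):
        raise ValueError(f"R={R} exceeds the smallest image dimension")
    row_edges = np.arange(0, height, R)
    col_edges = np.arange(0, width, R)
    sums = np.add.reduceat(np.add.reduceat(lab, row_edges, axis=0), col_edges, axis=1)
    row_sizes = np.diff(np.append(row_edges, height))
    col_sizes = np.diff(np.append(col_edges, width))
    counts = np.outer(row_sizes, col_sizes)[..., None]
    means = sums / counts
    return np.repeat(np.repeat(means, row_sizes, axis=0), col_sizes, axis=1)
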