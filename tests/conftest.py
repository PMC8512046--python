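from __future__ import annotations

import numpy as np
import pytest

from gridpeaks.grid_features import FeaturePointSet


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def random_rgb(rng) -> np.ndarray:
    return rng.integers(0, 256, size=(24, 24, 3), dtype=np.uint8)


def make_point_set(
    positions: np.ndarray, features: np.ndarray, R: int = 8
) -> FeaturePointSet:
    """Wrap arbitrary positions/features as a FeaturePointSet for the
    density-stage tests (grid bookkeeping fields are not used there)."""
    positions = np.asarray(positions, dtype=np.float64)
    n = len(positions)
    return FeaturePointSet(
        rows=positions[:, 0],
        cols=positions[:, 1],
        features=np.asarray(features, dtype=np.float64),
        grid_rows=n,
        grid_cols=1,
        height=int(positions[:, 0].max()) + 1 if n else 1,
        width=int(positions[:, 1].max()) + 1 if n else 1,
        R=R,
    )


def cluster_agreement(labels: np.ndarray, reference: np.ndarray) -> float:
    """Fraction of points whose cluster maps onto its majority reference id."""
    agree = 0
    for c in np.unique(labels):
        _, counts = np.unique(reference[labels == c], return_counts=True)
        agree += counts.max()
    return agree / len(labels)
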