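"""Deterministic synthetic scenes with known ground truth.

Every generator produces a piecewise-constant color image (regions defined
in Lab, rendered to 8-bit RGB through the inverse color transform) plus a
matching integer ground-truth label map.  Gaussian channel noise is added
in RGB space and clipped to [0, 255].  A single integer seed drives one
``numpy.random.default_rng`` stream per scene, so identical parameters give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .color_space import lab_to_rgb

#: Well-separated Lab colors (squared mutual distance far above the default
#: color gate of 13).
DEFAULT_PALETTE: tuple[tuple[float, float, float], ...] = (
    (60.0, 40.0, 20.0),
    (70.0, -45.0, 30.0),
    (40.0, 10.0, -50.0),
    (85.0, 5.0, 60.0),
    (30.0, -20.0, -10.0),
    (55.0, 60.0, -40.0),
    (75.0, -10.0, -60.0),
    (45.0, -55.0, 45.0),
)


@dataclass
class SyntheticScene:
    rgb: np.ndarray
    gt: np.ndarray
    region_colors: list[tuple[float, float, float]]
    seed: int


def _validate_dims(height: int, width: int) -> None:
    if height < 1 or width < 1:
        raise ValueError("height and width must be >= 1")


def _render(
    gt: np.ndarray,
    colors: Sequence[tuple[float, float, float]],
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    lab = np.asarray(colors, dtype=np.float64)[gt]
    rgb = lab_to_rgb(lab).astype(np.float64)
    if noise_sd > 0:
        rgb = rgb + rng.normal(0.0, noise_sd, size=rgb.shape)
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


def make_two_region(
    height: int,
    width: int,
    color_left: tuple[float, float, float] = DEFAULT_PALETTE[0],
    color_right: tuple[float, float, float] = DEFAULT_PALETTE[1],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SyntheticScene:
    """Vertical half-plane split: region 0 left, region 1 right."""
    _validate_dims(height, width)
    rng = np.random.default_rng(seed)
    gt = np.zeros((height, width), dtype=np.int64)
    gt[:, width // 2 :] = 1
    colors = [tuple(color_left), tuple(color_right)]
    return SyntheticScene(_render(gt, colors, noise_sd, rng), gt, colors, seed)


def make_disk(
    height: int,
    width: int,
    bg: tuple[float, float, float] = DEFAULT_PALETTE[0],
    fg: tuple[float, float, float] = DEFAULT_PALETTE[2],
    radius: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SyntheticScene:
    """Centred disk (region 1) on a background (region 0)."""
    _validate_dims(height, width)
    rng = np.random.default_rng(seed)
    rr, cc = np.mgrid[:height, :width]
    dist2 = (rr - (height - 1) / 2.0) ** 2 + (cc - (width - 1) / 2.0) ** 2
    gt = (dist2 <= radius**2).astype(np.int64)
    colors = [tuple(bg), tuple(fg)]
    return SyntheticScene(_render(gt, colors, noise_sd, rng), gt, colors, seed)


def make_voronoi_mosaic(
    height: int,
    width: int,
    n_sites: int,
    palette: Sequence[tuple[float, float, float]] = DEFAULT_PALETTE,
    noise_sd: float = 0.0,
    seed: int = 0,
    min_color_gap: float = 13.0,
) -> SyntheticScene:
    """Voronoi partition of ``n_sites`` random sites.

    Cell colors are drawn greedily from ``palette`` so that 4-adjacent cells
    differ by more than ``min_color_gap`` in squared Lab distance; raises
    ``ValueError`` when the palette cannot color the adjacency graph.
    """
    _validate_dims(height, width)
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    sites = np.column_stack(
        [rng.uniform(0, height, n_sites), rng.uniform(0, width, n_sites)]
    )
    rr, cc = np.mgrid[:height, :width]
    pix = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(np.float64)
    d2 = ((pix[:, None, :] - sites[None, :, :]) ** 2).sum(axis=2)
    gt = d2.argmin(axis=1).reshape(height, width)

    # adjacency of cells that actually touch in the raster
    adjacency: dict[int, set[int]] = {i: set() for i in range(n_sites)}
    for a, b in zip(gt[:, :-1].ravel(), gt[:, 1:].ravel()):
        if a != b:
            adjacency[int(a)].add(int(b))
            adjacency[int(b)].add(int(a))
    for a, b in zip(gt[:-1, :].ravel(), gt[1:, :].ravel()):
        if a != b:
            adjacency[int(a)].add(int(b))
            adjacency[int(b)].add(int(a))

    pal = np.asarray(palette, dtype=np.float64)
    choice = np.full(n_sites, -1, dtype=np.int64)
    for cell in range(n_sites):
        taken = [choice[n] for n in adjacency[cell] if choice[n] >= 0]
        ok = None
        for k in range(len(pal)):
            if any(
                k == t or ((pal[k] - pal[t]) ** 2).sum() <= min_color_gap
                for t in taken
            ):
                continue
            ok = k
            break
        if ok is None:
            raise ValueError(
                "palette too small to color adjacent cells distinctly"
            )
        choice[cell] = ok
    colors = [tuple(pal[k]) for k in choice]
    return SyntheticScene(_render(gt, colors, noise_sd, rng), gt, colors, seed)


def write_scene(scene: SyntheticScene, out_dir, name: str) -> dict[str, Path]:
    """Materialise a scene as ``<name>.png`` + ``<name>_gt.csv``."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    img_path = out_dir / f"{name}.png"
    gt_path = out_dir / f"{name}_gt.csv"
    iio.imwrite(img_path, scene.rgb)
    np.savetxt(gt_path, scene.gt, delimiter=",", fmt="%d")
    return {"image": img_path, "gt": gt_path}


def standard_scenes(seed: int = 0) -> dict[str, SyntheticScene]:
    """The canonical test set used by the CLI's ``fixtures generate``."""
    return {
        "two_region": make_two_region(160, 160, noise_sd=2.0, seed=seed),
        "disk": make_disk(192, 192, radius=60.0, noise_sd=2.0, seed=seed + 1),
        "voronoi": make_voronoi_mosaic(192, 192, 5, noise_sd=2.0, seed=seed + 2),
    }
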