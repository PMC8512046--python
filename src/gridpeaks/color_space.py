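"""RGB <-> CIELAB conversion used by the segmentation pipeline.

The forward transform applies a fixed 3x3 RGB->XYZ matrix to channel values
normalised to [0, 1], followed by the standard CIE piecewise cube-root
mapping against the white point (0.9505, 1.0, 1.089).  By default no sRGB
gamma expansion is performed before the matrix (``linearize=False``); pass
``linearize=True`` for colorimetrically linearised input handling.
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)

#: Row-stochastic-to-white RGB->XYZ matrix (rows sum to the white point).
RGB_TO_XYZ = np.array(
    [
        [0.4124, 0.3576, 0.1805],
        [0.2126, 0.7152, 0.0722],
        [0.0193, 0.1192, 0.9505],
    ]
)

XYZ_TO_RGB = np.linalg.inv(RGB_TO_XYZ)

#: White point (Xn, Yn, Zn).
WHITE_POINT = np.array([0.9505, 1.0, 1.089])

_T0 = (6.0 / 29.0) ** 3
_SLOPE = 1.0 / (3.0 * (6.0 / 29.0) ** 2)
_OFFSET = 4.0 / 29.0


def validate_rgb(image: np.ndarray) -> np.ndarray:
    """Check an 8-bit RGB raster and return it as a float array.

    Raises
    ------
    ValueError
        If the array is not H x W x 3 or intensities leave [0, 255].
    """
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(
            f"expected an HxWx3 RGB image, got shape {arr.shape!r}"
        )
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError("image must have height >= 1 and width >= 1")
    values = arr.astype(np.float64)
    if np.any(values < 0) or np.any(values > 255) or not np.all(np.isfinite(values)):
        raise ValueError("RGB intensities must lie within [0, 255]")
    return values


def _f(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=np.float64)
    return np.where(t > _T0, np.cbrt(t), _SLOPE * t + _OFFSET)


def _f_inv(u: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=np.float64)
    return np.where(u > 6.0 / 29.0, u**3, (u - _OFFSET) / _SLOPE)


def srgb_linearize(c: np.ndarray) -> np.ndarray:
    """sRGB electro-optical transfer (gamma expansion) on [0, 1] values."""
    c = np.asarray(c, dtype=np.float64)
    return np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)


def srgb_delinearize(c: np.ndarray) -> np.ndarray:
    c = np.asarray(c, dtype=np.float64)
    c = np.clip(c, 0.0, 1.0)
    return np.where(c <= 0.0031308, 12.92 * c, 1.055 * c ** (1 / 2.4) - 0.055)


def rgb_to_lab(image: np.ndarray, *, linearize: bool = False) -> np.ndarray:
    """Convert an 8-bit RGB image to Lab.

    Parameters
    ----------
    image
        H x W x 3 array with intensities in [0, 255].
    linearize
        If True, apply sRGB gamma expansion before the XYZ matrix.

    Returns
    -------
    H x W x 3 float array with channels (L, a, b); L in [0, 100].
    """
    rgb = validate_rgb(image) / 255.0
    if linearize:
        rgb = srgb_linearize(rgb)
    xyz = rgb @ RGB_TO_XYZ.T
    fxyz = _f(xyz / WHITE_POINT)
    fx, fy, fz = fxyz[..., 0], fxyz[..., 1], fxyz[..., 2]
    lab = np.empty_like(xyz)
    lab[..., 0] = 116.0 * fy - 16.0
    lab[..., 1] = 500.0 * (fx - fy)
    lab[..., 2] = 200.0 * (fy - fz)
    return lab


def lab_to_rgb(lab: np.ndarray, *, delinearize: bool = False) -> np.ndarray:
    """Inverse of :func:`rgb_to_lab`, quantised to uint8.

    Out-of-gamut values are clipped to [0, 255].
    """
    lab = np.asarray(lab, dtype=np.float64)
    if lab.ndim != 3 or lab.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 Lab image, got shape {lab.shape!r}")
    fy = (lab[..., 0] + 16.0) / 116.0
    fx = fy + lab[..., 1] / 500.0
    fz = fy - lab[..., 2] / 200.0
    xyz = np.stack([_f_inv(fx), _f_inv(fy), _f_inv(fz)], axis=-1) * WHITE_POINT
    rgb = xyz @ XYZ_TO_RGB.T
    if delinearize:
        rgb = srgb_delinearize(rgb)
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)


def load_rgb(path) -> np.ndarray:
    """Read a PNG/JPEG file as an H x W x 3 uint8 array.

    Grayscale inputs are promoted to 3 channels by replication; an alpha
    channel, if present, is dropped.
    """
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 2:
        logger.info("promoting grayscale image %s to 3 channels", path)
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.shape[2] == 4:
        arr = arr[..., :3]
    if arr.dtype != np.uint8:
        raise ValueError(f"expected 8-bit image data in {path}, got {arr.dtype}")
    return arr
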