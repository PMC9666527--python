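"""Pixel-level primitives for vegetation segmentation.

Images are plain numpy arrays of unsigned-integer digital numbers, shaped
``(H, W, 3)`` for RGB or ``(H, W, 4)`` for RGBA, at 8- or 16-bit depth.
Scalar maps (e.g. the excess-green index) are float arrays of shape
``(H, W)``; binary masks are boolean arrays of the same shape.

The segmentation chain implemented here is

    RGB image --ExG--> scalar map --Otsu--> binary vegetation mask
              --alpha--> 4-band RGBA cut-out source

The excess green index ExG = (2g - r - b) / (r + g + b) is computed on raw
digital numbers and is therefore bit-depth invariant: high for green
vegetation, near or below zero for soil.
"""

from __future__ import annotations

import numpy as np
from skimage.filters import threshold_otsu

__all__ = [
    "full_scale",
    "validate_raster",
    "compute_exg",
    "otsu_threshold",
    "vegetation_mask",
    "attach_alpha",
]

_VALID_DTYPES = (np.uint8, np.uint16)


def full_scale(image: np.ndarray) -> int:
    """Maximum representable digital number for the image's bit depth."""
    return int(np.iinfo(image.dtype).max)


def validate_raster(image: np.ndarray, *, min_channels: int = 3) -> np.ndarray:
    """Check that *image* is a valid H x W x C unsigned-integer raster.

    Parameters
    ----------
    image : ndarray
        Candidate raster.
    min_channels : int
        Minimum number of channels required (3 for RGB operations).

    Returns
    -------
    ndarray
        The validated image, unchanged.

    Raises
    ------
    ValueError
        If the array is not 3-dimensional, has an unsupported channel
        count or dtype, or has a zero spatial extent.
    """
    arr = np.asarray(image)
    if arr.ndim != 3:
        raise ValueError(f"expected a (H, W, C) array, got shape {arr.shape}")
    h, w, c = arr.shape
    if h < 1 or w < 1:
        raise ValueError("image must have height >= 1 and width >= 1")
    if c not in (3, 4):
        raise ValueError(f"expected 3 or 4 channels, got {c}")
    if c < min_channels:
        raise ValueError(f"operation requires >= {min_channels} channels, got {c}")
    if arr.dtype.type not in _VALID_DTYPES:
        raise ValueError(f"expected uint8 or uint16 pixels, got dtype {arr.dtype}")
    return arr


def compute_exg(image: np.ndarray) -> np.ndarray:
    """Excess green index per pixel, (2g - r - b) / (r + g + b).

    Computed on raw digital numbers; pixels with r + g + b = 0 (pure
    black) are defined as 0, treating them like bareground. The result is
    algebraically bounded in [-1, 2].

    Parameters
    ----------
    image : ndarray, shape (H, W, 3) or (H, W, 4)
        RGB(A) raster; only the first three channels are used.

    Returns
    -------
    ndarray of float64, shape (H, W)
    """
    arr = validate_raster(image, min_channels=3)
    rgb = arr[..., :3].astype(np.float64)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    total = r + g + b
    num = 2.0 * g - r - b
    with np.errstate(divide="ignore", invalid="ignore"):
        exg = np.where(total > 0, num / np.where(total > 0, total, 1.0), 0.0)
    return exg


def otsu_threshold(scalar_map: np.ndarray, n_bins: int = 256) -> float:
    """Otsu threshold of a scalar map.

    Builds an ``n_bins`` histogram over the observed [min, max] range and
    returns the threshold maximizing the between-class variance.

    Raises
    ------
    ValueError
        If the map is constant (no class separation exists).
    """
    values = np.asarray(scalar_map, dtype=np.float64)
    if values.size == 0:
        raise ValueError("empty scalar map")
    if np.ptp(values) == 0:
        raise ValueError("constant scalar map: Otsu threshold is undefined")
    return float(threshold_otsu(values.ravel(), nbins=int(n_bins)))


def vegetation_mask(image: np.ndarray, n_bins: int = 256) -> np.ndarray:
    """Boolean vegetation mask: ExG above its per-image Otsu threshold.

    Raises
    ------
    ValueError
        If the image's ExG map is constant (e.g. an all-gray frame).
    """
    exg = compute_exg(image)
    t = otsu_threshold(exg, n_bins=n_bins)
    return exg > t


def attach_alpha(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Append an alpha channel: full-scale where *mask* is true, 0 elsewhere.

    RGB values are passed through unchanged; the output is a 4-band raster
    of the input's dtype.
    """
    arr = validate_raster(image, min_channels=3)
    m = np.asarray(mask)
    if m.shape != arr.shape[:2]:
        raise ValueError(
            f"mask extent {m.shape} does not match image extent {arr.shape[:2]}"
        )
    alpha = np.where(m, full_scale(arr), 0).astype(arr.dtype)
    return np.dstack([arr[..., :3], alpha])
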