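"""Image conditioning applied ahead of pose detection.

Four steps: brightening (gamma mapping), cropping to a region of interest,
denoising (box mean filter), and edge detection (Sobel gradient magnitude).
The simplest member of each named operator family is used; all are pure
functions on uint8 arrays.  Border handling is reflection everywhere.

Images are numpy arrays, H x W (grayscale) or H x W x 3 (color), values in
[0, 255]; every operation clips back to that range and never produces NaN.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import GericareError

__all__ = ["brighten", "crop", "denoise", "edge_detect", "to_grayscale"]


class ParameterError(GericareError, ValueError):
    pass


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim not in (2, 3) or image.shape[0] < 1 or image.shape[1] < 1:
        raise ParameterError(f"expected HxW or HxWx3 image, got shape {image.shape}")
    if image.ndim == 3 and image.shape[2] != 3:
        raise ParameterError(f"color image must have 3 channels, got {image.shape[2]}")
    return image


def _finish(image: np.ndarray) -> np.ndarray:
    return np.clip(np.nan_to_num(image), 0.0, 255.0).astype(np.uint8)


def brighten(image: np.ndarray, gamma: float) -> np.ndarray:
    """Gamma brightening: out = 255 * (in/255)**(1/gamma).  gamma > 1 brightens."""
    image = _check_image(image)
    if not gamma > 0:
        raise ParameterError(f"gamma must be positive, got {gamma}")
    out = 255.0 * (image.astype(float) / 255.0) ** (1.0 / gamma)
    return _finish(out)


def crop(image: np.ndarray, roi: tuple[int, int, int, int]) -> np.ndarray:
    """Crop to (x_min, y_min, x_max, y_max), half-open on the max edges."""
    image = _check_image(image)
    x_min, y_min, x_max, y_max = (int(v) for v in roi)
    h, w = image.shape[:2]
    if not (0 <= x_min < x_max <= w and 0 <= y_min < y_max <= h):
        raise ParameterError(f"roi {roi} degenerate or outside {w}x{h} image bounds")
    return image[y_min:y_max, x_min:x_max].copy()


def denoise(image: np.ndarray, kernel_size: int = 3) -> np.ndarray:
    """Box (mean) low-pass filter with reflective border; kernel 1 is identity."""
    image = _check_image(image)
    kernel_size = int(kernel_size)
    if kernel_size < 1 or kernel_size % 2 == 0:
        raise ParameterError(f"kernel_size must be odd and >= 1, got {kernel_size}")
    if kernel_size == 1:
        return image.astype(np.uint8).copy()
    size = (kernel_size, kernel_size) + (1,) * (image.ndim - 2)
    out = ndimage.uniform_filter(image.astype(float), size=size, mode="reflect")
    return _finish(out)


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Collapse a color image by channel-mean luminance; pass grayscale through."""
    image = _check_image(image)
    if image.ndim == 2:
        return image
    return image.astype(float).mean(axis=2)


def edge_detect(image: np.ndarray) -> np.ndarray:
    """Sobel 3x3 gradient-magnitude map, rescaled to [0, 255].

    Color inputs are first collapsed to luminance.  A constant image maps to
    all zeros.
    """
    gray = to_grayscale(_check_image(image)).astype(float)
    gx = ndimage.sobel(gray, axis=1, mode="reflect")
    gy = ndimage.sobel(gray, axis=0, mode="reflect")
    mag = np.hypot(gx, gy)
    peak = mag.max()
    if peak > 0:
        mag = mag * (255.0 / peak)
    return _finish(mag)
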