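"""Grayscale conversion and the Gaussian multi-scale image stack.

Every descriptor in this package starts from a 2D integer raster quantized
to ``n_levels`` gray levels (256 by default).  Multi-scale analysis smooths
the input with small symmetric Gaussian lowpass filters (kernel sizes 3 and
5, sigma 1) and extracts descriptors from the original image and each
smoothed version.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

N_GL_DEFAULT = 256

#: ITU-R BT.601 luminance weights used to collapse RGB to gray.
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class GrayImage:
    """A 2D integer raster with values in ``[0, n_levels - 1]``."""

    pixels: np.ndarray
    n_levels: int = N_GL_DEFAULT

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"expected a 2D raster, got ndim={px.ndim}")
        if px.shape[0] < 2 or px.shape[1] < 2:
            raise ValueError(
                f"image must be at least 2x2 (a co-occurrence matrix needs "
                f"at least one pixel pair), got {px.shape}"
            )
        if not np.issubdtype(px.dtype, np.integer):
            raise ValueError("pixel values must be integers")
        if px.min() < 0 or px.max() > self.n_levels - 1:
            raise ValueError(
                f"pixel values must lie in [0, {self.n_levels - 1}], got "
                f"range [{px.min()}, {px.max()}]"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class ScaleStack:
    """Ordered stack ``[original, smoothed_k3, smoothed_k5]``."""

    images: tuple
    kernel_sizes: tuple = (3, 5)
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if len(self.images) != 1 + len(self.kernel_sizes):
            raise ValueError("stack must hold the original plus one image per kernel size")
        dims = {(im.height, im.width) for im in self.images}
        if len(dims) != 1:
            raise ValueError("all stack members must share the original's dimensions")

    def __iter__(self):
        return iter(self.images)

    def __len__(self) -> int:
        return len(self.images)

    def __getitem__(self, i):
        return self.images[i]


def to_gray(image: np.ndarray, n_levels: int = N_GL_DEFAULT) -> GrayImage:
    """Convert a raster (grayscale or RGB, 8- or 16-bit) to a quantized GrayImage.

    RGB is collapsed by luminance weighting; the value range of the source
    bit depth is linearly rescaled to ``[0, n_levels - 1]`` and rounded.
    """
    arr = np.asarray(image)
    if arr.size == 0:
        raise ValueError("empty image")
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        if arr.shape[2] == 3:
            arr = arr.astype(np.float64) @ _LUMA_WEIGHTS
        elif arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            raise ValueError(f"unsupported channel count {arr.shape[2]}")
    elif arr.ndim != 2:
        raise ValueError(f"expected 2D or 3D raster, got ndim={arr.ndim}")
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError(f"image must be at least 2x2, got {arr.shape}")

    if np.issubdtype(np.asarray(image).dtype, np.integer):
        bits = np.asarray(image).dtype.itemsize * 8
        src_max = float(2**bits - 1)
    else:
        src_max = 255.0
    arr = arr.astype(np.float64)
    scaled = np.rint(arr * (n_levels - 1) / src_max)
    return GrayImage(np.clip(scaled, 0, n_levels - 1).astype(np.int64), n_levels)


def gaussian_kernel(size: int, sigma: float = 1.0) -> np.ndarray:
    """Discrete 2D Gaussian kernel of odd ``size``, normalized to unit sum."""
    if size < 1 or size % 2 == 0:
        raise ValueError("kernel size must be a positive odd integer")
    half = size // 2
    ax = np.arange(-half, half + 1, dtype=np.float64)
    g1 = np.exp(-(ax**2) / (2.0 * sigma**2))
    k = np.outer(g1, g1)
    return k / k.sum()


def smooth(img: GrayImage, size: int, sigma: float = 1.0) -> GrayImage:
    """Gaussian lowpass filter with edge replication, re-quantized to integers."""
    k = gaussian_kernel(size, sigma)
    out = ndimage.convolve(img.pixels.astype(np.float64), k, mode="nearest")
    out = np.clip(np.rint(out), 0, img.n_levels - 1).astype(np.int64)
    return GrayImage(out, img.n_levels)


def gaussian_stack(
    img: GrayImage, kernel_sizes: tuple = (3, 5), sigma: float = 1.0
) -> ScaleStack:
    """Build ``[original] + [smoothed at each kernel size]``."""
    images = (img,) + tuple(smooth(img, k, sigma) for k in kernel_sizes)
    return ScaleStack(images, tuple(kernel_sizes), sigma)


def load_image(path, n_levels: int = N_GL_DEFAULT) -> GrayImage:
    """Read a PNG/TIFF/BMP file and quantize to ``n_levels`` gray levels."""
    import imageio.v3 as iio

    return to_gray(iio.imread(path), n_levels)
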