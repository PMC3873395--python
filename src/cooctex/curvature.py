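"""Curvature histogram descriptor of the co-occurrence matrix level curves.

For level slices of the co-occurrence matrix at heights 1, 4, 7, 10, 13, a
circular mask of radius r is centered on every contour point of the main
blob and the fraction of blob pixels falling inside the mask is taken as an
area-ratio curvature estimate: about 0.5 on a straight edge, below 0.5 on
convex contours (0.25 at a right-angle corner), above 0.5 on concave ones.
Per level and radius the estimates over all contour points are quantized
into a histogram of equal-width bins on [0, 1], normalized to unit sum.

The radii set {3, 5, 7} and bin count 8 are package defaults chosen for the
256x256 matrix scale; both are configurable.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .glcm import DISTANCES, THETAS, CooccurrenceMatrix, GlcmSet, MatrixWindow, crop_window
from .shape import LevelSlice, level_slices

CURVATURE_HEIGHTS = tuple(range(1, 16, 3))  # 1, 4, 7, 10, 13
DEFAULT_RADII = (3, 5, 7)
DEFAULT_BINS = 8

_STRUCT4 = ndimage.generate_binary_structure(2, 1)


def contour_points(slice_: LevelSlice) -> np.ndarray:
    """(k, 2) array of main-blob boundary pixels.

    A boundary pixel is a blob pixel with at least one 4-neighbor outside
    the blob; pixels on the matrix border count as boundary.
    """
    blob = slice_.main_blob
    if not blob.any():
        return np.empty((0, 2), dtype=np.intp)
    interior = ndimage.binary_erosion(blob, structure=_STRUCT4, border_value=0)
    return np.argwhere(blob & ~interior)


def _disc_offsets(r: int) -> np.ndarray:
    if r < 1:
        raise ValueError("mask radius must be >= 1")
    rng = np.arange(-r, r + 1)
    dr, dc = np.meshgrid(rng, rng, indexing="ij")
    keep = dr**2 + dc**2 <= r**2
    return np.column_stack([dr[keep], dc[keep]])


def disc_area(r: int) -> int:
    return len(_disc_offsets(r))


def _contour_mask(blob: np.ndarray) -> np.ndarray:
    interior = ndimage.binary_erosion(blob, structure=_STRUCT4, border_value=0)
    return blob & ~interior


def _blob_weight(blob: np.ndarray) -> np.ndarray:
    """Blob pixels weighted 1, except boundary pixels weighted 1/2.

    The discrete contour is a width-1 approximation of the continuous
    boundary curve, which in the continuum splits the disc; half-weighting
    it removes the discretization bias that would otherwise push the
    straight-edge estimate above 0.5.
    """
    w = blob.astype(np.float64)
    w[_contour_mask(blob)] = 0.5
    return w


def curvature_measure(blob: np.ndarray, p: tuple, r: int) -> float:
    """Weighted fraction of disc(p, r) pixels that belong to the blob."""
    offs = _disc_offsets(r)
    pts = offs + np.asarray(p)
    h, w = blob.shape
    inb = (pts[:, 0] >= 0) & (pts[:, 0] < h) & (pts[:, 1] >= 0) & (pts[:, 1] < w)
    pts = pts[inb]
    weight = _blob_weight(blob)
    inside = weight[pts[:, 0], pts[:, 1]].sum()
    return float(inside) / len(offs)


def _curvatures_all_points(blob: np.ndarray, contour: np.ndarray, r: int) -> np.ndarray:
    """Area-ratio curvature at every contour point, via one disc convolution."""
    kernel = np.zeros((2 * r + 1, 2 * r + 1))
    offs = _disc_offsets(r)
    kernel[offs[:, 0] + r, offs[:, 1] + r] = 1.0
    cover = ndimage.convolve(_blob_weight(blob), kernel, mode="constant", cval=0.0)
    return cover[contour[:, 0], contour[:, 1]] / len(offs)


def curvature_histograms(
    m: CooccurrenceMatrix,
    heights: tuple = CURVATURE_HEIGHTS,
    radii: tuple = DEFAULT_RADII,
    n_bins: int = DEFAULT_BINS,
) -> np.ndarray:
    """Concatenated per-(level, radius) curvature histograms of one matrix.

    Length ``len(heights) * len(radii) * n_bins``; empty levels contribute
    all-zero histograms, non-empty ones sum to 1 per (level, radius).
    """
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    out = []
    for s in level_slices(m, heights):
        contour = contour_points(s)
        for r in radii:
            if len(contour) == 0:
                out.append(np.zeros(n_bins))
                continue
            curv = _curvatures_all_points(s.main_blob, contour, r)
            hist, _ = np.histogram(np.clip(curv, 0.0, 1.0), bins=edges)
            out.append(hist / hist.sum())
    return np.concatenate(out)


def cu_descriptor(
    s: GlcmSet,
    window: MatrixWindow | None = None,
    heights: tuple = CURVATURE_HEIGHTS,
    radii: tuple = DEFAULT_RADII,
    n_bins: int = DEFAULT_BINS,
    distances: tuple = DISTANCES,
    thetas: tuple = THETAS,
) -> np.ndarray:
    """Curvature histograms concatenated over levels, radii, theta, d.

    Length 5 * 3 * 8 * 4 * 2 = 960 at the defaults.
    """
    blocks = []
    for d in distances:
        for t in thetas:
            m = s[(d, t)]
            if window is not None:
                m = crop_window(m, window)
            blocks.append(curvature_histograms(m, heights, radii, n_bins))
    return np.concatenate(blocks)


def cu_feature_names(
    heights: tuple = CURVATURE_HEIGHTS,
    radii: tuple = DEFAULT_RADII,
    n_bins: int = DEFAULT_BINS,
    distances: tuple = DISTANCES,
    thetas: tuple = THETAS,
) -> list:
    return [
        f"cu_d{d}_t{t}_h{h}_r{r}_b{b}"
        for d in distances
        for t in thetas
        for h in heights
        for r in radii
        for b in range(n_bins)
    ]
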