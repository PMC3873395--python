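"""Level-curve SHAPE descriptor of the co-occurrence matrix.

The co-occurrence matrix is treated as a 3D surface and intersected with
horizontal planes at heights 1, 3, ..., 19 (the matrix is *not* normalized:
the low-height region is stable, while the peak region fluctuates with image
noise).  At each height the binary slice ``counts > h`` is decomposed into
8-connected blobs; the largest blob ("main blob") is approximated by its
moment-equivalent ellipse.  Nine summary features describe how the level
curves evolve with height:

1. slope of main-blob area vs. height (least squares over non-empty levels)
2. intercept of the same fit
3. mean eccentricity over non-empty levels
4. slope of eccentricity vs. height
5. circular mean of the ellipse orientation (axis-type angle, period pi)
6. total centroid path length across consecutive non-empty levels
7. number of non-empty levels
8. mean blob count per level
9. area ratio highest/lowest non-empty level (in (0, 1] by nesting)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .glcm import (
    DISTANCES,
    SHAPE_WINDOWS,
    THETAS,
    CooccurrenceMatrix,
    GlcmSet,
    MatrixWindow,
    crop_window,
)

SHAPE_HEIGHTS = tuple(range(1, 20, 2))  # 1, 3, ..., 19
N_EVOLUTION_FEATURES = 9

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class EllipseFit:
    """Moment-equivalent ellipse of a blob (axis lengths, not semi-axes)."""

    center: tuple
    major_axis: float
    minor_axis: float
    orientation: float
    area: int
    empty: bool = False

    @property
    def eccentricity(self) -> float:
        if self.major_axis <= 0:
            return 0.0
        return float(np.sqrt(max(0.0, 1.0 - (self.minor_axis / self.major_axis) ** 2)))


EMPTY_ELLIPSE = EllipseFit((0.0, 0.0), 0.0, 0.0, 0.0, 0, empty=True)


@dataclass(frozen=True)
class LevelSlice:
    height: int
    mask: np.ndarray
    n_blobs: int
    main_blob: np.ndarray  # boolean mask of the largest component (may be empty)

    @property
    def empty(self) -> bool:
        return self.n_blobs == 0


def _slice_at(counts: np.ndarray, h: int) -> LevelSlice:
    mask = counts > h
    labels, n = ndimage.label(mask, structure=_STRUCT8)
    if n == 0:
        return LevelSlice(h, mask, 0, np.zeros_like(mask))
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    # largest area; ties broken by the component containing the smallest
    # top-left (row-major) pixel, which is the lowest label index from
    # scipy's raster-order labeling
    best = int(np.argmax(areas)) + 1
    return LevelSlice(h, mask, n, labels == best)


def level_slices(
    m: CooccurrenceMatrix, heights: tuple = SHAPE_HEIGHTS
) -> list:
    """One LevelSlice per height, on the raw (unnormalized) counts."""
    return [_slice_at(m.counts, h) for h in heights]


def fit_ellipse(blob: np.ndarray) -> EllipseFit:
    """Moment-equivalent ellipse of a boolean blob mask.

    Computed from the covariance of the blob's pixel coordinates: axis
    lengths are 4*sqrt(eigenvalue) (a filled disc of radius R yields major ≈
    minor ≈ 2R) and the orientation is the angle of the major-axis
    eigenvector, measured from the row axis toward the column axis and
    mapped into [-pi/2, pi/2).
    """
    if not blob.any():
        return EMPTY_ELLIPSE
    pts = np.argwhere(blob).astype(np.float64)
    center = pts.mean(axis=0)
    if len(pts) == 1:
        return EllipseFit(tuple(center), 0.0, 0.0, 0.0, 1)
    cov = np.cov(pts.T, bias=True)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    evals = np.maximum(evals, 0.0)
    major, minor = 4.0 * np.sqrt(evals[1]), 4.0 * np.sqrt(evals[0])
    v = evecs[:, 1]  # (row, col) direction of the major axis
    ang = np.arctan2(v[1], v[0])
    if ang >= np.pi / 2:
        ang -= np.pi
    elif ang < -np.pi / 2:
        ang += np.pi
    return EllipseFit(tuple(center), float(major), float(minor), float(ang), len(pts))


def _circular_mean_axis(angles: np.ndarray) -> float:
    """Mean of axis-type angles (period pi) via angle doubling."""
    s = np.sin(2 * angles).mean()
    c = np.cos(2 * angles).mean()
    if s == 0 and c == 0:
        return 0.0
    return float(np.arctan2(s, c) / 2.0)


def evolution_features(slices: list) -> np.ndarray:
    """Nine deterministic summaries of the per-level ellipse series.

    All-empty input yields the all-zero vector.
    """
    if not slices:
        raise ValueError("need at least one level slice")
    fits = [fit_ellipse(s.main_blob) if not s.empty else EMPTY_ELLIPSE for s in slices]
    heights = np.array([s.height for s in slices], dtype=np.float64)
    nonempty = np.array([not f.empty for f in fits])
    if not nonempty.any():
        return np.zeros(N_EVOLUTION_FEATURES)

    h_ne = heights[nonempty]
    areas = np.array([f.area for f in fits], dtype=np.float64)[nonempty]
    eccs = np.array([f.eccentricity for f in fits])[nonempty]
    orients = np.array([f.orientation for f in fits])[nonempty]
    centers = np.array([f.center for f in fits])[nonempty]

    if h_ne.size >= 2:
        area_slope, area_icpt = np.polyfit(h_ne, areas, 1)
        ecc_slope = np.polyfit(h_ne, eccs, 1)[0]
    else:
        area_slope, area_icpt, ecc_slope = 0.0, float(areas[0]), 0.0

    path = float(np.linalg.norm(np.diff(centers, axis=0), axis=1).sum()) if len(centers) > 1 else 0.0
    n_blobs_mean = float(np.mean([s.n_blobs for s in slices]))
    area_ratio = float(areas[-1] / areas[0]) if areas[0] > 0 else 0.0

    return np.array(
        [
            float(area_slope),
            float(area_icpt),
            float(eccs.mean()),
            float(ecc_slope),
            _circular_mean_axis(orients),
            path,
            float(nonempty.sum()),
            n_blobs_mean,
            area_ratio,
        ]
    )


def shape_features(m: CooccurrenceMatrix, heights: tuple = SHAPE_HEIGHTS) -> np.ndarray:
    """Nine evolution features of one (possibly cropped) matrix."""
    return evolution_features(level_slices(m, heights))


def sh_descriptor(
    s: GlcmSet,
    window: MatrixWindow | None = None,
    heights: tuple = SHAPE_HEIGHTS,
    distances: tuple = DISTANCES,
    thetas: tuple = THETAS,
) -> np.ndarray:
    """SHAPE features of one window, concatenated over all (d, theta).

    Length 9 * 2 * 4 = 72 at the defaults.  Each of the 13 windows (whole
    matrix plus the 12 printed subwindows) feeds a separate classifier in
    the SHsub/SHsca ensembles.
    """
    blocks = []
    for d in distances:
        for t in thetas:
            m = s[(d, t)]
            if window is not None:
                m = crop_window(m, window)
            blocks.append(shape_features(m, heights))
    return np.concatenate(blocks)


def sh_all_windows(s: GlcmSet, heights: tuple = SHAPE_HEIGHTS) -> dict:
    """The 13 per-window SHAPE descriptors: whole + 12 subwindows."""
    out = {"whole": sh_descriptor(s, None, heights)}
    for w in SHAPE_WINDOWS:
        out[w.label] = sh_descriptor(s, w, heights)
    return out


def sh_feature_names(distances: tuple = DISTANCES, thetas: tuple = THETAS) -> list:
    return [
        f"sh_d{d}_t{t}_f{k}"
        for d in distances
        for t in thetas
        for k in range(1, N_EVOLUTION_FEATURES + 1)
    ]
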