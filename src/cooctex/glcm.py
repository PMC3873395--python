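"""Gray-level co-occurrence matrices (GLCM / GLDM) and matrix subwindows.

The co-occurrence matrix is an ``N_GL x N_GL`` histogram counting gray-level
transitions between pixel pairs at displacement ``(d, theta)``.  Four
orientations are used — horizontal (0°), right-down diagonal (45°), vertical
(90°) and left-down diagonal (135°) — with distances d = 1 and d = 3.
Accumulation is symmetric: each pixel pair is counted in both orders, so the
matrix is symmetric and its total equals twice the number of valid pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .multiscale import GrayImage

THETAS = (0, 45, 90, 135)
DISTANCES = (1, 3)

#: (row, col) displacement per orientation, for unit distance.
_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass(frozen=True)
class CooccurrenceMatrix:
    counts: np.ndarray
    d: int
    theta: int
    source_dims: tuple

    @property
    def n_levels(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class MatrixWindow:
    """Inclusive rectangular window on the co-occurrence matrix."""

    origin: tuple
    corner: tuple
    label: str = ""

    def __post_init__(self) -> None:
        if self.origin[0] > self.corner[0] or self.origin[1] > self.corner[1]:
            raise ValueError(f"window origin {self.origin} exceeds corner {self.corner}")
        if min(self.origin) < 0:
            raise ValueError("window origin out of bounds")

    @property
    def shape(self) -> tuple:
        return (self.corner[0] - self.origin[0] + 1, self.corner[1] - self.origin[1] + 1)


#: Whole 256x256 matrix.
WINDOW_WHOLE = MatrixWindow((0, 0), (255, 255), "whole")

#: The four 128x128 quadrant subwindows used by the *sub variants of the
#: Haralick, run-length, curvature and subspace descriptors.
QUADRANT_WINDOWS = (
    MatrixWindow((0, 0), (127, 127), "q1"),
    MatrixWindow((128, 128), (255, 255), "q2"),
    MatrixWindow((128, 0), (255, 127), "q3"),
    MatrixWindow((0, 128), (127, 255), "q4"),
)

#: The 12 subwindows used by the level-curve SHAPE descriptor.
SHAPE_WINDOWS = tuple(
    MatrixWindow(o, c, f"s{i + 1}")
    for i, (o, c) in enumerate(
        [
            ((0, 0), (127, 127)),
            ((128, 128), (255, 255)),
            ((0, 0), (191, 191)),
            ((64, 64), (255, 255)),
            ((0, 0), (95, 95)),
            ((31, 31), (95, 95)),
            ((63, 63), (127, 127)),
            ((95, 95), (159, 159)),
            ((127, 127), (191, 191)),
            ((159, 159), (223, 223)),
            ((191, 191), (255, 255)),
            ((63, 63), (191, 191)),
        ]
    )
)


def compute_glcm(img: GrayImage, d: int, theta: int) -> CooccurrenceMatrix:
    """Symmetric co-occurrence matrix at displacement distance ``d``, angle ``theta``.

    Offsets (row, col): 0° -> (0, +d); 45° -> (-d, +d); 90° -> (-d, 0);
    135° -> (-d, -d).  Each in-bounds pair (p, q) increments both
    ``counts[v(p), v(q)]`` and ``counts[v(q), v(p)]``.
    """
    if d < 1:
        raise ValueError("displacement distance must be >= 1")
    if theta not in _OFFSETS:
        raise ValueError(f"theta must be one of {THETAS}, got {theta}")
    dr, dc = (_OFFSETS[theta][0] * d, _OFFSETS[theta][1] * d)
    px = img.pixels
    h, w = px.shape
    # slice the image into the pair of co-displaced views
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r1 <= r0 or c1 <= c0:
        raise ValueError(f"no valid pixel pairs at d={d}, theta={theta} for shape {px.shape}")
    a = px[r0:r1, c0:c1].ravel()
    b = px[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
    n = img.n_levels
    counts = np.bincount(a * n + b, minlength=n * n).reshape(n, n)
    counts = counts + counts.T
    return CooccurrenceMatrix(counts.astype(np.int64), d, theta, (h, w))


@dataclass(frozen=True)
class GlcmSet:
    """The 8 co-occurrence matrices of one image: d in {1,3} x four orientations."""

    matrices: dict

    def __post_init__(self) -> None:
        n_levels = {m.n_levels for m in self.matrices.values()}
        if len(n_levels) != 1:
            raise ValueError("all matrices must share the same number of gray levels")

    def __getitem__(self, key) -> CooccurrenceMatrix:
        return self.matrices[key]

    def keys(self):
        return self.matrices.keys()

    def values(self):
        return self.matrices.values()

    def items(self):
        return self.matrices.items()


def glcm_set(
    img: GrayImage, distances: tuple = DISTANCES, thetas: tuple = THETAS
) -> GlcmSet:
    """All (d, theta) co-occurrence matrices, d-major / theta-minor order."""
    return GlcmSet(
        {(d, t): compute_glcm(img, d, t) for d in distances for t in thetas}
    )


def crop_window(m: CooccurrenceMatrix, w: MatrixWindow) -> CooccurrenceMatrix:
    """Inclusive submatrix of the counts; no renormalization."""
    n = m.n_levels
    if w.corner[0] >= n or w.corner[1] >= n:
        raise ValueError(f"window {w.origin}-{w.corner} exceeds matrix size {n}")
    sub = m.counts[w.origin[0] : w.corner[0] + 1, w.origin[1] : w.corner[1] + 1]
    return CooccurrenceMatrix(sub.copy(), m.d, m.theta, m.source_dims)


def save_glcm_csv(m: CooccurrenceMatrix, path) -> None:
    np.savetxt(path, m.counts, fmt="%d", delimiter=",")


def load_glcm_csv(path, d: int = 1, theta: int = 0) -> CooccurrenceMatrix:
    counts = np.loadtxt(path, delimiter=",", dtype=np.int64)
    return CooccurrenceMatrix(counts, d, theta, (0, 0))
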