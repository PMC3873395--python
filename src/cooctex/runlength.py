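"""Gray-level run-length features evaluated on the co-occurrence matrix.

A gray-level run is a maximal set of consecutive equal-valued pixels along a
scan direction; the run-length matrix p(i, j) counts runs of level i and
length j.  Here the "image" the runs are extracted from is the co-occurrence
matrix itself: its heavy-tailed bin counts are first log-compressed to a
small number of gray levels (16 by default), then runs are enumerated along
the four directions theta_GL in {0°, 45°, 90°, 135°} and summarized by the
eleven classical indicators SRE, LRE, GLN, RLN, RP, LGRE, HGRE, SRLGE,
SRHGE, LRLGE, LRHGE.

Gray levels are indexed from 0, so the low/high gray-level emphasis families
weight by (i + 1) to avoid dividing by zero at level 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .glcm import DISTANCES, THETAS, CooccurrenceMatrix, GlcmSet, MatrixWindow, crop_window
from .multiscale import GrayImage

RL_STAT_NAMES = (
    "SRE",
    "LRE",
    "GLN",
    "RLN",
    "RP",
    "LGRE",
    "HGRE",
    "SRLGE",
    "SRHGE",
    "LRLGE",
    "LRHGE",
)

RL_THETAS = (0, 45, 90, 135)
DEFAULT_RL_LEVELS = 16


@dataclass(frozen=True)
class RunLengthMatrix:
    """p[i, j-1] = number of runs of gray level i and length j (j >= 1)."""

    p: np.ndarray
    theta_gl: int
    n_p: int

    @property
    def n_r(self) -> int:
        return int(self.p.sum())


def quantize_glcm(m: CooccurrenceMatrix, n_levels: int = DEFAULT_RL_LEVELS) -> GrayImage:
    """Log-compress co-occurrence counts to an ``n_levels``-level image.

    c -> floor(n_levels * log(1+c) / log(1+max_count)), clipped to
    [0, n_levels-1]; an all-zero matrix maps to the all-zero image.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    c = m.counts.astype(np.float64)
    cmax = c.max()
    if cmax <= 0:
        q = np.zeros_like(c, dtype=np.int64)
    else:
        q = np.floor(n_levels * np.log1p(c) / np.log1p(cmax)).astype(np.int64)
        q = np.clip(q, 0, n_levels - 1)
    return GrayImage(q, n_levels)


def _lines(px: np.ndarray, theta_gl: int) -> list:
    """The scan lines of the image along one run direction.

    0° scans rows left-to-right, 90° scans columns, 45° scans anti-diagonals
    (bottom-left to top-right) and 135° scans main diagonals; length-1 corner
    diagonals are included.
    """
    h, w = px.shape
    if theta_gl == 0:
        return [px[r, :] for r in range(h)]
    if theta_gl == 90:
        return [px[:, c] for c in range(w)]
    if theta_gl == 135:
        return [px.diagonal(k) for k in range(-(h - 1), w)]
    if theta_gl == 45:
        f = np.flipud(px)
        return [f.diagonal(k) for k in range(-(h - 1), w)]
    raise ValueError(f"theta_gl must be one of {RL_THETAS}, got {theta_gl}")


def runlength_matrix(img: GrayImage, theta_gl: int) -> RunLengthMatrix:
    """Enumerate maximal runs along every line in direction ``theta_gl``."""
    px = img.pixels
    lines = _lines(px, theta_gl)
    # join all lines with a -1 separator so one pass finds every run
    sep = np.full(1, -1, dtype=np.int64)
    joined = np.concatenate([part for line in lines for part in (line.astype(np.int64), sep)])
    change = np.flatnonzero(np.diff(joined) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change, [joined.size - 1]))
    values = joined[starts]
    lengths = ends - starts + 1
    keep = values >= 0
    values, lengths = values[keep], lengths[keep]

    max_len = max(px.shape)
    p = np.zeros((img.n_levels, max_len), dtype=np.int64)
    np.add.at(p, (values, lengths - 1), 1)
    return RunLengthMatrix(p, theta_gl, n_p=px.size)


def rl_indicators(P: RunLengthMatrix) -> np.ndarray:
    """The 11 run-length indicators of one run-length matrix."""
    n_r = P.n_r
    if n_r <= 0:
        raise ValueError("empty run-length matrix")
    p = P.p.astype(np.float64)
    n_levels, max_len = p.shape
    j = np.arange(1, max_len + 1, dtype=np.float64)
    g = np.arange(1, n_levels + 1, dtype=np.float64)  # level index + 1

    run_j = p.sum(axis=0)  # runs per length
    run_g = p.sum(axis=1)  # runs per level

    sre = float((run_j / j**2).sum() / n_r)
    lre = float((run_j * j**2).sum() / n_r)
    gln = float((run_g**2).sum() / n_r)
    rln = float((run_j**2).sum() / n_r)
    rp = float(n_r / P.n_p)
    lgre = float((run_g / g**2).sum() / n_r)
    hgre = float((run_g * g**2).sum() / n_r)
    srlge = float(((p / g[:, None] ** 2) / j[None, :] ** 2).sum() / n_r)
    srhge = float(((p * g[:, None] ** 2) / j[None, :] ** 2).sum() / n_r)
    lrlge = float(((p / g[:, None] ** 2) * j[None, :] ** 2).sum() / n_r)
    lrhge = float(((p * g[:, None] ** 2) * j[None, :] ** 2).sum() / n_r)

    return np.array(
        [sre, lre, gln, rln, rp, lgre, hgre, srlge, srhge, lrlge, lrhge]
    )


def gl_descriptor(
    s: GlcmSet,
    window: MatrixWindow | None = None,
    n_levels: int = DEFAULT_RL_LEVELS,
    distances: tuple = DISTANCES,
    thetas: tuple = THETAS,
    rl_thetas: tuple = RL_THETAS,
) -> np.ndarray:
    """Run-length indicators of every (d, theta) matrix along every run direction.

    Concatenation is d-major, theta, then theta_GL; at the defaults the
    descriptor has length 11 * 2 * 4 * 4 = 352.
    """
    blocks = []
    for d in distances:
        for t in thetas:
            m = s[(d, t)]
            if window is not None:
                m = crop_window(m, window)
            q = quantize_glcm(m, n_levels)
            for tg in rl_thetas:
                blocks.append(rl_indicators(runlength_matrix(q, tg)))
    return np.concatenate(blocks)


def gl_feature_names(
    distances: tuple = DISTANCES, thetas: tuple = THETAS, rl_thetas: tuple = RL_THETAS
) -> list:
    return [
        f"gl_d{d}_t{t}_r{tg}_{stat}"
        for d in distances
        for t in thetas
        for tg in rl_thetas
        for stat in RL_STAT_NAMES
    ]
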