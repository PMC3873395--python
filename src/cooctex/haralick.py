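"""The 13 Haralick statistics of a co-occurrence matrix.

The matrix is normalized to a joint probability table p(i, j) and summarized
by thirteen scalar statistics: energy, correlation, inertia (contrast),
entropy, inverse difference moment, sum average, sum variance, sum entropy,
difference average, difference variance, difference entropy, and the two
information measures of correlation.  Sum and difference statistics are
evaluated on the distributions of i + j and |i - j|.  Logarithms are base 2
with the 0*log(0) := 0 convention.

Notes on the ambiguous definitions:

* *Sum variance* is the variance of the i + j distribution about the sum
  average (not about the sum entropy, which appears in some transcriptions
  of the original formulas but is dimensionally inconsistent).
* *Difference variance* is the variance of the |i - j| distribution about
  the difference average.
* Degenerate matrices with zero marginal variance return correlation = 0 and
  IMC1 = 0 (with a warning) so that subwindow pipelines stay total.
"""

from __future__ import annotations

import warnings

import numpy as np

from .glcm import DISTANCES, THETAS, CooccurrenceMatrix, GlcmSet, MatrixWindow, crop_window

STAT_NAMES = (
    "energy",
    "correlation",
    "inertia",
    "entropy",
    "inverse_difference_moment",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "difference_average",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
)

N_STATS = len(STAT_NAMES)


def _entropy(p: np.ndarray) -> float:
    """Shannon entropy in bits with 0*log2(0) := 0."""
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def haralick_13(m: CooccurrenceMatrix) -> np.ndarray:
    """The 13 statistics of one co-occurrence matrix, in canonical order.

    Raises ``ValueError`` on an all-zero matrix (the joint distribution is
    undefined).
    """
    total = m.counts.sum()
    if total <= 0:
        raise ValueError("empty co-occurrence matrix: statistics undefined")
    p = m.counts.astype(np.float64) / total
    n = p.shape[0]
    i = np.arange(n, dtype=np.float64)

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(i @ px)
    mu_y = float(i @ py)
    var_x = float(((i - mu_x) ** 2) @ px)
    var_y = float(((i - mu_y) ** 2) @ py)

    ii, jj = np.meshgrid(i, i, indexing="ij")

    # distribution of i + j over 2n-1 values, and of |i - j| over n values
    sums = (ii + jj).astype(np.intp)
    diffs = np.abs(ii - jj).astype(np.intp)
    p_sum = np.bincount(sums.ravel(), weights=p.ravel(), minlength=2 * n - 1)
    p_diff = np.bincount(diffs.ravel(), weights=p.ravel(), minlength=n)
    k_sum = np.arange(2 * n - 1, dtype=np.float64)
    k_diff = np.arange(n, dtype=np.float64)

    energy = float((p**2).sum())
    inertia = float(((ii - jj) ** 2 * p).sum())
    entropy = _entropy(p.ravel())
    idm = float((p / (1.0 + (ii - jj) ** 2)).sum())

    if var_x > 0 and var_y > 0:
        correlation = float(((ii * jj * p).sum() - mu_x * mu_y) / np.sqrt(var_x * var_y))
    else:
        warnings.warn("degenerate matrix (zero marginal variance): correlation set to 0")
        correlation = 0.0

    sum_avg = float(k_sum @ p_sum)
    sum_var = float(((k_sum - sum_avg) ** 2) @ p_sum)
    sum_ent = _entropy(p_sum)

    diff_avg = float(k_diff @ p_diff)
    diff_var = float(((k_diff - diff_avg) ** 2) @ p_diff)
    diff_ent = _entropy(p_diff)

    hx = _entropy(px)
    hy = _entropy(py)
    hxy = entropy
    # cross entropies against the independent product distribution
    pxy = np.outer(px, py)
    mask = (p > 0) & (pxy > 0)
    hxy1 = float(-(p[mask] * np.log2(pxy[mask])).sum())
    mask2 = pxy > 0
    hxy2 = float(-(pxy[mask2] * np.log2(pxy[mask2])).sum())
    if max(hx, hy) > 0:
        imc1 = (hxy - hxy1) / max(hx, hy)
    else:
        warnings.warn("degenerate matrix (zero marginal entropy): IMC1 set to 0")
        imc1 = 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    return np.array(
        [
            energy,
            correlation,
            inertia,
            entropy,
            idm,
            sum_avg,
            sum_var,
            sum_ent,
            diff_avg,
            diff_var,
            diff_ent,
            imc1,
            imc2,
        ]
    )


def har_descriptor(
    s: GlcmSet,
    window: MatrixWindow | None = None,
    distances: tuple = DISTANCES,
    thetas: tuple = THETAS,
) -> np.ndarray:
    """Concatenated 13-statistic blocks over all (d, theta), d-major order.

    With the default two distances and four orientations the descriptor has
    length 104.  A window with zero total count contributes an all-zero
    13-block (with a warning) rather than aborting.
    """
    blocks = []
    for d in distances:
        for t in thetas:
            m = s[(d, t)]
            if window is not None:
                m = crop_window(m, window)
            if m.total == 0:
                warnings.warn(
                    f"window {getattr(window, 'label', '?')} of (d={d}, theta={t}) "
                    "matrix is empty; features set to zeros"
                )
                blocks.append(np.zeros(N_STATS))
            else:
                blocks.append(haralick_13(m))
    return np.concatenate(blocks)


def har_feature_names(distances: tuple = DISTANCES, thetas: tuple = THETAS) -> list:
    return [
        f"har_d{d}_t{t}_{stat}" for d in distances for t in thetas for stat in STAT_NAMES
    ]
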