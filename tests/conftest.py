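"""Shared fixtures and independent brute-force oracles.

The oracles here re-derive each quantity from its definition with explicit
loops, independently of the library's vectorized implementations.
"""

from __future__ import annotations

import numpy as np
import pytest

from cooctex import CooccurrenceMatrix, GrayImage

# ---------------------------------------------------------------------------
# oracles


def glcm_oracle(pixels: np.ndarray, d: int, theta: int, n_levels: int = 256) -> np.ndarray:
    """Naive O(HW) pair enumeration with symmetric accumulation."""
    offsets = {0: (0, d), 45: (-d, d), 90: (-d, 0), 135: (-d, -d)}
    dr, dc = offsets[theta]
    h, w = pixels.shape
    counts = np.zeros((n_levels, n_levels), dtype=np.int64)
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                a, b = pixels[r, c], pixels[r2, c2]
                counts[a, b] += 1
                counts[b, a] += 1
    return counts


def haralick_oracle(counts: np.ndarray) -> np.ndarray:
    """Literal transcription of the 13 statistics with explicit loops."""
    n = counts.shape[0]
    p = counts.astype(float) / counts.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = sum(i * px[i] for i in range(n))
    mu_y = sum(j * py[j] for j in range(n))
    sx = np.sqrt(sum((i - mu_x) ** 2 * px[i] for i in range(n)))
    sy = np.sqrt(sum((j - mu_y) ** 2 * py[j] for j in range(n)))

    p_sum = np.zeros(2 * n - 1)
    p_diff = np.zeros(n)
    for i in range(n):
        for j in range(n):
            p_sum[i + j] += p[i, j]
            p_diff[abs(i - j)] += p[i, j]

    def ent(q):
        return -sum(v * np.log2(v) for v in np.ravel(q) if v > 0)

    energy = (p**2).sum()
    if sx > 0 and sy > 0:
        corr = sum(
            (i - mu_x) * (j - mu_y) * p[i, j] for i in range(n) for j in range(n)
        ) / (sx * sy)
    else:
        corr = 0.0
    inertia = sum((i - j) ** 2 * p[i, j] for i in range(n) for j in range(n))
    entropy = ent(p)
    idm = sum(p[i, j] / (1 + (i - j) ** 2) for i in range(n) for j in range(n))
    sum_avg = sum(k * p_sum[k] for k in range(2 * n - 1))
    sum_var = sum((k - sum_avg) ** 2 * p_sum[k] for k in range(2 * n - 1))
    sum_ent = ent(p_sum)
    diff_avg = sum(k * p_diff[k] for k in range(n))
    diff_var = sum((k - diff_avg) ** 2 * p_diff[k] for k in range(n))
    diff_ent = ent(p_diff)
    hx, hy, hxy = ent(px), ent(py), entropy
    hxy1 = -sum(
        p[i, j] * np.log2(px[i] * py[j])
        for i in range(n)
        for j in range(n)
        if p[i, j] > 0 and px[i] * py[j] > 0
    )
    hxy2 = -sum(
        px[i] * py[j] * np.log2(px[i] * py[j])
        for i in range(n)
        for j in range(n)
        if px[i] * py[j] > 0
    )
    imc1 = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = np.sqrt(max(0.0, 1 - np.exp(-2 * (hxy2 - hxy))))
    return np.array(
        [energy, corr, inertia, entropy, idm, sum_avg, sum_var, sum_ent,
         diff_avg, diff_var, diff_ent, imc1, imc2]
    )


def runs_oracle(pixels: np.ndarray, theta_gl: int):
    """All maximal runs (level, length) along direction theta_gl, by scanning."""
    h, w = pixels.shape
    lines = []
    if theta_gl == 0:
        lines = [pixels[r, :].tolist() for r in range(h)]
    elif theta_gl == 90:
        lines = [pixels[:, c].tolist() for c in range(w)]
    elif theta_gl == 135:
        for k in range(-(h - 1), w):
            lines.append([pixels[i, i + k] for i in range(h) if 0 <= i + k < w])
    elif theta_gl == 45:
        for k in range(h + w - 1):  # anti-diagonals r + c = k
            lines.append([pixels[r, k - r] for r in range(h) if 0 <= k - r < w])
    runs = []
    for line in lines:
        i = 0
        while i < len(line):
            j = i
            while j + 1 < len(line) and line[j + 1] == line[i]:
                j += 1
            runs.append((line[i], j - i + 1))
            i = j + 1
    return runs


def rl_indicators_oracle(runs, n_pixels: int) -> np.ndarray:
    """The 11 run-length indicators from the raw run list, literal formulas."""
    n_r = len(runs)
    sre = sum(1.0 / L**2 for _, L in runs) / n_r
    lre = sum(float(L**2) for _, L in runs) / n_r
    levels = sorted({g for g, _ in runs})
    gln = sum(sum(1 for g2, _ in runs if g2 == g) ** 2 for g in levels) / n_r
    lens = sorted({L for _, L in runs})
    rln = sum(sum(1 for _, L2 in runs if L2 == L) ** 2 for L in lens) / n_r
    rp = n_r / n_pixels
    lgre = sum(1.0 / (g + 1) ** 2 for g, _ in runs) / n_r
    hgre = sum(float((g + 1) ** 2) for g, _ in runs) / n_r
    srlge = sum(1.0 / ((g + 1) ** 2 * L**2) for g, L in runs) / n_r
    srhge = sum((g + 1) ** 2 / L**2 for g, L in runs) / n_r
    lrlge = sum(L**2 / (g + 1) ** 2 for g, L in runs) / n_r
    lrhge = sum(float((g + 1) ** 2 * L**2) for g, L in runs) / n_r
    return np.array([sre, lre, gln, rln, rp, lgre, hgre, srlge, srhge, lrlge, lrhge])


def auc_concordance_oracle(scores: np.ndarray, labels: np.ndarray) -> float:
    """One-vs-all AUC by counting concordant pairs (ties = 0.5), averaged."""
    classes = np.unique(labels)
    aucs = []
    for k, c in enumerate(classes):
        pos = scores[labels == c, k]
        neg = scores[labels != c, k]
        if len(pos) == 0 or len(neg) == 0:
            continue
        conc = 0.0
        for sp in pos:
            for sn in neg:
                conc += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
        aucs.append(conc / (len(pos) * len(neg)))
    return float(np.mean(aucs))


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def random_small_image(rng):
    return GrayImage(rng.integers(0, 256, size=(16, 16)), 256)


def random_matrix(rng, n: int = 8, scale: int = 20) -> CooccurrenceMatrix:
    c = rng.integers(0, scale, size=(n, n))
    c = c + c.T  # symmetric, like a real co-occurrence matrix
    return CooccurrenceMatrix(c.astype(np.int64), 1, 0, (0, 0))
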