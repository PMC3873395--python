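"""Synthetic labeled texture images and analytic co-occurrence fixtures.

These generators stand in for real image collections so the whole pipeline
is testable offline.  The workhorse is the separable first-order
autoregressive (AR(1)) random field: its lag-1 autocorrelation ``rho``
directly controls the diagonal concentration of the co-occurrence matrix,
so classes with different ``rho`` are separable by construction and the
expected Haralick correlation is known analytically (≈ rho at unit lag).

``make_gaussian_bump_matrix`` builds a co-occurrence-matrix-shaped Gaussian
bump whose level-set ellipses are known in closed form, providing an exact
oracle for the level-curve SHAPE features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .glcm import CooccurrenceMatrix
from .multiscale import N_GL_DEFAULT, GrayImage

GENERATORS = ("constant", "stripes", "checkerboard", "correlated_noise", "blob_field")


@dataclass(frozen=True)
class TextureSpec:
    """Deterministic recipe for one texture image (same spec+seed → same image)."""

    generator: str
    size: tuple = (64, 64)
    n_levels: int = N_GL_DEFAULT
    level: int = 128           # constant
    period: int = 4            # stripes
    orientation: str = "v"     # stripes: "v" | "h"
    cell: int = 4              # checkerboard
    rho: float = 0.5           # correlated_noise, in [0, 1)
    density: float = 0.02      # blob_field
    radius: int = 3            # blob_field
    seed: int = 0

    def __post_init__(self) -> None:
        if self.generator not in GENERATORS:
            raise ValueError(f"unknown generator {self.generator!r}")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError(f"rho must lie in [0, 1), got {self.rho}")


def _ar1_field(shape: tuple, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Separable AR(1) Gaussian field with lag-1 autocorrelation rho per axis."""
    z = rng.standard_normal(shape)
    if rho > 0:
        # IIR filter x[n] = rho*x[n-1] + z[n] along rows then columns
        z = signal.lfilter([1.0], [1.0, -rho], z, axis=0)
        z = signal.lfilter([1.0], [1.0, -rho], z, axis=1)
    return z


def _quantize_field(z: np.ndarray, n_levels: int) -> np.ndarray:
    """Standardize and clip at ±3 sigma, then map linearly to gray levels."""
    z = (z - z.mean()) / (z.std() + 1e-12)
    z = np.clip(z, -3.0, 3.0)
    return np.rint((z + 3.0) / 6.0 * (n_levels - 1)).astype(np.int64)


def make_image(spec: TextureSpec) -> GrayImage:
    """Render one deterministic texture image from its spec."""
    h, w = spec.size
    rng = np.random.default_rng(spec.seed)
    g = spec.generator
    if g == "constant":
        px = np.full((h, w), spec.level, dtype=np.int64)
    elif g == "stripes":
        idx = np.arange(w) if spec.orientation == "v" else np.arange(h)
        line = ((idx // spec.period) % 2) * (spec.n_levels - 1)
        px = np.tile(line, (h, 1)) if spec.orientation == "v" else np.tile(line[:, None], (1, w))
        px = px.astype(np.int64)
    elif g == "checkerboard":
        r, c = np.meshgrid(np.arange(h) // spec.cell, np.arange(w) // spec.cell, indexing="ij")
        px = (((r + c) % 2) * (spec.n_levels - 1)).astype(np.int64)
    elif g == "correlated_noise":
        px = _quantize_field(_ar1_field((h, w), spec.rho, rng), spec.n_levels)
    elif g == "blob_field":
        px = np.zeros((h, w))
        n_blobs = max(1, int(spec.density * h * w))
        rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        for _ in range(n_blobs):
            cy, cx = rng.integers(0, h), rng.integers(0, w)
            px += np.exp(-((rr - cy) ** 2 + (cc - cx) ** 2) / (2.0 * spec.radius**2))
        px = _quantize_field(px, spec.n_levels)
    return GrayImage(px, spec.n_levels)


@dataclass(frozen=True)
class LabeledImageSet:
    images: tuple
    labels: np.ndarray
    specs: tuple


def make_dataset(n_per_class: int, class_specs: list, seed: int = 0) -> LabeledImageSet:
    """Balanced labeled image set; every image gets a distinct derived seed.

    ``class_specs`` maps class id -> TextureSpec template; the template's own
    seed is ignored and replaced by a per-image seed derived from ``seed``.
    """
    if len(class_specs) < 2:
        raise ValueError("need at least 2 classes")
    if n_per_class < 5:
        import warnings

        warnings.warn("fewer than 5 images per class: CV folds will be tiny")
    images, labels, specs = [], [], []
    from dataclasses import replace

    for ci, template in enumerate(class_specs):
        for k in range(n_per_class):
            s = replace(template, seed=(seed * 1_000_003 + ci * 10_007 + k) % (2**31 - 1))
            images.append(make_image(s))
            labels.append(ci)
            specs.append(s)
    return LabeledImageSet(tuple(images), np.array(labels), tuple(specs))


def two_class_ar1_dataset(
    n_per_class: int = 50,
    size: tuple = (64, 64),
    rho_a: float = 0.2,
    rho_b: float = 0.8,
    seed: int = 0,
) -> LabeledImageSet:
    """The canonical two-class AR(1) benchmark used throughout the tests."""
    specs = [
        TextureSpec("correlated_noise", size=size, rho=rho_a),
        TextureSpec("correlated_noise", size=size, rho=rho_b),
    ]
    return make_dataset(n_per_class, specs, seed=seed)


def write_dataset(ds: LabeledImageSet, out_dir) -> str:
    """Write images as PNG plus a CSV manifest; returns the manifest path."""
    import csv
    from pathlib import Path

    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["path", "label", "seed", "spec"])
        for k, (img, lab, spec) in enumerate(zip(ds.images, ds.labels, ds.specs)):
            name = f"img_{k:05d}.png"
            iio.imwrite(out / name, img.pixels.astype(np.uint8))
            wr.writerow([name, int(lab), spec.seed, spec.generator])
    return str(manifest)


def make_gaussian_bump_matrix(
    center: tuple = (128.0, 128.0),
    covariance=((400.0, 0.0), (0.0, 400.0)),
    amplitude: float = 100.0,
    n_levels: int = N_GL_DEFAULT,
) -> tuple:
    """Gaussian-bump counts matrix with closed-form level-set ellipses.

    counts[i, j] = round(amplitude * exp(-0.5 * d' Sigma^-1 d)).  The level
    set at height h is the ellipse d' Sigma^-1 d < 2*log(amplitude/h), whose
    semi-axes are sqrt(2*log(amplitude/h) * eigvals(Sigma)).  Returns
    (CooccurrenceMatrix, analytic) where ``analytic(h)`` gives the semi-axes
    and orientation of the level-h ellipse, or None when empty.
    """
    cov = np.asarray(covariance, dtype=np.float64)
    evals, evecs = np.linalg.eigh(cov)
    if (evals <= 0).any():
        raise ValueError("covariance must be positive definite")
    ii, jj = np.meshgrid(np.arange(n_levels), np.arange(n_levels), indexing="ij")
    d = np.stack([ii - center[0], jj - center[1]], axis=-1)
    prec = np.linalg.inv(cov)
    q = np.einsum("...i,ij,...j->...", d, prec, d)
    counts = np.rint(amplitude * np.exp(-0.5 * q)).astype(np.int64)
    m = CooccurrenceMatrix(counts, d=1, theta=0, source_dims=(0, 0))

    def analytic(h: float):
        if h <= 0 or amplitude <= h:
            return None
        scale2 = 2.0 * np.log(amplitude / h)
        semi = np.sqrt(scale2 * evals)  # ascending: (minor, major)
        major_vec = evecs[:, 1]
        orientation = float(np.arctan2(major_vec[1], major_vec[0]))
        return {
            "semi_minor": float(semi[0]),
            "semi_major": float(semi[1]),
            "axis_ratio": float(semi[1] / semi[0]),
            "orientation": orientation,
        }

    return m, analytic
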