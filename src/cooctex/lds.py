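"""Lower-dimensional subspace (PCA) descriptor of the co-occurrence matrix.

The co-occurrence matrix itself is used as a feature vector: each (d, theta)
matrix is flattened (row-major), normalized to a probability table so image
size does not dominate the variance, and projected onto the principal
subspace retaining at least 99% of the training variance.  One subspace
model is fitted per (d, theta) slot (and per window/scale in the sub/sca
ensembles) on the training fold only; the per-slot projections are then
concatenated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .glcm import CooccurrenceMatrix

DEFAULT_VARIANCE = 0.99


@dataclass(frozen=True)
class SubspaceModel:
    mean: np.ndarray
    basis: np.ndarray  # (n_components, n_features), orthonormal rows
    explained_variance_ratio: np.ndarray
    key: tuple = ()

    @property
    def n_components(self) -> int:
        return self.basis.shape[0]

    @property
    def retained_variance_fraction(self) -> float:
        return float(self.explained_variance_ratio.sum())


def _flatten(m: CooccurrenceMatrix, normalize: bool = True) -> np.ndarray:
    v = m.counts.astype(np.float64).ravel()
    if normalize:
        total = v.sum()
        if total > 0:
            v = v / total
    return v


def fit_subspace(
    training: list,
    variance: float = DEFAULT_VARIANCE,
    normalize: bool = True,
    key: tuple = (),
) -> SubspaceModel:
    """Fit a PCA subspace on training-fold matrices only.

    Keeps the smallest number of components whose cumulative explained
    variance reaches ``variance``.  Zero-variance training data yields a
    single-component model (all projections zero) with a warning.
    """
    if len(training) < 2:
        raise ValueError("need at least 2 training matrices to fit a subspace")
    shapes = {m.counts.shape for m in training}
    if len(shapes) != 1:
        raise ValueError("training matrices must share one shape")
    X = np.stack([_flatten(m, normalize) for m in training])
    mean = X.mean(axis=0)
    if np.allclose(X, X[0]):
        warnings.warn("zero-variance training data: single-component subspace")
        basis = np.zeros((1, X.shape[1]))
        basis[0, 0] = 1.0
        return SubspaceModel(mean, basis, np.zeros(1), key)
    pca = PCA(n_components=variance, svd_solver="full")
    pca.fit(X)
    return SubspaceModel(mean, pca.components_, pca.explained_variance_ratio_, key)


def project(m: CooccurrenceMatrix, model: SubspaceModel, normalize: bool = True) -> np.ndarray:
    """Project a centered flattened matrix onto the subspace basis."""
    v = _flatten(m, normalize)
    if v.shape[0] != model.mean.shape[0]:
        raise ValueError(
            f"matrix size {v.shape[0]} does not match model size {model.mean.shape[0]}"
        )
    return model.basis @ (v - model.mean)


def save_model(model: SubspaceModel, path) -> None:
    """Persist mean + basis + metadata as a portable npz archive."""
    np.savez(
        path,
        mean=model.mean,
        basis=model.basis,
        explained_variance_ratio=model.explained_variance_ratio,
        key=np.array(list(map(str, model.key))),
    )


def load_model(path) -> SubspaceModel:
    z = np.load(path, allow_pickle=False)
    return SubspaceModel(
        z["mean"], z["basis"], z["explained_variance_ratio"], tuple(z["key"].tolist())
    )
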