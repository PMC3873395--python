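"""SVM score fusion and cross-validated evaluation of the descriptor family.

Each descriptor/window/scale combination trains a separate SVM; its per-class
decision scores form a ScorePanel.  Panels are z-score normalized (mean 0,
std 1 per class column) and combined by weighted sum rule.  Performance is
the one-vs-all AUC averaged over classes, under stratified 5-fold
cross-validation with per-fold retraining of scorers, normalizers and
subspace models (no test-fold leakage).

Method identifiers:

* ``HR/GR/CU/SH/LD`` — one SVM on the whole-matrix descriptor.
* ``*sub`` — whole matrix + subwindows (four quadrants, weight 4 for the
  whole-matrix SVM and 1 for each subwindow; SHAPE uses its 13 windows with
  weight 1 for the first five and 0.5 for the rest).
* ``*sca`` — the sub panels replicated over the three Gaussian scales,
  weight 4 for original-image panels and 1 for filtered ones.
* ``SUM2`` = HRsca + GRsca (weights 1:1); ``WS2`` = 2:1;
  ``W2`` = SUM2:SHsca 2:1; ``W3`` = SUM2:SHsca 3:1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import curvature, haralick, lds, runlength, shape
from .glcm import DISTANCES, QUADRANT_WINDOWS, SHAPE_WINDOWS, THETAS, GlcmSet, MatrixWindow, crop_window
from .multiscale import GrayImage, gaussian_stack

# ---------------------------------------------------------------------------
# score panels, normalization, fusion

@dataclass
class ScorePanel:
    """Per-sample, per-class classifier scores from one descriptor panel."""

    scores: np.ndarray  # (n_samples, n_classes)
    source: str = ""
    normalized: bool = False


def normalize_panel(p: ScorePanel) -> ScorePanel:
    """Column-wise z-scoring (population std); constant columns map to 0."""
    s = np.asarray(p.scores, dtype=np.float64)
    if not np.isfinite(s).all():
        raise ValueError(f"non-finite scores in panel {p.source!r}")
    mu = s.mean(axis=0)
    sd = s.std(axis=0)
    out = np.where(sd > 0, (s - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return ScorePanel(out, p.source, normalized=True)


@dataclass(frozen=True)
class FusionRule:
    """Weighted members of a sum-rule fusion; weights must be positive."""

    members: tuple  # of (selector, weight)

    def __post_init__(self) -> None:
        if len(self.members) == 0:
            raise ValueError("fusion rule needs at least one member")
        if any(w <= 0 for _, w in self.members):
            raise ValueError("fusion weights must be positive")


def fuse(panels: list, weights: list, source: str = "fused") -> ScorePanel:
    """Weighted sum of aligned score panels: fused = sum_k w_k * panel_k."""
    if len(panels) != len(weights):
        raise ValueError("one weight per panel required")
    shapes = {p.scores.shape for p in panels}
    if len(shapes) != 1:
        raise ValueError("panels must be aligned on samples and classes")
    acc = np.zeros(panels[0].scores.shape)
    for p, w in zip(panels, weights):
        acc += w * p.scores
    return ScorePanel(acc, source, normalized=False)


# ---------------------------------------------------------------------------
# one-vs-all AUC

def auc_ova(scores: np.ndarray, labels: np.ndarray, classes=None) -> float:
    """Per-class one-vs-all AUC (ties count 0.5), averaged over classes."""
    scores = np.asarray(scores)
    labels = np.asarray(labels)
    if classes is None:
        classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    aucs = []
    for k, c in enumerate(classes):
        pos = labels == c
        if not pos.any() or pos.all():
            warnings.warn(f"class {c} absent from one side of the test labels; skipped")
            continue
        aucs.append(roc_auc_score(pos, scores[:, k]))
    return float(np.mean(aucs))


# ---------------------------------------------------------------------------
# SVM scorer with inner model selection

DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)
DEFAULT_GAMMA_GRID = tuple(2.0**k for k in range(-5, 4))
DEFAULT_POLY_DEGREES = (2, 3)


def _param_grid(c_grid, gamma_grid, poly_degrees):
    return [
        {"svm__kernel": ["linear"], "svm__C": list(c_grid)},
        {"svm__kernel": ["rbf"], "svm__C": list(c_grid), "svm__gamma": list(gamma_grid)},
        {
            "svm__kernel": ["poly"],
            "svm__C": list(c_grid),
            "svm__degree": list(poly_degrees),
            "svm__gamma": ["scale"],
        },
    ]


def train_scorer(
    features: np.ndarray,
    labels: np.ndarray,
    inner_folds: int = 5,
    random_state: int = 0,
    c_grid=DEFAULT_C_GRID,
    gamma_grid=DEFAULT_GAMMA_GRID,
    poly_degrees=DEFAULT_POLY_DEGREES,
    descriptor: str = "",
):
    """Fit an SVM whose kernel and hyperparameters are chosen by inner CV.

    Linear, polynomial and RBF kernels compete on an inner stratified
    ``inner_folds``-fold split of the *training* partition only.  Returns the
    refitted best estimator (a scaler+SVC pipeline exposing
    ``decision_function``).
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if not np.isfinite(X).all():
        raise ValueError(f"NaN/inf in features of descriptor {descriptor!r}")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training data contains a single class")
    pipe = Pipeline([("scale", StandardScaler()), ("svm", SVC(decision_function_shape="ovr"))])
    n_min = np.bincount(np.searchsorted(classes, y)).min()
    folds = max(2, min(inner_folds, n_min))
    gs = GridSearchCV(
        pipe,
        _param_grid(c_grid, gamma_grid, poly_degrees),
        cv=StratifiedKFold(folds, shuffle=True, random_state=random_state),
        scoring="accuracy",
        n_jobs=1,
        refit=True,
    )
    gs.fit(X, y)
    return gs.best_estimator_


def decision_scores(model, X: np.ndarray) -> np.ndarray:
    """(n_samples, n_classes) decision scores; binary expands to 2 columns."""
    s = model.decision_function(np.asarray(X, dtype=np.float64))
    if s.ndim == 1:
        return np.column_stack([-s, s])
    return s


# ---------------------------------------------------------------------------
# cross-validation plan

@dataclass(frozen=True)
class CvPlan:
    n_folds: int = 5
    seed: int = 0

    def splits(self, labels: np.ndarray):
        labels = np.asarray(labels)
        skf = StratifiedKFold(self.n_folds, shuffle=True, random_state=self.seed)
        return list(skf.split(np.zeros(len(labels)), labels))


# ---------------------------------------------------------------------------
# panel definitions per method

@dataclass(frozen=True)
class PanelSpec:
    descriptor: str  # har | gl | cu | sh | ld
    window: MatrixWindow | None  # None = whole matrix
    scale: int  # index into the Gaussian scale stack
    weight: float

    @property
    def name(self) -> str:
        wl = self.window.label if self.window is not None else "whole"
        return f"{self.descriptor}_{wl}_s{self.scale}"


_BASE_DESCRIPTOR = {"HR": "har", "GR": "gl", "CU": "cu", "SH": "sh", "LD": "ld"}

COMPOSITE_METHODS = {
    "SUM2": (("HRsca", 1.0), ("GRsca", 1.0)),
    "WS2": (("HRsca", 2.0), ("GRsca", 1.0)),
    "W2": (("SUM2", 2.0), ("SHsca", 1.0)),
    "W3": (("SUM2", 3.0), ("SHsca", 1.0)),
}

METHOD_IDS = tuple(
    [b + v for b in _BASE_DESCRIPTOR for v in ("", "sub", "sca")]
) + tuple(COMPOSITE_METHODS)


def _sub_windows(desc: str):
    """(window, weight) pairs of the sub variant of one descriptor."""
    if desc == "sh":
        pairs = [(None, 1.0)] + [(w, 1.0) for w in SHAPE_WINDOWS[:4]]
        pairs += [(w, 0.5) for w in SHAPE_WINDOWS[4:]]
        return pairs
    return [(None, 4.0)] + [(w, 1.0) for w in QUADRANT_WINDOWS]


def panel_specs(method: str) -> tuple:
    """The (descriptor, window, scale, weight) panels of a non-composite method."""
    if method in COMPOSITE_METHODS:
        raise ValueError(f"{method} is a composite of fused methods, not panels")
    for base, desc in _BASE_DESCRIPTOR.items():
        if method == base:
            return (PanelSpec(desc, None, 0, 1.0),)
        if method == base + "sub":
            return tuple(PanelSpec(desc, w, 0, wt) for w, wt in _sub_windows(desc))
        if method == base + "sca":
            specs = []
            for scale in (0, 1, 2):
                sw = 4.0 if scale == 0 else 1.0
                for w, _ in _sub_windows(desc):
                    specs.append(PanelSpec(desc, w, scale, sw))
            return tuple(specs)
    raise ValueError(f"unknown method id {method!r}")


# ---------------------------------------------------------------------------
# feature extraction per panel

_STATIC_EXTRACTORS = {
    "har": haralick.har_descriptor,
    "gl": runlength.gl_descriptor,
    "cu": curvature.cu_descriptor,
    "sh": shape.sh_descriptor,
}


def glcm_stacks(images: list, n_scales: int = 3, distances=DISTANCES) -> list:
    """Per image, the GLCM sets of the original and smoothed versions."""
    from .glcm import glcm_set

    out = []
    for img in images:
        stack = gaussian_stack(img) if n_scales > 1 else [img]
        out.append([glcm_set(s, distances) for s in list(stack)[:n_scales]])
    return out


def static_panel_features(stacks: list, spec: PanelSpec) -> np.ndarray:
    """Feature matrix of a fold-independent descriptor panel."""
    fn = _STATIC_EXTRACTORS[spec.descriptor]
    return np.stack([fn(s[spec.scale], spec.window) for s in stacks])


def ld_panel_features(stacks: list, spec: PanelSpec, train_idx: np.ndarray) -> np.ndarray:
    """Subspace projections with the PCA models fitted on the training fold."""
    blocks = []
    example = stacks[0][spec.scale]
    for key in example.keys():
        mats = [
            crop_window(s[spec.scale][key], spec.window) if spec.window is not None else s[spec.scale][key]
            for s in stacks
        ]
        model = lds.fit_subspace([mats[i] for i in train_idx], key=key)
        blocks.append(np.stack([lds.project(m, model) for m in mats]))
    return np.concatenate(blocks, axis=1)


# ---------------------------------------------------------------------------
# experiment driver

def _fold_fused_scores(
    method: str,
    stacks: list,
    labels: np.ndarray,
    classes: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    seed: int,
    static_cache: dict,
) -> ScorePanel:
    """Fused, normalized test-fold scores of one method on one outer fold."""
    if method in COMPOSITE_METHODS:
        members, weights = [], []
        for sub_method, w in COMPOSITE_METHODS[method]:
            fused = _fold_fused_scores(
                method=sub_method, stacks=stacks, labels=labels, classes=classes,
                train_idx=train_idx, test_idx=test_idx, seed=seed,
                static_cache=static_cache,
            )
            members.append(normalize_panel(fused))
            weights.append(w)
        return normalize_panel(fuse(members, weights, source=method))

    panels, weights = [], []
    for spec in panel_specs(method):
        if spec.descriptor == "ld":
            X = ld_panel_features(stacks, spec, train_idx)
        else:
            if spec.name not in static_cache:
                static_cache[spec.name] = static_panel_features(stacks, spec)
            X = static_cache[spec.name]
        model = train_scorer(
            X[train_idx], labels[train_idx], random_state=seed, descriptor=spec.name
        )
        scores = decision_scores(model, X[test_idx])
        panels.append(normalize_panel(ScorePanel(scores, spec.name)))
        weights.append(spec.weight)
    return normalize_panel(fuse(panels, weights, source=method))


def run_experiment(
    images: list,
    labels: np.ndarray,
    method: str,
    cv: CvPlan | None = None,
    distances=DISTANCES,
) -> dict:
    """Mean outer-fold one-vs-all AUC of one method, with a per-fold log."""
    if method not in METHOD_IDS:
        raise ValueError(f"unknown method {method!r}; known: {METHOD_IDS}")
    cv = cv or CvPlan()
    labels = np.asarray(labels)
    classes = np.unique(labels)

    needs_scales = "sca" in method or method in COMPOSITE_METHODS
    from .glcm import glcm_set

    stacks = []
    for img in images:
        stack = gaussian_stack(img) if needs_scales else [img]
        stacks.append([glcm_set(s, distances) for s in stack])

    static_cache: dict = {}
    fold_aucs = []
    fold_log = []
    for k, (train_idx, test_idx) in enumerate(cv.splits(labels)):
        fused = _fold_fused_scores(
            method, stacks, labels, classes, train_idx, test_idx, cv.seed, static_cache
        )
        auc = auc_ova(fused.scores, labels[test_idx], classes)
        fold_aucs.append(auc)
        fold_log.append({"fold": k, "auc": auc, "n_test": len(test_idx)})
    return {
        "method": method,
        "auc_mean": float(np.mean(fold_aucs)),
        "auc_folds": fold_aucs,
        "folds": fold_log,
        "n_samples": len(labels),
        "n_classes": len(classes),
        "seed": cv.seed,
    }
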