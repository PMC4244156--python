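"""SVM genotype classifier: scaling, grid search, calling, persistence.

Each (individual, site) feature vector is one point in a 5-dimensional
space; homozygous-reference, heterozygous and homozygous-indel carriers
form three clusters that an RBF-kernel support-vector machine separates.
Models are trained per indel kind (deletion features and insertion features
have different semantics) with min-max scaling to [-1, 1], a (C, gamma)
grid search scored by stratified 10-fold cross-validation, and optional
pairwise-coupling class probabilities.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

logger = logging.getLogger("indelgt")

__all__ = [
    "Scaler",
    "GenotypeModel",
    "GenotypeCall",
    "DEFAULT_C_GRID",
    "DEFAULT_GAMMA_GRID",
    "SMALL_C_GRID",
    "SMALL_GAMMA_GRID",
    "fit_scaler",
    "apply_scaler",
    "train_genotyper",
    "call_genotypes",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1

#: Canonical coarse grid for RBF model selection.
DEFAULT_C_GRID: tuple[float, ...] = tuple(2.0 ** k for k in range(-5, 16, 2))
DEFAULT_GAMMA_GRID: tuple[float, ...] = tuple(2.0 ** k for k in range(-15, 4, 2))

#: Reduced grid for pipeline runs where refined selection is not worth the fits.
SMALL_C_GRID: tuple[float, ...] = tuple(2.0 ** k for k in (-1, 1, 3, 5, 7, 9))
SMALL_GAMMA_GRID: tuple[float, ...] = tuple(2.0 ** k for k in (-7, -5, -3, -1, 1))


@dataclass(frozen=True)
class Scaler:
    """Per-dimension min-max map onto [-1, 1] fitted on training data.

    Constant training columns (min == max) map every input to 0.  Values
    outside the training range extrapolate linearly; no clamping.
    """

    mins: np.ndarray
    maxs: np.ndarray

    @property
    def n_features(self) -> int:
        return len(self.mins)


def fit_scaler(vectors: Sequence[Sequence[float]] | np.ndarray) -> Scaler:
    x = np.asarray(vectors, dtype=float)
    if x.ndim != 2 or x.shape[0] == 0:
        raise ValueError("need a non-empty 2-D training matrix")
    return Scaler(mins=x.min(axis=0), maxs=x.max(axis=0))


def apply_scaler(scaler: Scaler, vectors: Sequence[Sequence[float]] | np.ndarray) -> np.ndarray:
    x = np.asarray(vectors, dtype=float)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    if x.shape[1] != scaler.n_features:
        raise ValueError(
            f"dimension mismatch: scaler has {scaler.n_features}, input has {x.shape[1]}"
        )
    span = scaler.maxs - scaler.mins
    out = np.zeros_like(x)
    nz = span > 0
    out[:, nz] = -1.0 + 2.0 * (x[:, nz] - scaler.mins[nz]) / span[nz]
    return out[0] if single else out


@dataclass
class GenotypeModel:
    """Scaler + trained SVC for one indel kind, with its selection metadata."""

    scaler: Scaler
    svc: SVC
    C: float
    gamma: float
    cv_accuracy: float
    classes: tuple[int, ...]
    indel_kind: str
    feature_names: tuple[str, ...]
    seed: int
    # Scaled training data kept for deterministic persistence (refit-on-load).
    train_x: np.ndarray = field(repr=False, default=None)
    train_y: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class GenotypeCall:
    sample: str
    site_id: str
    g: int
    probs: tuple[float, float, float] | None = None


def _fit_svc(
    xs: np.ndarray, y: np.ndarray, C: float, gamma: float,
    class_weight: str | None, seed: int,
) -> SVC:
    svc = SVC(
        kernel="rbf", C=C, gamma=gamma, probability=True,
        class_weight=class_weight, random_state=seed,
    )
    with warnings.catch_warnings():
        # sklearn >= 1.9 deprecates SVC(probability=True); the Platt
        # pairwise-coupling probabilities are exactly what we want here.
        warnings.simplefilter("ignore", FutureWarning)
        svc.fit(xs, y)
    return svc


def _grid_cv_accuracy(
    x: np.ndarray, y: np.ndarray, C: float, gamma: float, folds: int, seed: int,
    class_weight: str | None,
) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    correct = 0
    for train_idx, test_idx in skf.split(x, y):
        clf = SVC(kernel="rbf", C=C, gamma=gamma, class_weight=class_weight)
        clf.fit(x[train_idx], y[train_idx])
        correct += int(np.sum(clf.predict(x[test_idx]) == y[test_idx]))
    return correct / len(y)


def train_genotyper(
    vectors: Sequence[Sequence[float]] | np.ndarray,
    labels: Sequence[int],
    folds: int = 10,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    seed: int = 0,
    indel_kind: str = "DEL",
    feature_names: Sequence[str] | None = None,
    balance_classes: bool = False,
) -> GenotypeModel:
    """Grid search + stratified k-fold CV, then refit on all data.

    The winner maximizes CV accuracy; ties prefer smaller C, then smaller
    gamma (smoother decision surfaces).  Fold assignment is
    seed-deterministic.  ``balance_classes`` weights classes by inverse
    frequency (useful at low allele frequency where genotype 0 dominates);
    off by default.
    """
    x = np.asarray(vectors, dtype=float)
    y = np.asarray(labels, dtype=int)
    if x.ndim != 2 or len(x) != len(y):
        raise ValueError("vectors and labels must align")
    classes = tuple(sorted(set(int(v) for v in y)))
    if len(classes) < 2:
        raise ValueError("training requires at least two distinct genotype labels")
    if not set(classes) <= {0, 1, 2}:
        raise ValueError("genotype labels must be in {0, 1, 2}")
    counts = np.bincount(y)
    min_class = int(counts[counts > 0].min())
    eff_folds = min(folds, len(y), min_class)
    eff_folds = max(2, eff_folds)
    if eff_folds < folds:
        logger.warning("reducing CV folds from %d to %d (small class)", folds, eff_folds)

    scaler = fit_scaler(x)
    xs = apply_scaler(scaler, x)
    class_weight = "balanced" if balance_classes else None

    best = None  # (acc, C, gamma); ties resolved by scan order below
    for C in sorted(c_grid):
        for gamma in sorted(gamma_grid):
            acc = _grid_cv_accuracy(xs, y, C, gamma, eff_folds, seed, class_weight)
            if best is None or acc > best[0]:
                best = (acc, C, gamma)
    cv_acc, C, gamma = best

    svc = _fit_svc(xs, y, C, gamma, class_weight, seed)
    return GenotypeModel(
        scaler=scaler,
        svc=svc,
        C=C,
        gamma=gamma,
        cv_accuracy=cv_acc,
        classes=classes,
        indel_kind=str(indel_kind),
        feature_names=tuple(feature_names) if feature_names else tuple(f"f{i+1}" for i in range(x.shape[1])),
        seed=int(seed),
        train_x=xs,
        train_y=y,
    )


def call_genotypes(
    model: GenotypeModel,
    vectors: Sequence[Sequence[float]] | np.ndarray,
    with_probs: bool = False,
    samples: Sequence[str] | None = None,
    site_ids: Sequence[str] | None = None,
) -> list[GenotypeCall]:
    """One genotype call per vector; the scaler is applied internally.

    With probabilities the reported genotype is the argmax of the 3-class
    probability vector (ties break to the smaller genotype), so call and
    probabilities are always consistent.
    """
    x = np.asarray(vectors, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    xs = apply_scaler(model.scaler, x)
    n = len(xs)
    samples = samples if samples is not None else ["sample"] * n
    site_ids = site_ids if site_ids is not None else [f"site{i}" for i in range(n)]

    calls: list[GenotypeCall] = []
    if with_probs:
        raw = model.svc.predict_proba(xs)
        for i in range(n):
            probs = np.zeros(3)
            for j, cls in enumerate(model.svc.classes_):
                probs[int(cls)] = raw[i, j]
            probs = probs / probs.sum()
            g = int(np.argmax(probs))  # ties -> smaller genotype
            calls.append(GenotypeCall(samples[i], site_ids[i], g, tuple(float(p) for p in probs)))
    else:
        pred = model.svc.predict(xs)
        for i in range(n):
            calls.append(GenotypeCall(samples[i], site_ids[i], int(pred[i])))
    return calls


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_model(model: GenotypeModel, path: str) -> None:
    """Write a self-describing JSON model file.

    The scaled training matrix and labels are stored alongside the winning
    kernel parameters; :func:`load_model` refits deterministically, which
    reproduces predictions bit-for-bit.
    """
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "indel_kind": model.indel_kind,
        "feature_names": list(model.feature_names),
        "classes": list(model.classes),
        "C": model.C,
        "gamma": model.gamma,
        "cv_accuracy": model.cv_accuracy,
        "seed": model.seed,
        "scaler": {"mins": model.scaler.mins.tolist(), "maxs": model.scaler.maxs.tolist()},
        "train_x": model.train_x.tolist(),
        "train_y": model.train_y.tolist(),
        "balanced": model.svc.class_weight == "balanced",
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path: str, expected_feature_names: Sequence[str] | None = None) -> GenotypeModel:
    with open(path) as fh:
        payload = json.load(fh)
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {version!r}")
    names = tuple(payload["feature_names"])
    if expected_feature_names is not None and tuple(expected_feature_names) != names:
        raise ValueError(
            f"model feature order {names} does not match expected {tuple(expected_feature_names)}"
        )
    scaler = Scaler(
        mins=np.asarray(payload["scaler"]["mins"], float),
        maxs=np.asarray(payload["scaler"]["maxs"], float),
    )
    xs = np.asarray(payload["train_x"], float)
    y = np.asarray(payload["train_y"], int)
    svc = _fit_svc(
        xs, y, float(payload["C"]), float(payload["gamma"]),
        "balanced" if payload.get("balanced") else None, int(payload["seed"]),
    )
    return GenotypeModel(
        scaler=scaler,
        svc=svc,
        C=float(payload["C"]),
        gamma=float(payload["gamma"]),
        cv_accuracy=float(payload["cv_accuracy"]),
        classes=tuple(int(c) for c in payload["classes"]),
        indel_kind=str(payload["indel_kind"]),
        feature_names=names,
        seed=int(payload["seed"]),
        train_x=xs,
        train_y=y,
    )
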