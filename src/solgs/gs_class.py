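"""Classification-based genomic prediction of ordinal descriptor traits.

Conventional-descriptor traits are scored into a handful of categories, so
their genomic prediction is framed as classification on marker dosages.
Two families are provided: a bootstrap-aggregated tree ensemble (random
forest, 1000 trees, sqrt(p) split candidates) and a radial-basis-kernel
maximum-margin classifier (SVC) whose cost and kernel-width parameters are
chosen from 15 x 15 candidate grids by inner cross-validated accuracy.
Class imbalance is addressed by SMOTE interpolation, applied strictly
inside training folds by the evaluation engine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

#: Default 15-point cost grid for the kernel-margin classifier.
DEFAULT_COST_GRID = np.logspace(-2, 3, 15)


@dataclass
class ClassifierSpec:
    """Configuration of a classification GS model.

    ``width_grid`` holds RBF gamma values; when absent it is built at fit
    time as 15 log-spaced values around the median-heuristic kernel width.
    """

    family: str = "tree_ensemble"     # or "kernel_margin"
    n_trees: int = 1000
    split_candidates: int | None = None   # default floor(sqrt(p))
    cost_grid: np.ndarray | None = None
    width_grid: np.ndarray | None = None
    inner_cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("tree_ensemble", "kernel_margin"):
            raise ValueError(f"unknown classifier family {self.family!r}")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        for grid in (self.cost_grid, self.width_grid):
            if grid is not None and len(grid) != 15:
                raise ValueError("hyperparameter grids must hold 15 values")


def smote(Xf: np.ndarray, labels: np.ndarray, k: int = 5,
          seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority oversampling to a fully balanced class design.

    Each synthetic sample interpolates a minority sample x toward one of
    its k nearest same-class neighbors z: x + U(0,1) (z - x).  A singleton
    class cannot be interpolated and falls back to duplication with a
    warning.  Originals come first in the output; deterministic under seed.
    """
    Xf = np.asarray(Xf, dtype=float)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(labels, return_counts=True)
    n_max = counts.max()
    X_out = [Xf]
    y_out = [labels]
    for cls, cnt in zip(classes, counts):
        need = n_max - cnt
        if need == 0:
            continue
        Xc = Xf[labels == cls]
        if cnt == 1:
            warnings.warn(f"class {cls!r} has one sample; duplicating instead "
                          "of interpolating")
            synth = np.repeat(Xc, need, axis=0)
        else:
            kk = min(k, cnt - 1)
            nn = NearestNeighbors(n_neighbors=kk + 1).fit(Xc)
            _, nbr = nn.kneighbors(Xc)   # col 0 is the point itself
            base = rng.integers(cnt, size=need)
            pick = rng.integers(kk, size=need)
            z = Xc[nbr[base, pick + 1]]
            gap = rng.random(need)[:, None]
            synth = Xc[base] + gap * (z - Xc[base])
        X_out.append(synth)
        y_out.append(np.full(need, cls, dtype=labels.dtype))
    return np.vstack(X_out), np.concatenate(y_out)


class FittedClassifier:
    """Fitted estimator with score/label prediction and feature checking.

    Labels are always the argmax of the class-score matrix, so
    ``predict_class`` and ``predict_scores`` cannot disagree.
    """

    def __init__(self, estimator, n_features: int):
        self._est = estimator
        self._n_features = n_features

    @property
    def classes_(self) -> np.ndarray:
        return self._est.classes_

    def _check(self, Xf: np.ndarray) -> np.ndarray:
        Xf = np.atleast_2d(np.asarray(Xf, dtype=float))
        if Xf.shape[1] != self._n_features:
            raise ValueError("feature dimension mismatch with training data")
        return Xf

    def predict_scores(self, Xf: np.ndarray) -> np.ndarray:
        """Row-stochastic class score matrix.

        Tree ensembles report vote fractions; margin classifiers report
        softmax-normalized one-vs-rest decision margins (rank-preserving
        per class, so AUC is unaffected by the normalization).
        """
        Xf = self._check(Xf)
        if hasattr(self._est, "predict_proba"):
            return self._est.predict_proba(Xf)
        margins = self._est.decision_function(Xf)
        if margins.ndim == 1:
            margins = np.column_stack([-margins, margins])
        margins = margins - margins.max(axis=1, keepdims=True)
        expm = np.exp(margins)
        return expm / expm.sum(axis=1, keepdims=True)

    def predict_class(self, Xf: np.ndarray) -> np.ndarray:
        scores = self.predict_scores(Xf)
        return self.classes_[np.argmax(scores, axis=1)]


def fit_classifier(spec: ClassifierSpec, Xf: np.ndarray,
                   labels: np.ndarray) -> FittedClassifier:
    """Fit the configured classifier on a feature matrix and labels."""
    Xf = np.asarray(Xf, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    p = Xf.shape[1]

    if spec.family == "tree_ensemble":
        max_features = spec.split_candidates or max(int(np.sqrt(p)), 1)
        est = RandomForestClassifier(
            n_estimators=spec.n_trees,
            max_features=max_features,
            random_state=spec.seed,
            n_jobs=1,
        )
        est.fit(Xf, labels)
    else:
        cost = spec.cost_grid if spec.cost_grid is not None else DEFAULT_COST_GRID
        if spec.width_grid is not None:
            gamma = spec.width_grid
        else:
            sub = Xf[np.random.default_rng(spec.seed).permutation(len(Xf))[:200]]
            d2 = np.sum((sub[:, None, :] - sub[None, :, :]) ** 2, axis=-1)
            med = np.median(d2[np.triu_indices_from(d2, k=1)])
            gamma0 = 1.0 / max(med, 1e-12)
            gamma = gamma0 * np.logspace(-2, 2, 15)
        n_splits = min(spec.inner_cv_folds, counts.min())
        if n_splits >= 2:
            cv = StratifiedKFold(n_splits=n_splits, shuffle=True,
                                 random_state=spec.seed)
            search = GridSearchCV(
                SVC(kernel="rbf", decision_function_shape="ovr",
                    random_state=spec.seed),
                {"C": list(cost), "gamma": list(gamma)},
                scoring="accuracy", cv=cv, n_jobs=1,
            )
            search.fit(Xf, labels)
            est = search.best_estimator_
        else:
            warnings.warn("too few samples per class for inner CV; fitting "
                          "at median-heuristic width and C=1")
            est = SVC(kernel="rbf", C=1.0, gamma=float(np.median(gamma)),
                      decision_function_shape="ovr", random_state=spec.seed)
            est.fit(Xf, labels)
    return FittedClassifier(est, p)
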