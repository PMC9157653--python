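"""Cross-validation engine, predictability metrics and transfer scenarios.

Predictability of a regression GS model is assessed in repeated k-fold
cross-validation (default 5 folds x 30 repetitions = 150 sets) by four
per-set metrics: Pearson and Spearman correlation between measured and
predicted values, and the matched rate of the top 30% / 15% accessions.
Classification models are scored by accuracy and (macro one-vs-rest) AUC.
Regression predictions can be mapped onto the class proportions of an
ordinal trait by rank quantiles, putting both model families on the same
accuracy footing.

Population-transfer scenarios probe prediction of divergent wild material:
train on cultivated only (baseline), augment the cultivated training set
with a small stratified wild sample, or balance cultivated and wild counts
in training; each non-baseline scenario is redrawn independently per set.

Everything fitted inside a set (marker centering, SMOTE, hyperparameter
grids) sees training folds only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from . import gs_class, gs_core, gs_multi
from .simdata import derive_categorical_trait

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Fold construction
# ---------------------------------------------------------------------------


@dataclass
class CVScheme:
    """Repeated k-fold assignments: ``assignments[r, i]`` is the fold of
    accession i in repetition r; folds partition the accessions with sizes
    differing by at most one."""

    accession_ids: np.ndarray
    n_folds: int
    n_repetitions: int
    assignments: np.ndarray
    seed: int

    @property
    def n_sets(self) -> int:
        return self.n_folds * self.n_repetitions


def make_cv_folds(accession_ids, n_folds: int = 5, n_repetitions: int = 30,
                  seed: int = 0) -> CVScheme:
    """Seeded uniform permutation per repetition, round-robin fold labels."""
    accession_ids = np.asarray(accession_ids, dtype=object)
    n = len(accession_ids)
    if n < n_folds:
        raise ValueError("fewer accessions than folds")
    rng = np.random.default_rng(seed)
    assignments = np.empty((n_repetitions, n), dtype=int)
    for r in range(n_repetitions):
        perm = rng.permutation(n)
        assignments[r, perm] = np.arange(n) % n_folds
    return CVScheme(accession_ids=accession_ids, n_folds=n_folds,
                    n_repetitions=n_repetitions, assignments=assignments,
                    seed=seed)


def iter_splits(scheme: CVScheme):
    """Yield (repetition, fold, train_index, test_index) over all sets."""
    for r in range(scheme.n_repetitions):
        for f in range(scheme.n_folds):
            test = np.flatnonzero(scheme.assignments[r] == f)
            train = np.flatnonzero(scheme.assignments[r] != f)
            yield r, f, train, test


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def metric_pearson(yhat, y) -> float:
    """Pearson correlation; NaN (recorded as missing) for constant input."""
    yhat = np.asarray(yhat, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 observations")
    if np.std(yhat) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.pearsonr(yhat, y).statistic)


def metric_spearman(yhat, y) -> float:
    """Spearman rank correlation; NaN for constant input."""
    yhat = np.asarray(yhat, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 observations")
    if np.std(yhat) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.spearmanr(yhat, y).statistic)


def metric_top_match(yhat, y, fraction: float) -> float:
    """Matched rate of the top ``fraction`` sets of predicted and measured
    values: |top-s by yhat intersect top-s by y| / s with s = ceil(f n).
    Ranking ties are broken by accession (input) order."""
    yhat = np.asarray(yhat, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    s = math.ceil(fraction * n)
    top_hat = set(np.argsort(-yhat, kind="stable")[:s].tolist())
    top_obs = set(np.argsort(-y, kind="stable")[:s].tolist())
    return len(top_hat & top_obs) / s


def metric_accuracy(pred_labels, true_labels) -> float:
    """Fraction of exact label matches."""
    pred_labels = np.asarray(pred_labels)
    true_labels = np.asarray(true_labels)
    if len(pred_labels) != len(true_labels):
        raise ValueError("length mismatch")
    return float(np.mean(pred_labels == true_labels))


def metric_auc(scores: np.ndarray, true_labels, classes=None) -> float:
    """ROC AUC from a sample x class score matrix.

    Binary: rank-based (Mann-Whitney) AUC of the positive-class score.
    Multiclass: macro-averaged one-vs-rest over classes present in truth.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    true_labels = np.asarray(true_labels)
    present = np.unique(true_labels)
    if len(present) < 2:
        raise ValueError("AUC undefined for single-class truth")
    if classes is None:
        classes = present
    classes = np.asarray(classes)
    if scores.shape[1] == 2 and len(present) == 2:
        pos_col = int(np.flatnonzero(classes == present[1])[0])
        return float(roc_auc_score(true_labels == present[1], scores[:, pos_col]))
    aucs = []
    for cls in present:
        col = int(np.flatnonzero(classes == cls)[0])
        aucs.append(roc_auc_score(true_labels == cls, scores[:, col]))
    return float(np.mean(aucs))


def map_regression_to_categories(yhat, class_proportions) -> np.ndarray:
    """Rank-quantile assignment of predicted values to ordinal classes using
    the observed class proportions of the related descriptor trait."""
    return derive_categorical_trait(np.asarray(yhat, dtype=float),
                                    class_proportions)


def paired_t_test(metric_a, metric_b) -> tuple[float, float]:
    """Two-sided paired t-test on per-set metric differences."""
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    diff = a - b
    if np.std(diff, ddof=1) == 0:
        if np.allclose(diff, 0):
            return 0.0, 1.0
        logger.warning("paired_t_test: zero-variance nonzero differences")
        return math.copysign(math.inf, diff.mean()), 0.0
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Cross-validation runners
# ---------------------------------------------------------------------------


@dataclass
class CVReport:
    """Per-set metric records for one (trait, model, scenario)."""

    trait: str
    model: str
    scenario: str
    records: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        """Mean and standard deviation per metric, missing values excluded."""
        vals = self.records.drop(columns=["repetition", "fold"], errors="ignore")
        n_missing = vals.isna().sum()
        if n_missing.any():
            logger.info("CVReport %s/%s: excluded missing values per metric: %s",
                        self.trait, self.model, n_missing.to_dict())
        return pd.DataFrame({"mean": vals.mean(), "sd": vals.std()})


def run_cv_regression(Z: np.ndarray, y: np.ndarray, scheme: CVScheme,
                      lam: float | None = None,
                      marker_index: np.ndarray | None = None,
                      trait: str = "trait", model: str = "rrblup",
                      scenario: str = "standard_cv",
                      fold_callback=None) -> CVReport:
    """Repeated k-fold rrBLUP predictability.

    ``marker_index`` optionally restricts to a marker subset (e.g. tag
    SNPs).  ``fold_callback(train_index)`` is an instrumentation hook used
    to verify fold hygiene in tests.
    """
    Z = np.asarray(Z, dtype=float)
    if marker_index is not None:
        Z = Z[:, np.asarray(marker_index)]
    y = np.asarray(y, dtype=float)
    rows = []
    for r, f, train, test in iter_splits(scheme):
        if fold_callback is not None:
            fold_callback(train)
        m = gs_core.fit_rrblup(Z[train], y[train], lam=lam)
        yhat = gs_core.predict(m, Z[test])
        rows.append({
            "repetition": r, "fold": f,
            "pearson": metric_pearson(yhat, y[test]),
            "spearman": metric_spearman(yhat, y[test]),
            "top30_match": metric_top_match(yhat, y[test], 0.30),
            "top15_match": metric_top_match(yhat, y[test], 0.15),
        })
    return CVReport(trait, model, scenario, pd.DataFrame(rows))


def run_cv_multitrait(Z: np.ndarray, Y: np.ndarray, scheme: CVScheme,
                      trait_names: list[str] | None = None,
                      scenario: str = "standard_cv") -> CVReport:
    """Repeated k-fold multivariate predictability.

    Records per-trait Pearson correlations plus the Rv coefficient between
    the predicted and measured trait matrices of the test fold.
    """
    Z = np.asarray(Z, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    t = Y.shape[1]
    if trait_names is None:
        trait_names = [f"trait_{a + 1}" for a in range(t)]
    rows = []
    for r, f, train, test in iter_splits(scheme):
        K_train, K_cross = gs_core.kinship_pair(Z[train], Z[test])
        m = gs_multi.fit_multitrait(K_train, Y[train], trait_names=trait_names)
        pred = gs_multi.predict_multitrait(m, K_cross)
        row = {"repetition": r, "fold": f}
        for a, name in enumerate(trait_names):
            row[f"pearson_{name}"] = metric_pearson(pred[:, a], Y[test, a])
        row["rv"] = gs_multi.rv_coefficient(pred, Y[test])
        rows.append(row)
    return CVReport("+".join(trait_names), "multitrait", scenario,
                    pd.DataFrame(rows))


def run_cv_classification(Z: np.ndarray, labels: np.ndarray,
                          spec: gs_class.ClassifierSpec, scheme: CVScheme,
                          smote_balance: bool = True, trait: str = "trait",
                          scenario: str = "standard_cv",
                          fold_callback=None) -> CVReport:
    """Repeated k-fold classification predictability (accuracy and AUC).

    SMOTE balancing, when enabled, is applied to the training fold only.
    Sets whose training fold holds a single class are skipped and logged;
    single-class test folds record accuracy with missing AUC.
    """
    Z = np.asarray(Z, dtype=float)
    labels = np.asarray(labels)
    rows = []
    n_skipped = 0
    for r, f, train, test in iter_splits(scheme):
        if fold_callback is not None:
            fold_callback(train)
        X_tr, y_tr = Z[train], labels[train]
        if len(np.unique(y_tr)) < 2:
            n_skipped += 1
            continue
        if smote_balance:
            X_tr, y_tr = gs_class.smote(X_tr, y_tr, seed=spec.seed + r * scheme.n_folds + f)
        fitted = gs_class.fit_classifier(spec, X_tr, y_tr)
        scores = fitted.predict_scores(Z[test])
        pred = fitted.classes_[np.argmax(scores, axis=1)]
        truth = labels[test]
        try:
            auc = metric_auc(scores, truth, classes=fitted.classes_)
        except ValueError:
            auc = float("nan")
        rows.append({"repetition": r, "fold": f,
                     "accuracy": metric_accuracy(pred, truth), "auc": auc})
    if n_skipped:
        logger.info("run_cv_classification: skipped %d single-class sets", n_skipped)
    return CVReport(trait, spec.family, scenario, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Population-transfer scenarios
# ---------------------------------------------------------------------------


@dataclass
class ScenarioSpec:
    """Transfer-scenario configuration.

    Modes: ``baseline_transfer`` (train on all cultivated, test on all
    wild; one split), ``wild_augment`` (cultivated + ``n_wild`` wild
    accessions with at least one per wild species when stratified, tested
    on the remaining wild) and ``wild_balanced`` (equal cultivated and wild
    counts in training, tested on everything else).  Non-baseline draws are
    independent per set.
    """

    mode: str = "wild_augment"
    n_wild: int | None = None
    n_cultivated: int | None = None
    stratify_species: bool = True
    n_draws: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("standard_cv", "wild_augment", "wild_balanced",
                             "baseline_transfer"):
            raise ValueError(f"unknown scenario mode {self.mode!r}")


def build_scenarios(meta: pd.DataFrame, spec: ScenarioSpec) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded (train ids, test ids) splits for a transfer scenario.

    ``meta`` is indexed by accession id with columns ``species`` and
    ``is_wild``.
    """
    wild_ids = meta.index[meta["is_wild"]].to_numpy(dtype=object)
    cult_ids = meta.index[~meta["is_wild"]].to_numpy(dtype=object)
    rng = np.random.default_rng(spec.seed)

    if spec.mode == "baseline_transfer":
        return [(cult_ids.copy(), wild_ids.copy())]

    species = meta.loc[wild_ids, "species"].to_numpy()
    uniq_species = pd.unique(species)
    splits = []
    for _ in range(spec.n_draws):
        if spec.mode == "wild_augment":
            if spec.n_wild is None:
                raise ValueError("wild_augment requires n_wild")
            if spec.stratify_species and spec.n_wild < len(uniq_species):
                raise ValueError("n_wild smaller than the number of wild species")
            chosen = _draw_wild(rng, wild_ids, species, uniq_species,
                                spec.n_wild, spec.stratify_species)
            train = np.concatenate([cult_ids, chosen])
            test = np.setdiff1d(wild_ids, chosen)
        elif spec.mode == "wild_balanced":
            n = spec.n_cultivated if spec.n_cultivated is not None else spec.n_wild
            if n is None:
                raise ValueError("wild_balanced requires a training count")
            chosen_w = _draw_wild(rng, wild_ids, species, uniq_species, n,
                                  spec.stratify_species and n >= len(uniq_species))
            chosen_c = rng.choice(cult_ids, size=n, replace=False)
            train = np.concatenate([chosen_c, chosen_w])
            test = np.setdiff1d(np.concatenate([cult_ids, wild_ids]), train)
        else:
            raise ValueError(f"mode {spec.mode!r} has no draw-based splits")
        splits.append((train, test))
    return splits


def _draw_wild(rng, wild_ids, species, uniq_species, n_wild, stratify) -> np.ndarray:
    if n_wild > len(wild_ids):
        raise ValueError("n_wild exceeds the number of wild accessions")
    if stratify:
        chosen = [rng.choice(wild_ids[species == sp]) for sp in uniq_species]
        rest = np.setdiff1d(wild_ids, np.asarray(chosen, dtype=object))
        extra = n_wild - len(chosen)
        if extra > 0:
            chosen.extend(rng.choice(rest, size=extra, replace=False))
        return np.asarray(chosen, dtype=object)
    return rng.choice(wild_ids, size=n_wild, replace=False)


def evaluate_transfer(Z: np.ndarray, y: np.ndarray, accession_ids,
                      splits: list[tuple[np.ndarray, np.ndarray]],
                      lam: float | None = None) -> pd.DataFrame:
    """Fit on each split's training ids and score the held-out ids.

    Returns one row per split with the four regression metrics.
    """
    accession_ids = np.asarray(accession_ids, dtype=object)
    index = {a: i for i, a in enumerate(accession_ids)}
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    rows = []
    for s, (train_ids, test_ids) in enumerate(splits):
        tr = np.asarray([index[a] for a in train_ids])
        te = np.asarray([index[a] for a in test_ids])
        m = gs_core.fit_rrblup(Z[tr], y[tr], lam=lam)
        yhat = gs_core.predict(m, Z[te])
        rows.append({
            "split": s,
            "pearson": metric_pearson(yhat, y[te]),
            "spearman": metric_spearman(yhat, y[te]),
            "top30_match": metric_top_match(yhat, y[te], 0.30),
            "top15_match": metric_top_match(yhat, y[te], 0.15),
        })
    return pd.DataFrame(rows)


def write_report(report: CVReport, path: str) -> None:
    """Tidy per-set records with identifying columns prepended."""
    df = report.records.copy()
    df.insert(0, "trait", report.trait)
    df.insert(1, "model", report.model)
    df.insert(2, "scenario", report.scenario)
    df.to_csv(path, sep="\t", index=False)
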