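"""Per-interaction ridge sub-classifiers, boosted combination, and CV metrics.

Each selected interaction becomes one ridge-regression sub-classifier whose
design matrix contains the interaction's variables *and every product term
among them* — for binary codes the products are the joint-occurrence (AND)
indicators that let a linear fit capture non-additive joint action such as
XOR.  Sub-classifiers are combined by an AdaBoost-style sample-reweighting
scheme over the fixed pool of interactions, and the whole pipeline is
evaluated by stratified k-fold cross-validation.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import Ridge, RidgeCV
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "SubClassifier",
    "Ensemble",
    "Metrics",
    "CVResult",
    "expand_products",
    "fit_subclassifier",
    "boost_combine",
    "evaluate_cv",
]

log = logging.getLogger(__name__)

RIDGE_ALPHAS = np.logspace(-3, 3, 10)
MAX_INTERACTION_SIZE = 12  # 2^12 product columns is the feature blow-up guard


def _as_values(matrix) -> np.ndarray:
    return np.asarray(getattr(matrix, "values", matrix))


def expand_products(matrix, interaction):
    """Design matrix of an interaction's variables and all their products.

    Columns are the ``m`` singletons followed by the products of every
    subset of size >= 2, ordered by subset size then index — ``2**m - 1``
    columns total.  Returns ``(features, feature_map)`` where ``feature_map``
    lists the variable-index tuple behind each column.
    """
    values = _as_values(matrix)
    idx = tuple(sorted(int(i) for i in interaction))
    m = len(idx)
    if m < 1:
        raise ValueError("interaction must be non-empty")
    if m > MAX_INTERACTION_SIZE:
        raise ValueError(f"interaction size {m} exceeds {MAX_INTERACTION_SIZE}")
    feature_map = []
    for size in range(1, m + 1):
        feature_map.extend(itertools.combinations(idx, size))
    cols = np.empty((values.shape[0], len(feature_map)), dtype=float)
    for j, subset in enumerate(feature_map):
        cols[:, j] = np.prod(values[:, list(subset)], axis=1)
    return cols, feature_map


@dataclass
class SubClassifier:
    """Ridge regression of the 0/1 label on one interaction's product features."""

    interaction: tuple
    feature_map: list
    coefficients: np.ndarray
    intercept: float
    ridge_penalty: float

    def decision_values(self, matrix) -> np.ndarray:
        values = _as_values(matrix)
        feats = np.empty((values.shape[0], len(self.feature_map)), dtype=float)
        for j, subset in enumerate(self.feature_map):
            feats[:, j] = np.prod(values[:, list(subset)], axis=1)
        return feats @ self.coefficients + self.intercept

    def predict(self, matrix) -> np.ndarray:
        """Predict 1 iff the fitted value reaches 0.5."""
        return (self.decision_values(matrix) >= 0.5).astype(np.int8)


def fit_subclassifier(matrix, labels, interaction, cv_folds: int = 5,
                      seed: int = 0, sample_weight=None) -> SubClassifier:
    """Fit one ridge sub-classifier with an internally cross-validated penalty.

    The penalty is chosen from a 10-point log grid over [1e-3, 1e3] by
    ``cv_folds``-fold CV on squared error; when ``sample_weight`` is given
    (boosting), the coefficients are refit at that penalty with the weights.
    """
    labels = np.asarray(labels, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("training data contains a single class")
    feats, feature_map = expand_products(matrix, interaction)
    cv = max(2, min(cv_folds, len(labels)))
    selector = RidgeCV(alphas=RIDGE_ALPHAS, cv=cv,
                       scoring="neg_mean_squared_error")
    selector.fit(feats, labels)
    alpha = float(selector.alpha_)
    if sample_weight is not None:
        # keep the data-vs-penalty balance independent of the weights' scale
        sample_weight = np.asarray(sample_weight, dtype=float)
        sample_weight = sample_weight * (len(labels) / sample_weight.sum())
    model = Ridge(alpha=alpha)
    model.fit(feats, labels, sample_weight=sample_weight)
    return SubClassifier(
        interaction=tuple(sorted(int(i) for i in interaction)),
        feature_map=feature_map,
        coefficients=model.coef_.copy(),
        intercept=float(model.intercept_),
        ridge_penalty=alpha,
    )


@dataclass
class Ensemble:
    """Boosted collection of sub-classifiers with a weighted-vote decision."""

    members: list
    weights: list
    threshold: float = 0.5

    def decision_values(self, matrix) -> np.ndarray:
        """Weighted vote on the [0, 1] scale (fraction of weight voting 1)."""
        total = sum(self.weights)
        votes = np.zeros(_as_values(matrix).shape[0])
        for member, w in zip(self.members, self.weights):
            votes += w * member.predict(matrix)
        return votes / total

    def predict(self, matrix) -> np.ndarray:
        return (self.decision_values(matrix) >= self.threshold).astype(np.int8)


def boost_combine(matrix, labels, interactions, rounds: int | None = None,
                  seed: int = 0, cv_folds: int = 5) -> Ensemble:
    """AdaBoost-style combination of the interaction pool.

    Each round fits every remaining interaction's sub-classifier under the
    current sample weights, takes the one with the lowest weighted error
    ``eps``, gives it vote weight ``alpha = 0.5*log((1-eps)/eps)``, and
    reweights the samples multiplicatively.  Stops when the pool is
    exhausted or no remaining member beats chance (``eps >= 0.5``); if even
    the first member fails that bar, the single best sub-classifier is
    returned alone, with a warning.
    """
    interactions = sorted(tuple(sorted(i)) for i in interactions)
    if not interactions:
        raise ValueError("need at least one interaction")
    labels = np.asarray(labels)
    n = len(labels)
    w = np.full(n, 1.0 / n)
    pool = list(interactions)
    members, alphas = [], []
    max_rounds = len(pool) if rounds is None else min(rounds, len(pool))
    for _ in range(max_rounds):
        best = None
        for itx in pool:
            sc = fit_subclassifier(matrix, labels, itx, cv_folds=cv_folds,
                                   seed=seed, sample_weight=w)
            pred = sc.predict(matrix)
            eps = float(w[pred != labels].sum())
            if best is None or eps < best[0]:
                best = (eps, itx, sc, pred)
        eps, itx, sc, pred = best
        if eps >= 0.5:
            if not members:
                log.warning("no sub-classifier beats chance; "
                            "falling back to the single best one")
                members, alphas = [sc], [1.0]
            break
        eps_c = min(max(eps, 1e-12), 1.0 - 1e-12)  # eps = 0 -> large finite alpha
        alpha = 0.5 * math.log((1.0 - eps_c) / eps_c)
        members.append(sc)
        alphas.append(alpha)
        pool.remove(itx)
        agree = np.where(pred == labels, 1.0, -1.0)
        w = w * np.exp(-alpha * agree)
        w = w / w.sum()
    return Ensemble(members=members, weights=alphas)


@dataclass(frozen=True)
class Metrics:
    """Confusion counts with the derived proportions."""

    tp: int
    fp: int
    tn: int
    fn: int

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "Metrics":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        pos = self.tp + self.fn
        return self.tp / pos if pos else float("nan")

    @property
    def specificity(self) -> float:
        neg = self.tn + self.fp
        return self.tn / neg if neg else float("nan")

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
                "accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "specificity": self.specificity}


@dataclass
class CVResult:
    per_fold: list

    @property
    def accuracy(self) -> float:
        return float(np.mean([m.accuracy for m in self.per_fold]))

    @property
    def sensitivity(self) -> float:
        return float(np.mean([m.sensitivity for m in self.per_fold]))

    @property
    def specificity(self) -> float:
        return float(np.mean([m.specificity for m in self.per_fold]))

    def to_dict(self) -> dict:
        return {"per_fold": [m.to_dict() for m in self.per_fold],
                "average": {"accuracy": self.accuracy,
                            "sensitivity": self.sensitivity,
                            "specificity": self.specificity}}


def evaluate_cv(matrix, labels, fit_predict, folds: int = 5,
                seed: int = 0) -> CVResult:
    """Stratified k-fold evaluation of an arbitrary train-then-predict pipeline.

    ``fit_predict(train_matrix, train_labels)`` must return an object with a
    ``predict(matrix)`` method; the *entire* pipeline (screening, subset
    search, classifier construction) should live inside it so no information
    leaks from the held-out fold.
    """
    values = _as_values(matrix)
    labels = np.asarray(labels).astype(int)
    counts = np.bincount(labels, minlength=2)
    if counts.min() < folds:
        raise ValueError(f"each class needs >= {folds} samples for {folds}-fold CV")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    per_fold = []
    for train_idx, test_idx in skf.split(values, labels):
        model = fit_predict(values[train_idx], labels[train_idx])
        pred = model.predict(values[test_idx])
        per_fold.append(Metrics.from_predictions(labels[test_idx], pred))
    return CVResult(per_fold=per_fold)
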