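"""Recursive feature elimination with a linear-margin ranker and a forest ranker.

The elimination loop is the classic one: rank the surviving features
with the chosen model, drop the lowest-scoring ``step`` features,
re-rank on the survivors, and repeat until the target size is reached.
Two rankers are provided — squared weights of a linear soft-margin SVM,
and permutation importance of a random forest — plus a consensus rule
for combining their selected sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from .errors import ValidationError

logger = logging.getLogger(__name__)

Ranker = Callable[[np.ndarray, np.ndarray], np.ndarray]

_SVM_C = 1.0  # fixed regularization, recorded for reproducibility


def _check_matrix(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValidationError("feature matrix must be 2-dimensional")
    if len(y) != X.shape[0]:
        raise ValidationError("labels must match the number of rows")
    if np.isnan(X).any():
        raise ValidationError("feature matrix contains absent cells")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValidationError(f"exactly 2 classes required, got {len(classes)}")
    if counts.min() < 2:
        raise ValidationError("each class needs >= 2 samples")
    return X, y


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-standardize; returns (Z, constant_mask). Constant columns -> 0."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    constant = sd == 0
    sd = np.where(constant, 1.0, sd)
    Z = (X - mu) / sd
    Z[:, constant] = 0.0
    return Z, constant


def rank_features_linear_margin(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Squared weights of a linear soft-margin SVM fit on standardized features.

    Constant columns score 0 by convention.  Deterministic given the data.
    """
    X, y = _check_matrix(X, y)
    Z, constant = _standardize(X)
    model = SVC(kernel="linear", C=_SVM_C)
    model.fit(Z, y)
    scores = np.ravel(model.coef_) ** 2
    scores[constant] = 0.0
    return scores


def make_forest_ranker(
    n_trees: int = 200,
    seed: int = 0,
    importance: str = "impurity",
    n_repeats: int = 5,
) -> Ranker:
    """Random-forest ranker with a fixed seed, usable inside the RFE loop."""

    def ranker(X: np.ndarray, y: np.ndarray) -> np.ndarray:
        return rank_features_forest(
            X, y, n_trees=n_trees, seed=seed, importance=importance, n_repeats=n_repeats
        )

    return ranker


def rank_features_forest(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 200,
    seed: int = 0,
    importance: str = "impurity",
    n_repeats: int = 5,
) -> np.ndarray:
    """Feature importances from a seeded random forest.

    ``importance="impurity"`` (default) is the mean impurity decrease
    averaged over trees.  ``importance="permutation"`` is the mean
    training-accuracy drop over ``n_repeats`` shuffles per feature,
    evaluated in one batched forest prediction.
    """
    X, y = _check_matrix(X, y)
    if importance not in ("impurity", "permutation"):
        raise ValidationError(f"unknown importance kind '{importance}'")
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    forest.fit(X, y)
    if importance == "impurity":
        return forest.feature_importances_

    rng = np.random.default_rng(seed)
    n, p = X.shape
    baseline = (forest.predict(X) == y).mean()
    # stack every (feature, repeat) permuted copy into one predict call
    stacked = np.tile(X, (p * n_repeats, 1, 1))
    for f in range(p):
        for r in range(n_repeats):
            stacked[f * n_repeats + r, :, f] = X[rng.permutation(n), f]
    preds = forest.predict(stacked.reshape(-1, p)).reshape(p * n_repeats, n)
    acc = (preds == y[None, :]).mean(axis=1).reshape(p, n_repeats)
    return baseline - acc.mean(axis=1)


@dataclass
class SelectionResult:
    """Outcome of one RFE run (or a pair of runs plus their consensus)."""

    ranking: dict[str, int]  # feature -> rank, 1 = best (last eliminated)
    trace: list[list[str]]  # surviving feature sets, one per elimination round
    selected: list[str]
    target_size: int
    method: str = "rfe"
    consensus: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ranks = sorted(self.ranking.values())
        if ranks != list(range(1, len(ranks) + 1)):
            raise ValidationError("ranking must be a permutation of 1..n")
        for earlier, later in zip(self.trace, self.trace[1:]):
            if not set(later) <= set(earlier):
                raise ValidationError("trace subsets must be nested")


def recursive_eliminate(
    ranker: Ranker,
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Sequence[str],
    target_size: int,
    step: int = 1,
    method: str = "rfe",
) -> SelectionResult:
    """Rank, drop the weakest ``step`` features, re-rank; stop at ``target_size``.

    Score ties are broken by feature index (earlier index ranks better).
    Returns the nested trace of surviving subsets and a full 1..n ranking
    in which eliminated features rank in reverse elimination order.
    """
    X, y = _check_matrix(X, y)
    names = list(feature_names)
    if len(names) != X.shape[1]:
        raise ValidationError("feature_names must match the number of columns")
    if not 1 <= target_size <= X.shape[1]:
        raise ValidationError(
            f"target_size must lie in [1, {X.shape[1]}], got {target_size}"
        )
    if step < 1:
        raise ValidationError("step must be >= 1")

    surviving = np.arange(X.shape[1])
    eliminated: list[int] = []  # original column ids, in elimination order
    trace: list[list[str]] = []

    while len(surviving) > target_size:
        scores = np.asarray(ranker(X[:, surviving], y), dtype=float)
        n_drop = min(step, len(surviving) - target_size)
        # sort worst-first; ties resolved toward dropping the later index
        order = np.lexsort((-surviving, scores))
        drop_local = order[:n_drop]
        # within one round, record drops worst-first
        eliminated.extend(surviving[drop_local])
        keep = np.ones(len(surviving), dtype=bool)
        keep[drop_local] = False
        surviving = surviving[keep]
        trace.append([names[i] for i in surviving])

    final_scores = np.asarray(ranker(X[:, surviving], y), dtype=float)
    order = np.lexsort((surviving, -final_scores))  # best first, index breaks ties
    ranking: dict[str, int] = {}
    for rank, local in enumerate(order, start=1):
        ranking[names[surviving[local]]] = rank
    for offset, col in enumerate(reversed(eliminated)):
        ranking[names[col]] = len(surviving) + 1 + offset

    selected = sorted((names[i] for i in surviving), key=ranking.__getitem__)
    return SelectionResult(
        ranking=ranking,
        trace=trace,
        selected=selected,
        target_size=target_size,
        method=method,
    )


def consensus_select(
    result_a: SelectionResult | Sequence[str],
    result_b: SelectionResult | Sequence[str],
    mode: str = "intersection",
) -> list[str]:
    """Combine two selected sets; ordering is by best combined rank when known."""
    if mode not in ("intersection", "union"):
        raise ValidationError(f"unknown consensus mode '{mode}'")

    def _set(r):
        return set(r.selected) if isinstance(r, SelectionResult) else set(r)

    def _rank(r, f):
        if isinstance(r, SelectionResult):
            return r.ranking.get(f, len(r.ranking) + 1)
        return 0

    sa, sb = _set(result_a), _set(result_b)
    combined = sa & sb if mode == "intersection" else sa | sb
    if not combined:
        logger.warning("consensus set is empty (%s of disjoint selections)", mode)
    return sorted(
        combined, key=lambda f: (_rank(result_a, f) + _rank(result_b, f), f)
    )
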