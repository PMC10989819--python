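"""Marker identification: RF importance ranking + top-k NN-CV AUC sweep.

Features are ranked by random-forest *mean decrease accuracy*: per tree,
the drop in out-of-bag accuracy when one feature's OOB values are
permuted, averaged over permutations and trees.  The bagged ensemble is
built explicitly from decision trees so the out-of-bag sample of every
tree is known exactly; features a tree never splits on contribute an
exact zero for that tree.

The marker set is then defined by a wrapper sweep: for each k in a grid,
the NN classifier is cross-validated on the top-k ranked features (with
identical fold assignments across k, so the curve varies only with k),
and the smallest k maximising mean AUC wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .classifiers import (CVResult, NNSpec, _check_xy, _fold_metrics,
                          crossval_evaluate, make_folds, train)
from .metrics import MetricSet

logger = logging.getLogger(__name__)

#: default top-k grid for species-level profiles
SPECIES_K_GRID = tuple(range(5, 61, 5))
#: default top-k grid for gene-level profiles
GENE_K_GRID = tuple(range(5, 101, 5))


@dataclass
class ImportanceRanking:
    """Features ordered by decreasing importance (a permutation of the
    input feature set); ties broken lexicographically by feature id."""

    feature_ids: list[str]
    scores: list[float]
    tie_break: str = "lexicographic by feature_id"

    def __post_init__(self) -> None:
        if len(self.feature_ids) != len(self.scores):
            raise ValueError("feature_ids and scores length mismatch")
        if any(a < b for a, b in zip(self.scores, self.scores[1:])):
            raise ValueError("scores must be non-increasing")

    def top(self, k: int) -> list[str]:
        return self.feature_ids[:k]


def rank_features(X, y, feature_ids: list[str] | None = None,
                  n_trees: int = 500, n_permutations: int = 10,
                  seed: int = 0) -> ImportanceRanking:
    """Rank features by per-tree out-of-bag mean decrease accuracy.

    For each of ``n_trees`` bootstrap trees (sqrt(p) candidate features
    per split), the accuracy on the tree's out-of-bag samples is compared
    with the accuracy after permuting one feature's OOB column,
    ``n_permutations`` times.  The importance of a feature is the mean
    accuracy drop over permutations and trees.  A feature no tree splits
    on — e.g. a constant — has importance exactly 0.
    """
    X, y = _check_xy(X, y)
    n, p = X.shape
    if feature_ids is None:
        feature_ids = [f"f{j}" for j in range(p)]
    if len(feature_ids) != p:
        raise ValueError("feature_ids length must match n_features")
    rng = np.random.default_rng(seed)
    importance = np.zeros(p)
    sample_range = np.arange(n)
    for _ in range(n_trees):
        boot = rng.integers(0, n, n)
        oob = np.setdiff1d(sample_range, boot)
        if oob.size == 0:
            continue
        tree = DecisionTreeClassifier(max_features="sqrt",
                                      random_state=int(rng.integers(2 ** 31)))
        tree.fit(X[boot], y[boot])
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        if used.size == 0:
            continue
        X_oob, y_oob = X[oob], y[oob]
        n_oob = oob.size
        base_acc = float((tree.predict(X_oob) == y_oob).mean())
        for j in used:
            stacked = np.tile(X_oob, (n_permutations, 1))
            for r in range(n_permutations):
                stacked[r * n_oob:(r + 1) * n_oob, j] = \
                    X_oob[rng.permutation(n_oob), j]
            correct = (tree.predict(stacked) == np.tile(y_oob, n_permutations))
            perm_acc = correct.reshape(n_permutations, n_oob).mean(axis=1)
            importance[j] += base_acc - float(perm_acc.mean())
    importance /= n_trees
    order = sorted(range(p), key=lambda j: (-importance[j], feature_ids[j]))
    return ImportanceRanking(feature_ids=[feature_ids[j] for j in order],
                             scores=[float(importance[j]) for j in order])


@dataclass
class SweepResult:
    """AUC-vs-k curve and the selected marker set."""

    k_grid: list[int]
    mean_auc: list[float]
    sd_auc: list[float]
    selected_k: int
    markers: list[str]
    cv_results: dict[int, CVResult] | None = None

    def curve(self) -> list[tuple[int, float, float]]:
        return list(zip(self.k_grid, self.mean_auc, self.sd_auc))


def topk_sweep(ranking: ImportanceRanking, X, y,
               feature_ids: list[str] | None = None,
               k_grid=SPECIES_K_GRID, nn_spec: NNSpec | None = None,
               n_folds: int = 5, seed: int = 0,
               keep_cv_results: bool = False) -> SweepResult:
    """Cross-validated AUC of the NN on the top-k features, for each k.

    ``feature_ids`` gives the feature id of each column of X (defaults to
    the ranking's feature set in ranked order being the columns — only
    valid when X was already column-ordered by the ranking).  Fold
    assignments are drawn once from ``seed`` and shared across the whole
    grid, so the curve varies only with k.  The selected k is the
    smallest grid value attaining the maximal mean AUC; the marker set is
    the first selected_k features of the ranking.
    """
    k_grid = sorted(int(k) for k in k_grid)
    if not k_grid:
        raise ValueError("k_grid must be non-empty")
    X, y = _check_xy(X, y)
    if max(k_grid) > X.shape[1]:
        raise ValueError(f"max(k_grid)={max(k_grid)} exceeds "
                         f"{X.shape[1]} features")
    nn_spec = nn_spec or NNSpec(seed=seed)
    if feature_ids is None:
        feature_ids = list(ranking.feature_ids)
    col_of = {f: j for j, f in enumerate(feature_ids)}
    if set(col_of) != set(ranking.feature_ids) or len(col_of) != X.shape[1]:
        raise ValueError("ranking must be a permutation of the profile features")
    folds = make_folds(y, n_folds, seed)

    mean_auc, sd_auc, cv_store = [], [], {}
    for k in k_grid:
        cols = [col_of[f] for f in ranking.top(k)]
        res = crossval_evaluate(nn_spec, X[:, cols], y,
                                fold_assignments=folds)
        m, s = res.aggregated["auc"]
        mean_auc.append(m)
        sd_auc.append(s)
        if keep_cv_results:
            cv_store[k] = res
    best = max(range(len(k_grid)), key=lambda i: (mean_auc[i], -k_grid[i]))
    selected_k = k_grid[best]
    return SweepResult(k_grid=list(k_grid), mean_auc=mean_auc, sd_auc=sd_auc,
                       selected_k=selected_k, markers=ranking.top(selected_k),
                       cv_results=cv_store if keep_cv_results else None)


def evaluate_markers(markers: list[str], X_train, y_train, X_test, y_test,
                     train_feature_ids: list[str],
                     test_feature_ids: list[str],
                     spec=None) -> MetricSet:
    """Train on the training set restricted to the markers, score the test
    set, and return hard-label metrics plus AUC.

    A marker absent from either feature list is a hard error naming it.
    """
    spec = spec or NNSpec()
    for name, ids in (("train", train_feature_ids), ("test", test_feature_ids)):
        missing = [m for m in markers if m not in set(ids)]
        if missing:
            raise KeyError(f"marker {missing[0]!r} absent from {name} features")
    tr_cols = [train_feature_ids.index(m) for m in markers]
    te_cols = [test_feature_ids.index(m) for m in markers]
    X_train, y_train = _check_xy(np.asarray(X_train)[:, tr_cols], y_train)
    X_test = np.asarray(X_test, dtype=float)[:, te_cols]
    scaler = StandardScaler().fit(X_train)
    model = train(spec, scaler.transform(X_train), y_train)
    scores = model.score(scaler.transform(X_test))
    return _fold_metrics(np.asarray(y_test, dtype=int), scores)
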