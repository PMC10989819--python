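"""The lightweight dense NN classifier, four baselines, and the CV harness.

The NN is a small multilayer perceptron — two dense hidden layers of 16
and 8 ReLU nodes, L2 weight penalty, Adam optimiser, cross-entropy loss,
logistic output — sized for cohorts of a few hundred samples.  Baselines
(linear SVM, RBF SVM, random forest, k-nearest-neighbours) run behind
the same contract: ``train`` returns a fitted handle whose ``score``
emits probability-like values oriented so that higher means more
case-like.

Cross-validation is stratified five-fold by default; per-feature
standardisation statistics are computed on the training folds only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import metrics as _metrics
from .metrics import ConfusionCounts, MetricSet
from .profiles_io import AbundanceProfile, PairedDataset, SampleMetadata

logger = logging.getLogger(__name__)

FAMILIES = ("nn", "svm_linear", "svm_rbf", "random_forest", "knn")


@dataclass
class NNSpec:
    """Architecture and training setup of the dense NN.

    ``loss`` selects the task: cross_entropy trains a classifier with a
    logistic-squashed single output node; mean_square_error trains a
    regressor whose single output node has no activation.
    """

    hidden_sizes: tuple[int, ...] = (16, 8)
    activation: str = "relu"
    l2_lambda: float = 1e-4
    loss: str = "cross_entropy"
    learning_rate: float = 1e-3
    epochs: int = 200
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.hidden_sizes or any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden_sizes must be non-empty positive integers")
        if self.l2_lambda < 0:
            raise ValueError("l2_lambda must be >= 0")
        if self.loss not in ("cross_entropy", "mean_square_error"):
            raise ValueError(f"unknown loss {self.loss!r}")


@dataclass
class ClassifierSpec:
    """A classifier family with its hyperparameters.

    Defaults: SVM regularisation C=1.0; RBF width gamma = 1 /
    (n_features * Var(X)); 500 trees; 5 neighbours.
    """

    family: str = "nn"
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown classifier family {self.family!r}; "
                             f"choose from {FAMILIES}")


def _build_estimator(spec):
    if isinstance(spec, NNSpec):
        cls = MLPClassifier if spec.loss == "cross_entropy" else MLPRegressor
        return cls(hidden_layer_sizes=tuple(spec.hidden_sizes),
                   activation=spec.activation, solver="adam",
                   alpha=spec.l2_lambda, learning_rate_init=spec.learning_rate,
                   max_iter=spec.epochs, batch_size=spec.batch_size,
                   random_state=spec.seed)
    p = spec.params
    if spec.family == "nn":
        return _build_estimator(NNSpec(seed=spec.seed, **p))
    if spec.family == "svm_linear":
        return SVC(kernel="linear", C=p.get("C", 1.0), random_state=spec.seed)
    if spec.family == "svm_rbf":
        return SVC(kernel="rbf", C=p.get("C", 1.0), gamma=p.get("gamma", "scale"),
                   random_state=spec.seed)
    if spec.family == "random_forest":
        return RandomForestClassifier(n_estimators=p.get("n_trees", 500),
                                      random_state=spec.seed)
    if spec.family == "knn":
        return KNeighborsClassifier(n_neighbors=p.get("n_neighbors", 5))
    raise AssertionError(spec.family)


@dataclass
class FittedModel:
    """A fitted classifier exposing case-oriented scores."""

    estimator: object

    def score(self, X) -> np.ndarray:
        """Probability-like scores in [0, 1]; higher = more case-like."""
        X = np.asarray(X, dtype=float)
        est = self.estimator
        if hasattr(est, "predict_proba"):
            proba = est.predict_proba(X)
            case_col = list(est.classes_).index(1)
            return proba[:, case_col]
        # margin classifiers: logistic squash of the signed distance
        margin = est.decision_function(X)
        return 1.0 / (1.0 + np.exp(-margin))


def _check_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains non-finite values")
    classes = np.unique(y)
    if set(classes.tolist()) - {0, 1}:
        raise ValueError("labels must be binary {0, 1}")
    if classes.size < 2:
        raise ValueError("labels contain a single class; need both")
    return X, y.astype(int)


def train(spec, X, y) -> FittedModel:
    """Fit a classifier; deterministic given the spec's seed."""
    X, y = _check_xy(X, y)
    est = _build_estimator(spec)
    est.fit(X, y)
    return FittedModel(est)


@dataclass
class CVResult:
    """Cross-validation output: folds partition the samples and every
    sample is scored exactly once out-of-fold."""

    fold_assignments: np.ndarray          # fold index per sample
    per_fold: list[MetricSet]
    aggregated: dict[str, tuple[float, float]]   # metric -> (mean, sd)
    oof_scores: np.ndarray                # out-of-fold score per sample

    @property
    def mean_auc(self) -> float:
        return self.aggregated["auc"][0]


def make_folds(y, n_folds: int, seed: int) -> np.ndarray:
    """Stratified random fold assignment (one fold index per sample)."""
    y = np.asarray(y)
    for cls in np.unique(y):
        if (y == cls).sum() < n_folds:
            raise ValueError(
                f"class {cls} has fewer samples than n_folds={n_folds}")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignment = np.empty(y.size, dtype=int)
    for k, (_, test_idx) in enumerate(skf.split(np.zeros((y.size, 1)), y)):
        assignment[test_idx] = k
    return assignment


def _fold_metrics(y_true, scores, threshold: float = 0.5) -> MetricSet:
    pred = (np.asarray(scores) >= threshold).astype(int)
    y_true = np.asarray(y_true)
    counts = ConfusionCounts(tp=int(((pred == 1) & (y_true == 1)).sum()),
                             fp=int(((pred == 1) & (y_true == 0)).sum()),
                             tn=int(((pred == 0) & (y_true == 0)).sum()),
                             fn=int(((pred == 0) & (y_true == 1)).sum()))
    ms = _metrics.classification_metrics(counts)
    ms.roc_points, ms.auc = _metrics.roc_auc(y_true, scores)
    return ms


def crossval_evaluate(spec, X, y, n_folds: int = 5, seed: int = 0,
                      fold_assignments: np.ndarray | None = None,
                      standardize: bool = True) -> CVResult:
    """Stratified k-fold cross-validation of one classifier.

    Standardisation (z-score per feature) is fit on the training folds
    and applied to the held-out fold.  Hard-label metrics use a score
    threshold of 0.5.  Precomputed ``fold_assignments`` let callers
    share identical folds across runs (e.g. across a top-k sweep).
    """
    X, y = _check_xy(X, y)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    folds = (np.asarray(fold_assignments) if fold_assignments is not None
             else make_folds(y, n_folds, seed))
    n_folds = int(folds.max()) + 1
    per_fold: list[MetricSet] = []
    oof = np.full(y.size, np.nan)
    for k in range(n_folds):
        test = folds == k
        train_idx = ~test
        X_tr, X_te = X[train_idx], X[test]
        if standardize:
            scaler = StandardScaler().fit(X_tr)
            X_tr, X_te = scaler.transform(X_tr), scaler.transform(X_te)
        model = train(spec, X_tr, y[train_idx])
        scores = model.score(X_te)
        oof[test] = scores
        per_fold.append(_fold_metrics(y[test], scores))
    assert not np.isnan(oof).any(), "every sample must be scored out-of-fold"
    return CVResult(fold_assignments=folds, per_fold=per_fold,
                    aggregated=_metrics.aggregate_folds(per_fold),
                    oof_scores=oof)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass
class HoldoutSplit:
    """Disjoint train/test sets from the control-donation construction."""

    train: PairedDataset
    test: PairedDataset
    moved_control_ids: list[str]


def make_holdout_split(case_profile: AbundanceProfile,
                       control_pool: AbundanceProfile,
                       control_fraction: float = 0.3, seed: int = 0,
                       train_cases: AbundanceProfile | None = None
                       ) -> HoldoutSplit:
    """Build an independent test set by donating controls to external cases.

    ``case_profile`` holds external case samples that lack matched
    controls; round(control_fraction * n_controls) controls (round half
    up) are drawn from ``control_pool`` without replacement and moved
    into the test set alongside all external cases.  The remaining
    controls — plus ``train_cases`` if given — form the training set.
    Train and test sample sets are disjoint by construction.
    """
    if not 0.0 < control_fraction < 1.0:
        raise ValueError("control_fraction must be in (0, 1)")
    if case_profile.feature_ids != control_pool.feature_ids:
        raise ValueError("case profile and control pool must share features")
    n_controls = control_pool.n_samples
    n_move = _round_half_up(control_fraction * n_controls)
    if n_move == 0:
        raise ValueError(
            f"control_fraction={control_fraction} moves zero of "
            f"{n_controls} controls")
    rng = np.random.default_rng(seed)
    moved_idx = sorted(rng.choice(n_controls, size=n_move, replace=False).tolist())
    moved_ids = [control_pool.sample_ids[i] for i in moved_idx]
    kept_ids = [s for s in control_pool.sample_ids if s not in set(moved_ids)]

    def _pair(profile: AbundanceProfile, label: int) -> list[SampleMetadata]:
        return [SampleMetadata(sample_id=s, label=label)
                for s in profile.sample_ids]

    test_profile = _stack(case_profile, control_pool.subset_samples(moved_ids))
    test_meta = _pair(case_profile, 1) + _pair(
        control_pool.subset_samples(moved_ids), 0)

    kept = control_pool.subset_samples(kept_ids)
    if train_cases is not None:
        if train_cases.feature_ids != control_pool.feature_ids:
            raise ValueError("train_cases must share features with the pool")
        train_profile = _stack(train_cases, kept)
        train_meta = _pair(train_cases, 1) + _pair(kept, 0)
    else:
        train_profile, train_meta = kept, _pair(kept, 0)
    logger.info("holdout split: moved %d of %d controls to the test set",
                n_move, n_controls)
    return HoldoutSplit(train=PairedDataset(train_profile, train_meta),
                        test=PairedDataset(test_profile, test_meta),
                        moved_control_ids=moved_ids)


def _stack(a: AbundanceProfile, b: AbundanceProfile) -> AbundanceProfile:
    return AbundanceProfile(list(a.sample_ids) + list(b.sample_ids),
                            list(a.feature_ids),
                            np.vstack([a.values, b.values]))
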