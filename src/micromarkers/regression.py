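"""NN regression of clinical covariates from marker abundances.

The regressor reuses the classifier architecture (dense 16 + 8 ReLU
hidden layers, L2 penalty, Adam) with a single linear output node and
mean-square-error loss.  Each covariate is predicted out-of-fold by
k-fold cross-validation and compared with the observed values by
Pearson correlation; covariates are then ranked by the significance of
that correlation, the top one being reported as the leading factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler

from .classifiers import NNSpec, _build_estimator

logger = logging.getLogger(__name__)


@dataclass
class RegressionResult:
    """Out-of-fold regression quality for one covariate."""

    covariate: str
    predictions: np.ndarray     # aligned to input samples; NaN where dropped
    r: float
    p: float
    n_used: int


def regression_spec(base: NNSpec | None = None, seed: int = 0) -> NNSpec:
    """The classifier architecture with a linear output and MSE loss."""
    base = base or NNSpec(seed=seed)
    return replace(base, loss="mean_square_error")


def crossval_regress(X, cov, nn_spec: NNSpec | None = None,
                     n_folds: int = 5, seed: int = 0) -> np.ndarray:
    """Out-of-fold NN predictions of a numeric covariate.

    Samples with a missing (NaN) covariate are dropped with a log
    message; every retained sample is predicted exactly once.  The
    covariate is standardised on the training folds and predictions are
    mapped back to its original units.  Returns a vector aligned to the
    input samples, NaN at dropped positions.
    """
    X = np.asarray(X, dtype=float)
    cov = np.asarray(cov, dtype=float)
    if X.shape[0] != cov.size:
        raise ValueError("X and cov must have the same number of samples")
    keep = np.isfinite(cov)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("dropping %d sample(s) with missing covariate", n_drop)
    Xk, ck = X[keep], cov[keep]
    if ck.size < 2 * n_folds:
        raise ValueError(f"need >= {2 * n_folds} samples with a finite "
                         f"covariate, got {ck.size}")
    if np.ptp(ck) == 0:
        raise ValueError("covariate is constant; regression is undefined")
    if not np.isfinite(Xk).all():
        raise ValueError("feature matrix contains non-finite values")
    spec = regression_spec(nn_spec, seed=seed)
    preds = np.full(cov.size, np.nan)
    keep_idx = np.flatnonzero(keep)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for tr, te in kf.split(Xk):
        xsc = StandardScaler().fit(Xk[tr])
        c_mu, c_sd = float(ck[tr].mean()), float(ck[tr].std())
        if c_sd == 0:
            raise ValueError("covariate constant within a training fold")
        est = _build_estimator(spec)
        est.fit(xsc.transform(Xk[tr]), (ck[tr] - c_mu) / c_sd)
        preds[keep_idx[te]] = est.predict(xsc.transform(Xk[te])) * c_sd + c_mu
    return preds


def correlate(pred, real) -> tuple[float, float]:
    """Pearson r and its two-sided p-value (t-distribution, n-2 df).

    NaN pairs are excluded; constant vectors and n < 3 are hard errors.
    """
    pred = np.asarray(pred, dtype=float)
    real = np.asarray(real, dtype=float)
    keep = np.isfinite(pred) & np.isfinite(real)
    pred, real = pred[keep], real[keep]
    if pred.size < 3:
        raise ValueError("need at least 3 finite pairs")
    if np.ptp(pred) == 0 or np.ptp(real) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = stats.pearsonr(pred, real)
    return float(res.statistic), float(res.pvalue)


def regress_covariates(X, covariates: dict[str, np.ndarray],
                       nn_spec: NNSpec | None = None, n_folds: int = 5,
                       seed: int = 0) -> list[RegressionResult]:
    """Cross-validated regression + correlation for several covariates."""
    results = []
    for name, values in covariates.items():
        preds = crossval_regress(X, values, nn_spec=nn_spec,
                                 n_folds=n_folds, seed=seed)
        r, p = correlate(preds, values)
        results.append(RegressionResult(
            covariate=name, predictions=preds, r=r, p=p,
            n_used=int(np.isfinite(preds).sum())))
    return results


def rank_covariates(results: list[RegressionResult]) -> list[RegressionResult]:
    """Order covariates by ascending p (ties by descending |r|); the first
    entry is the leading factor."""
    if not results:
        raise ValueError("no regression results to rank")
    return sorted(results, key=lambda res: (res.p, -abs(res.r)))
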