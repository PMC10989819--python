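"""Covariate-quantile stratification and per-feature group testing.

Samples are binned by quantiles of a clinical covariate (FBG quartiles
by default); per-bin mean marker abundances are min-max normalised per
feature to [0, 1], producing the heat-map matrix of marker dynamics
along the covariate.  Per-feature case/control differences are scored
with the Kruskal-Wallis rank test (tie-corrected H, chi-square p) and
classed as higher-in-case, higher-in-control or not-significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .profiles_io import AbundanceProfile

logger = logging.getLogger(__name__)

SIG_CASE = "higher-in-case"
SIG_CONTROL = "higher-in-control"
NOT_SIG = "not-significant"


def quantile_bins(values, probs=(0.25, 0.5, 0.75)) -> tuple[np.ndarray, np.ndarray]:
    """Quantile boundaries (linear interpolation) and bin assignments.

    Bin k is the half-open interval [b_{k-1}, b_k); the last bin is
    closed above, so every sample lands in exactly one of len(probs)+1
    bins (0-based indices).  All-identical values are a hard error.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4 or not np.isfinite(values).all():
        raise ValueError("need at least 4 finite values")
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 1 or probs.size == 0 or (np.diff(probs) <= 0).any() \
            or probs.min() <= 0 or probs.max() >= 1:
        raise ValueError("probs must be strictly increasing within (0, 1)")
    if np.ptp(values) == 0:
        raise ValueError("all values identical; no bins possible")
    boundaries = np.quantile(values, probs)  # linear interpolation
    # value == boundary belongs to the upper bin (half-open convention)
    assignments = np.searchsorted(boundaries, values, side="right")
    return boundaries, assignments


def binned_means(profile: AbundanceProfile, assignments) -> pd.DataFrame:
    """Feature x bin matrix of mean abundances; empty bins are an error."""
    assignments = np.asarray(assignments, dtype=int)
    if assignments.size != profile.n_samples:
        raise ValueError("assignments must cover every sample")
    n_bins = int(assignments.max()) + 1
    cols = {}
    for b in range(n_bins):
        mask = assignments == b
        if not mask.any():
            raise ValueError(f"bin Q{b + 1} is empty")
        cols[f"Q{b + 1}"] = profile.values[mask].mean(axis=0)
    return pd.DataFrame(cols, index=profile.feature_ids)


def minmax_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-row (x - min) / (max - min) to [0, 1]; constant rows map to
    all zeros with a warning."""
    values = matrix.to_numpy(dtype=float)
    lo = values.min(axis=1, keepdims=True)
    span = values.max(axis=1, keepdims=True) - lo
    flat = span[:, 0] == 0
    if flat.any():
        logger.warning("%d constant row(s) normalised to all zeros",
                       int(flat.sum()))
    span[flat] = 1.0
    out = (values - lo) / span
    out[flat.nonzero()[0], :] = 0.0
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def kruskal_wallis_per_feature(profile: AbundanceProfile, labels,
                               alpha: float = 0.05,
                               correction: str = "none") -> pd.DataFrame:
    """Per-feature Kruskal-Wallis case/control test.

    Returns a DataFrame indexed by feature id with columns H, p and
    ``significance`` — higher-in-case / higher-in-control when p < alpha
    (direction from the case-vs-control mean-rank difference), else
    not-significant.  A feature constant across all samples has H = 0,
    p = 1.

    Raw per-feature p-values are compared with ``alpha`` by default
    (the usual per-feature colouring convention);
    ``correction="benjamini-hochberg"`` instead thresholds
    FDR-adjusted p-values and adds a ``p_adjusted`` column.
    """
    if correction not in ("none", "benjamini-hochberg"):
        raise ValueError(f"unknown correction {correction!r}")
    labels = np.asarray(labels, dtype=int)
    if labels.size != profile.n_samples:
        raise ValueError("labels must cover every sample")
    case = labels == 1
    if case.sum() < 2 or (~case).sum() < 2:
        raise ValueError("both groups need at least 2 samples")
    rows = []
    for j, fid in enumerate(profile.feature_ids):
        x = profile.values[:, j]
        if np.ptp(x) == 0:
            rows.append((fid, 0.0, 1.0, 0.0))
            continue
        h, p = stats.kruskal(x[case], x[~case])
        ranks = stats.rankdata(x)
        direction = ranks[case].mean() - ranks[~case].mean()
        rows.append((fid, float(h), float(p), float(direction)))
    out = pd.DataFrame(rows, columns=["feature_id", "H", "p", "_direction"]
                       ).set_index("feature_id")
    decisive_p = out["p"]
    if correction == "benjamini-hochberg":
        out["p_adjusted"] = stats.false_discovery_control(out["p"], method="bh")
        decisive_p = out["p_adjusted"]
    out["significance"] = np.where(
        decisive_p >= alpha, NOT_SIG,
        np.where(out["_direction"] > 0, SIG_CASE, SIG_CONTROL))
    return out.drop(columns="_direction")


@dataclass
class StratifiedMatrix:
    """The heat-map product: normalised per-bin means + significance."""

    feature_ids: list[str]
    bin_labels: list[str]
    boundaries: np.ndarray
    matrix: pd.DataFrame                # feature x bin, entries in [0, 1]
    significance: pd.DataFrame          # per-feature H, p, class


def stratify(profile: AbundanceProfile, covariate, labels,
             probs=(0.25, 0.5, 0.75), alpha: float = 0.05) -> StratifiedMatrix:
    """Full stratification pipeline: quantile bins of the covariate,
    per-bin mean abundances, per-feature [0, 1] normalisation, and
    Kruskal-Wallis significance classes."""
    boundaries, assignments = quantile_bins(covariate, probs)
    means = binned_means(profile, assignments)
    normalised = minmax_rows(means)
    sig = kruskal_wallis_per_feature(profile, labels, alpha=alpha)
    return StratifiedMatrix(feature_ids=list(profile.feature_ids),
                            bin_labels=list(means.columns),
                            boundaries=boundaries, matrix=normalised,
                            significance=sig)
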