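"""Per-cancer comparator analyses and evaluation metrics.

Two separate-analysis baselines: Type I ranks sites by their p-values within
each cancer and calls DM by Benjamini-Hochberg; Type II fits a two-component
normal mixture (empirical null vs alternative) to each cancer's z-values and
ranks by the posterior non-null probability.  Evaluation helpers cover
K-means clustering of binary call patterns, row-normalized pattern-matching
(confusion) matrices, true positives among top-ranked sites, and the set of
sites found only by the joint model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multitest import multipletests

from .inference import _pooled_calls
from .matrices import PValueMatrix, ZMatrix
from .model import SIGMA_MIN
from .simulate import SimTruth

__all__ = [
    "SeparateCalls",
    "separate_type1",
    "separate_type2",
    "kmeans_patterns",
    "pattern_matching_matrix",
    "tp_at_top_n",
    "pandm_specific_dmc",
]


@dataclass
class SeparateCalls:
    """Output of one per-cancer baseline.

    ``rho`` holds binary DM indicators; ``scores`` the per-cancer ranking
    statistic (p-values for Type I, posterior non-null probabilities for
    Type II); ``score_ascending`` says whether smaller scores rank higher.
    """

    rho: np.ndarray           # (G, C) binary
    scores: np.ndarray        # (G, C), NaN at missing entries
    method: str               # "type1" | "type2"
    score_ascending: bool
    column_params: list | None = None


def separate_type1(p: PValueMatrix, level: float = 0.01) -> SeparateCalls:
    """Type I separate analysis: rank by p-value, call by per-cancer BH."""
    values, mask = p.values, p.observed_mask
    rho = np.zeros(values.shape, dtype=int)
    for c in range(values.shape[1]):
        obs = mask[:, c]
        if obs.any():
            reject, *_ = multipletests(values[obs, c], alpha=level,
                                       method="fdr_bh")
            rho[obs, c] = reject.astype(int)
    scores = np.where(mask, values, np.nan)
    return SeparateCalls(rho=rho, scores=scores, method="type1",
                         score_ascending=True)


def separate_type2(Z: ZMatrix, seed: int = 0, level: float = 0.01
                   ) -> SeparateCalls:
    """Type II separate analysis: per-cancer two-component normal mixture.

    The lower-mean component is the alternative (DM) per the p-to-z
    convention; scores are posterior non-null probabilities and calls control
    the global FDR column-wise by thresholding the local fdr (1 - score).
    """
    values, mask = Z.values, Z.observed_mask
    G, C = values.shape
    scores = np.full((G, C), np.nan)
    rho = np.zeros((G, C), dtype=int)
    column_params = []
    for c in range(C):
        obs = mask[:, c]
        col = values[obs, c]
        gm = GaussianMixture(n_components=2, covariance_type="diag",
                             random_state=seed, max_iter=2000, tol=1e-7,
                             reg_covar=SIGMA_MIN ** 2)
        gm.fit(col[:, None])
        if not gm.converged_:
            warnings.warn(f"column {c}: mixture EM did not converge",
                          RuntimeWarning)
        means = gm.means_.ravel()
        alt = int(np.argmin(means))
        post_alt = gm.predict_proba(col[:, None])[:, alt]
        scores[obs, c] = post_alt
        tau, _ = _pooled_calls(1.0 - post_alt, level)
        rho[obs, c] = (1.0 - post_alt <= tau).astype(int)
        column_params.append({
            "weight_alt": float(gm.weights_[alt]),
            "mu1": float(means[alt]),
            "sigma1": float(np.sqrt(gm.covariances_.ravel()[alt])),
            "mu0": float(means[1 - alt]),
            "sigma0": float(np.sqrt(gm.covariances_.ravel()[1 - alt])),
            "converged": bool(gm.converged_),
        })
    return SeparateCalls(rho=rho, scores=scores, method="type2",
                         score_ascending=False, column_params=column_params)


def kmeans_patterns(rho: np.ndarray, K: int, seed: int = 0
                    ) -> tuple[np.ndarray, np.ndarray]:
    """K-means on binary per-site call patterns; returns 1-based labels and
    the K x C matrix of per-cluster mean call rates."""
    rho = np.asarray(rho, dtype=float)
    if K < 1:
        raise ValueError("K must be >= 1")
    if K == 1:
        return np.ones(rho.shape[0], dtype=int), rho.mean(axis=0)[None, :]
    km = KMeans(n_clusters=K, n_init=10, random_state=seed)
    labels = km.fit_predict(rho)
    return labels + 1, km.cluster_centers_


def pattern_matching_matrix(true_labels, fitted_labels, K_true: int,
                            K_fit: int) -> np.ndarray:
    """Row-normalized confusion matrix between 1-based label vectors.

    Entry (k, l) is the fraction of true-cluster-k sites assigned to fitted
    cluster l; rows of empty true clusters are NaN (with a warning).
    """
    t = np.asarray(true_labels, dtype=int)
    f = np.asarray(fitted_labels, dtype=int)
    if t.min() < 1 or t.max() > K_true or f.min() < 1 or f.max() > K_fit:
        raise ValueError("labels out of range for the declared cluster counts")
    counts = np.zeros((K_true, K_fit))
    np.add.at(counts, (t - 1, f - 1), 1.0)
    totals = counts.sum(axis=1, keepdims=True)
    empty = totals.ravel() == 0
    if empty.any():
        warnings.warn(f"empty true cluster(s): {np.flatnonzero(empty) + 1}",
                      RuntimeWarning)
    with np.errstate(invalid="ignore"):
        return counts / totals


def tp_at_top_n(scores: np.ndarray, truth: SimTruth, n_grid,
                score_ascending: bool = True) -> np.ndarray:
    """True positives among the n best-ranked sites, per cancer.

    Returns a C x len(n_grid) count matrix.  Ranking is by score (ascending
    for p-value-like scores, descending for posterior-probability scores)
    with ties broken by site index via stable sort.
    """
    scores = np.asarray(scores, dtype=float)
    n_grid = list(n_grid)
    if max(n_grid) > scores.shape[0]:
        raise ValueError("n exceeds the number of sites")
    out = np.zeros((scores.shape[1], len(n_grid)), dtype=int)
    for c in range(scores.shape[1]):
        key = scores[:, c] if score_ascending else -scores[:, c]
        key = np.where(np.isnan(key), np.inf, key)  # missing ranks last
        order = np.argsort(key, kind="stable")
        hits = np.cumsum(truth.H[order, c])
        out[c] = [hits[n - 1] for n in n_grid]
    return out


def pandm_specific_dmc(pandm_calls, separate_calls: SeparateCalls
                       ) -> list[np.ndarray]:
    """Per cancer, the (0-based) site indices called DM by the joint model
    but not by the separate analysis."""
    joint = np.asarray(getattr(pandm_calls, "calls", pandm_calls), dtype=int)
    rho = separate_calls.rho
    if joint.shape != rho.shape:
        raise ValueError("call matrices must have matching shapes")
    return [np.flatnonzero((joint[:, c] == 1) & (rho[:, c] == 0))
            for c in range(joint.shape[1])]
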