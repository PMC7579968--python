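"""From a fitted model to cluster assignments, fdrs, and DM calls.

A site's local fdr in cancer c is the posterior probability that it is null
there, fdr_gc = 1 - Pr(H_gc = 1 | Z, fitted params).  The global FDR at a
local-fdr cutoff tau is the mean local fdr among entries at or below tau,
pooled over sites and cancers; DM is called at the largest cutoff whose
global FDR stays within the target level.  Pattern rows and cancer types can
be ordered by complete-linkage hierarchical clustering for display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .model import PanDMParams, Posteriors

__all__ = [
    "DMCalls",
    "assign_clusters",
    "local_fdr",
    "call_dm",
    "pattern_ordering",
    "sample_fitted_mixture",
]


@dataclass
class DMCalls:
    """FDR-controlled DM calls.

    calls[g, c] = 1 iff entry (g, c) is observed and its local fdr is at or
    below the selected cutoff ``tau``; ``achieved_fdr`` is the estimated
    global FDR of the called set (0 when nothing is called).
    """

    calls: np.ndarray       # (G, C) binary
    fdr_local: np.ndarray   # (G, C), NaN at missing entries
    tau: float
    level: float
    achieved_fdr: float


def assign_clusters(post: Posteriors, Q: np.ndarray | None = None
                    ) -> tuple[np.ndarray, np.ndarray | None]:
    """Hard pattern assignment: 1-based argmax of the membership posterior.

    Ties go to the lowest cluster index.  If the fitted pattern matrix ``Q``
    is given, the matching pattern row of each site is returned alongside.
    """
    labels = post.membership.argmax(axis=1) + 1
    rows = None if Q is None else np.asarray(Q)[labels - 1]
    return labels, rows


def local_fdr(post: Posteriors, observed_mask: np.ndarray | None = None
              ) -> np.ndarray:
    """Local fdr matrix, 1 - Pr(DM); NaN where the input was missing."""
    fdr = 1.0 - post.dm_prob
    if observed_mask is not None:
        fdr = np.where(observed_mask, fdr, np.nan)
    return fdr


def _pooled_calls(fdr_flat: np.ndarray, level: float) -> tuple[float, float]:
    """Largest cutoff tau among the observed fdr values whose running mean
    stays within ``level``; returns (tau, achieved FDR)."""
    order = np.sort(fdr_flat)
    running_mean = np.cumsum(order) / np.arange(1, order.size + 1)
    # evaluate each distinct fdr value at its last occurrence, so ties are
    # called (or rejected) as a block
    last_of_value = np.flatnonzero(np.diff(order, append=np.inf) != 0)
    ok = running_mean[last_of_value] <= level
    if not ok.any():
        return -np.inf, 0.0
    idx = last_of_value[np.flatnonzero(ok)[-1]]
    return float(order[idx]), float(running_mean[idx])


def call_dm(fdr_local: np.ndarray, level: float,
            scope: str = "pooled") -> DMCalls:
    """Call DM entries by thresholding local fdrs at a global FDR level.

    ``scope='pooled'`` applies one cutoff across all cancers (the default);
    ``scope='per-cancer'`` repeats the rule column by column.  Missing
    entries (NaN) never enter the sums and are never called.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level!r}")
    fdr_local = np.asarray(fdr_local, dtype=float)
    observed = ~np.isnan(fdr_local)
    calls = np.zeros(fdr_local.shape, dtype=int)

    if scope == "pooled":
        flat = fdr_local[observed]
        tau, achieved = _pooled_calls(flat, level) if flat.size else (-np.inf, 0.0)
        calls[observed & (fdr_local <= tau)] = 1
    elif scope == "per-cancer":
        taus, achs, weights = [], [], []
        for c in range(fdr_local.shape[1]):
            col = fdr_local[observed[:, c], c]
            t, a = _pooled_calls(col, level) if col.size else (-np.inf, 0.0)
            calls[observed[:, c] & (fdr_local[:, c] <= t), c] = 1
            taus.append(t)
            achs.append(a)
            weights.append(calls[:, c].sum())
        tau = float(np.max(taus)) if taus else -np.inf
        total = sum(weights)
        achieved = (sum(a * w for a, w in zip(achs, weights)) / total
                    if total else 0.0)
    else:
        raise ValueError("scope must be 'pooled' or 'per-cancer'")
    return DMCalls(calls=calls, fdr_local=fdr_local, tau=tau, level=level,
                   achieved_fdr=achieved)


def _leaf_order(points: np.ndarray) -> np.ndarray:
    if points.shape[0] < 2:
        return np.arange(points.shape[0])
    return leaves_list(linkage(pdist(points), method="complete"))


def pattern_ordering(Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Leaf orders of complete-linkage, Euclidean-distance clusterings of the
    pattern rows and of the cancer columns of Q (0-based indices)."""
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    return _leaf_order(Q), _leaf_order(Q.T)


def sample_fitted_mixture(params: PanDMParams, n: int, seed: int = 0
                          ) -> np.ndarray:
    """Draw n values per cancer from the fitted marginal mixture.

    For each draw, a pattern k is sampled from pi, DM status from Ber(q_kc),
    and z from the matching normal component; returns an (n, C) array.  Used
    as a goodness-of-fit diagnostic: compare sorted samples against sorted
    observed z-values (Q-Q).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    params.validate()
    rng = np.random.default_rng(seed)
    k = rng.choice(params.K, size=n, p=params.pi)
    h = rng.random((n, params.C)) < params.Q[k]
    mu = np.where(h, params.mu1, params.mu0)
    sigma = np.where(h, params.sigma1, params.sigma0)
    return rng.normal(mu, sigma)


def qq_pairs(samples: np.ndarray, data_column: np.ndarray
             ) -> tuple[np.ndarray, np.ndarray]:
    """Paired sorted quantiles of model samples vs an observed data column,
    interpolated onto a common probability grid."""
    data = np.asarray(data_column, dtype=float)
    data = data[~np.isnan(data)]
    probs = (np.arange(1, min(samples.size, data.size) + 1) - 0.5) / \
        min(samples.size, data.size)
    return (np.quantile(samples, probs), np.quantile(data, probs))
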