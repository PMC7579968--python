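"""Pattern-number selection by the Bayesian information criterion.

A model with K patterns spends K - 1 free mixture proportions, K*C pattern
probabilities and 4*C emission parameters, so
BIC(K) = -2 ln L_obs + (K - 1 + K*C + 4*C) ln G.  Every candidate K is fitted
independently (no warm starts across the grid, so BIC comparisons carry no
path dependence) and the smallest BIC wins; ties break toward smaller K.
"""

from __future__ import annotations

import numpy as np

from .model import FitRecord, bic_value, fit_em

__all__ = ["bic", "select_k"]


def bic(loglik: float, K: int, C: int, G: int) -> float:
    """BIC of a fitted model: -2 loglik + (K - 1 + K*C + 4*C) ln G."""
    if min(G, C, K) < 1:
        raise ValueError("G, C and K must all be >= 1")
    return bic_value(loglik, K, C, G)


def select_k(Z, k_grid, tol: float = 1e-4, max_iter: int = 1000,
             n_restarts: int = 1, seed: int = 0,
             ) -> tuple[FitRecord, list[FitRecord]]:
    """Fit every K in ``k_grid`` and return (best record, all records).

    The best record minimizes BIC; on ties the smaller K is kept.  Fit errors
    are re-raised annotated with the offending K.
    """
    k_grid = sorted(int(k) for k in k_grid)
    if not k_grid or k_grid[0] < 1:
        raise ValueError("k_grid must be a non-empty list of integers >= 1")
    records: list[FitRecord] = []
    for K in k_grid:
        try:
            records.append(fit_em(Z, K, tol=tol, max_iter=max_iter,
                                  n_restarts=n_restarts, seed=seed))
        except Exception as exc:
            raise type(exc)(f"fit at K={K} failed: {exc}") from exc
    bics = np.array([r.bic for r in records])
    best = records[int(np.argmin(bics))]  # argmin takes first == smallest K
    return best, records
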