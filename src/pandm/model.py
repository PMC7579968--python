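"""The pan-cancer DM mixture model: likelihood, EM algorithm, estimator.

Model.  Each CpG site g carries a latent cluster label a_g drawn from
proportions pi = (pi_1, ..., pi_K).  Given a_g = k, the site's DM status in
cancer c is Bernoulli, H_gc ~ Ber(q_kc), independently across cancers; the
observed z-value is drawn from the per-cancer alternative normal N(mu_c1,
sigma_c1^2) when H_gc = 1 and from the empirical-null normal N(mu_c0,
sigma_c0^2) otherwise.  Rows of the K x C matrix Q are the pan-cancer DM
patterns.  The alternative component lives on the negative-z side (small
p-values map to negative z), which is enforced as the identifiability
convention mu_c1 <= mu_c0 for every cancer.

Inference is by EM on the observed z-matrix; all mixture sums run in
log-space, and likelihood products / M-step sums run over observed entries
only, so missing values are marginalized out rather than imputed.

``PanDM`` is a scikit-learn-style estimator (fit / predict / predict_proba,
fitted attributes with a trailing underscore); the module-level functions
(`e_step`, `m_step`, `fit_em`, ...) expose the individual EM pieces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture
from sklearn.utils.validation import check_is_fitted

from .matrices import ValidationError, ZMatrix

__all__ = [
    "PanDM",
    "PanDMParams",
    "Posteriors",
    "FitRecord",
    "complete_loglik",
    "e_step",
    "m_step",
    "observed_loglik",
    "fit_em",
    "bic_value",
    "NumericalError",
    "Q_CLAMP",
    "SIGMA_MIN",
]

# numerical guards: keep ln q and ln(1-q) finite, stop variance collapse
Q_CLAMP = 1e-6
SIGMA_MIN = 1e-3
_DEGENERATE_FRAC = 1e-8


class NumericalError(FloatingPointError):
    """Raised when the likelihood becomes non-finite despite stabilization."""


@dataclass
class PanDMParams:
    """Full parameter set: cluster proportions, DM-probability patterns, and
    per-cancer null/alternative normal components."""

    pi: np.ndarray      # (K,)
    Q: np.ndarray       # (K, C)
    mu0: np.ndarray     # (C,) empirical-null means
    sigma0: np.ndarray  # (C,) empirical-null standard deviations
    mu1: np.ndarray     # (C,) alternative means
    sigma1: np.ndarray  # (C,) alternative standard deviations

    def __post_init__(self) -> None:
        self.pi = np.atleast_1d(np.asarray(self.pi, dtype=float))
        self.Q = np.atleast_2d(np.asarray(self.Q, dtype=float))
        for name in ("mu0", "sigma0", "mu1", "sigma1"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name),
                                                         dtype=float)))

    @property
    def K(self) -> int:
        return self.pi.shape[0]

    @property
    def C(self) -> int:
        return self.Q.shape[1]

    @property
    def n_free_parameters(self) -> int:
        """K - 1 mixture proportions, K*C pattern probabilities, 4*C
        emission parameters."""
        return self.K - 1 + self.K * self.C + 4 * self.C

    def validate(self) -> "PanDMParams":
        if self.Q.shape[0] != self.K:
            raise ValidationError("Q must have one row per cluster")
        if np.any(self.pi < 0) or abs(self.pi.sum() - 1.0) > 1e-12:
            raise ValidationError("pi must be a probability vector")
        if np.any(self.Q < 0) or np.any(self.Q > 1):
            raise ValidationError("Q entries must lie in [0, 1]")
        if np.any(self.sigma0 <= 0) or np.any(self.sigma1 <= 0):
            raise ValidationError("standard deviations must be positive")
        if np.any(self.mu1 > self.mu0):
            raise ValidationError(
                "identifiability requires mu_c1 <= mu_c0 (alternative on the "
                "negative side) for every cancer"
            )
        return self

    def flat(self) -> np.ndarray:
        """Concatenated parameter vector used by the convergence norm."""
        return np.concatenate([self.pi, self.Q.ravel(), self.mu0, self.sigma0,
                               self.mu1, self.sigma1])

    def copy(self) -> "PanDMParams":
        return PanDMParams(self.pi.copy(), self.Q.copy(), self.mu0.copy(),
                           self.sigma0.copy(), self.mu1.copy(),
                           self.sigma1.copy())


@dataclass
class Posteriors:
    """E-step output.

    membership[g, k] = Pr(a_g = k | Z); joint[g, k, c] = E[I(a_g=k) H_gc | Z];
    dm_prob[g, c] = Pr(H_gc = 1 | Z) = sum_k joint[g, k, c].  For a missing
    entry (g, c) the conditional DM probability given cluster k falls back to
    the prior q_kc, so dm_prob is the cluster-weighted prior there.
    """

    membership: np.ndarray  # (G, K)
    joint: np.ndarray       # (G, K, C)
    dm_prob: np.ndarray     # (G, C)
    loglik: float = field(default=np.nan)


@dataclass
class FitRecord:
    """One fitted model at a given K."""

    params: PanDMParams
    loglik_trace: np.ndarray
    bic: float
    n_iter: int
    converged: bool
    seed: int
    restarts_used: int

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])


def bic_value(loglik: float, K: int, C: int, G: int) -> float:
    """-2 ln L_obs + (K - 1 + K*C + 4*C) ln G."""
    return -2.0 * loglik + (K - 1 + K * C + 4 * C) * np.log(G)


class _MaskedView:
    """Cheap view pairing a z array with its precomputed observed mask."""

    __slots__ = ("values", "observed_mask")

    def __init__(self, values: np.ndarray, mask: np.ndarray):
        self.values = values
        self.observed_mask = mask


def _as_arrays(Z) -> tuple[np.ndarray, np.ndarray]:
    """Accept a ZMatrix, a _MaskedView, or a bare NaN-holed 2-D array."""
    if isinstance(Z, (ZMatrix, _MaskedView)):
        return Z.values, Z.observed_mask
    z = np.asarray(Z, dtype=float)
    if z.ndim != 2:
        raise ValidationError("z-values must form a 2-D array")
    return z, ~np.isnan(z)


_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)
# |log N1 - log N0| beyond this the entry is effectively single-component;
# capping keeps exp() finite without affecting posteriors (the cap shifts
# every cluster's per-entry term equally, so memberships are exact)
_LOG_RATIO_CAP = 700.0


def _log_emissions(z, mask, params):
    """Per-entry log densities under each component; 0 at missing entries."""
    zf = np.where(mask, z, 0.0)
    log_n0 = (-0.5 * ((zf - params.mu0) / params.sigma0) ** 2
              - np.log(params.sigma0) - _HALF_LOG_2PI)
    log_n1 = (-0.5 * ((zf - params.mu1) / params.sigma1) ** 2
              - np.log(params.sigma1) - _HALF_LOG_2PI)
    return np.where(mask, log_n0, 0.0), np.where(mask, log_n1, 0.0)


def _log_entry_mixture(z, mask, params):
    """log[q_kc N_c1(z_gc) + (1-q_kc) N_c0(z_gc)] as a (G, K, C) array.

    Missing entries contribute 0 (log of 1), i.e. they drop out of the
    per-site likelihood product.  Factored as log N0 + log[(1-q) + q R]
    with the density ratio R = N1/N0 shared across clusters, which avoids a
    (G, K, C) logaddexp.  Also returns the per-entry conditional DM
    probability q R / [(1-q) + q R], needed for the joint posteriors.
    """
    log_n0, log_n1 = _log_emissions(z, mask, params)
    ratio = np.exp(np.minimum(log_n1 - log_n0, _LOG_RATIO_CAP))  # (G, C)
    q = params.Q[None, :, :]
    inner = (1.0 - q) + q * ratio[:, None, :]          # (G, K, C)
    log_mix = log_n0[:, None, :] + np.log(inner)
    with np.errstate(invalid="ignore", divide="ignore"):
        cond = q * ratio[:, None, :] / inner
    miss = ~mask
    if miss.any():
        log_mix = np.where(miss[:, None, :], 0.0, log_mix)
    return log_mix, cond


def complete_loglik(Z, A, H, params: PanDMParams) -> float:
    """Complete-data log-likelihood for given cluster labels and DM states.

    ``A`` holds 1-based cluster labels; ``H`` is the binary G x C DM-status
    matrix.  Sums run over observed entries only.
    """
    z, mask = _as_arrays(Z)
    params.validate()
    A = np.asarray(A, dtype=int)
    H = np.asarray(H)
    if A.min() < 1 or A.max() > params.K:
        raise ValidationError(f"cluster labels must lie in 1..{params.K}")
    if not np.isin(H[mask], (0, 1)).all():
        raise ValidationError("H must be binary")
    k = A - 1
    log_n0, log_n1 = _log_emissions(z, mask, params)
    with np.errstate(divide="ignore"):
        log_q = np.log(params.Q)[k, :]      # (G, C)
        log_1mq = np.log1p(-params.Q)[k, :]
    h = np.where(mask, H, 0)
    terms = h * (log_q + log_n1) + (1 - h) * (log_1mq + log_n0)
    return float(np.log(params.pi[k]).sum() + terms[mask].sum())


def e_step(Z, params: PanDMParams) -> Posteriors:
    """Posterior cluster memberships and DM probabilities under ``params``.

    membership_gk is proportional to pi_k times the product over observed
    cancers of the two-component entry mixture; joint_gkc multiplies it by the
    conditional DM probability of entry (g, c) given cluster k.  All sums are
    log-space stabilized.
    """
    z, mask = _as_arrays(Z)
    log_mix, cond = _log_entry_mixture(z, mask, params)
    with np.errstate(divide="ignore"):
        log_unnorm = np.log(params.pi)[None, :] + log_mix.sum(axis=2)  # (G, K)
    log_norm = logsumexp(log_unnorm, axis=1)
    if not np.all(np.isfinite(log_norm)):
        g_bad = int(np.flatnonzero(~np.isfinite(log_norm))[0])
        raise NumericalError(
            f"non-finite site likelihood at row {g_bad} "
            "(all clusters have zero density)"
        )
    membership = np.exp(log_unnorm - log_norm[:, None])
    # conditional Pr(H_gc = 1 | a_g = k, z_gc); prior q_kc where missing
    cond = np.where(mask[:, None, :], cond, params.Q[None, :, :])
    joint = membership[:, :, None] * cond
    dm_prob = joint.sum(axis=1)
    return Posteriors(membership=membership, joint=joint, dm_prob=dm_prob,
                      loglik=float(log_norm.sum()))


def m_step(Z, post: Posteriors, prev_params: PanDMParams | None = None) -> PanDMParams:
    """Maximize the EM Q-function given E-step posteriors.

    pi_k averages the memberships; q_kc ratios joint over membership mass on
    the entries observed in cancer c.  The emission components are shared
    across clusters, so each observed z_gc is weighted by its total
    alternative mass w1_gc = sum_k joint_gkc (and 1 - w1 for the null).
    Guards: Q clamped to [Q_CLAMP, 1 - Q_CLAMP]; sigmas floored at SIGMA_MIN;
    null/alternative swapped per cancer if mu1 > mu0; a cluster whose total
    membership falls below 1e-8 * G keeps its previous Q row.
    """
    z, mask = _as_arrays(Z)
    membership, joint = post.membership, post.joint
    G, K = membership.shape

    pi = membership.sum(axis=0) / G
    obs = mask.astype(float)
    q_num = np.einsum("gkc,gc->kc", joint, obs)
    q_den = np.einsum("gk,gc->kc", membership, obs)
    with np.errstate(invalid="ignore", divide="ignore"):
        Q = q_num / q_den
    Q = np.clip(Q, Q_CLAMP, 1.0 - Q_CLAMP)

    mass = membership.sum(axis=0)
    degenerate = mass < _DEGENERATE_FRAC * G
    if degenerate.any():
        warnings.warn(
            f"degenerate cluster(s) {np.flatnonzero(degenerate) + 1}: "
            "membership mass ~ 0; holding previous pattern row",
            RuntimeWarning,
        )
        if prev_params is not None:
            Q[degenerate] = prev_params.Q[degenerate]

    w1 = np.where(mask, joint.sum(axis=1), 0.0)   # (G, C) alternative weight
    w0 = np.where(mask, 1.0 - joint.sum(axis=1), 0.0)
    zf = np.where(mask, z, 0.0)

    def _moments(w):
        tot = w.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mu = (w * zf).sum(axis=0) / tot
            var = (w * (zf - mu) ** 2).sum(axis=0) / tot
        return mu, var, tot

    mu1, var1, tot1 = _moments(w1)
    mu0, var0, tot0 = _moments(w0)
    if prev_params is not None:
        # a component with no weight in some cancer keeps its previous moments
        mu1 = np.where(tot1 > 0, mu1, prev_params.mu1)
        var1 = np.where(tot1 > 0, var1, prev_params.sigma1 ** 2)
        mu0 = np.where(tot0 > 0, mu0, prev_params.mu0)
        var0 = np.where(tot0 > 0, var0, prev_params.sigma0 ** 2)
    sigma1 = np.sqrt(np.maximum(var1, SIGMA_MIN ** 2))
    sigma0 = np.sqrt(np.maximum(var0, SIGMA_MIN ** 2))

    swap = mu1 > mu0
    if swap.any():
        mu0_s, mu1_s = np.where(swap, mu1, mu0), np.where(swap, mu0, mu1)
        s0_s = np.where(swap, sigma1, sigma0)
        s1_s = np.where(swap, sigma0, sigma1)
        Q = np.where(swap[None, :], 1.0 - Q, Q)
        mu0, mu1, sigma0, sigma1 = mu0_s, mu1_s, s0_s, s1_s

    return PanDMParams(pi=pi, Q=Q, mu0=mu0, sigma0=sigma0, mu1=mu1,
                       sigma1=sigma1)


def observed_loglik(Z, params: PanDMParams) -> float:
    """Observed-data log-likelihood (latent labels and DM states summed out)."""
    z, mask = _as_arrays(Z)
    log_mix, _ = _log_entry_mixture(z, mask, params)
    with np.errstate(divide="ignore"):
        log_unnorm = np.log(params.pi)[None, :] + log_mix.sum(axis=2)
    return float(logsumexp(log_unnorm, axis=1).sum())


def _column_mixture_init(z, mask, random_state):
    """Per-cancer two-component normal fits: emission init + hard DM calls."""
    C = z.shape[1]
    mu0 = np.zeros(C)
    sigma0 = np.ones(C)
    mu1 = np.zeros(C)
    sigma1 = np.ones(C)
    hard = np.zeros_like(z, dtype=float)
    for c in range(C):
        col = z[mask[:, c], c]
        gm = GaussianMixture(n_components=2, covariance_type="diag",
                             random_state=random_state, n_init=1,
                             max_iter=200, reg_covar=SIGMA_MIN ** 2)
        gm.fit(col[:, None])
        means = gm.means_.ravel()
        sds = np.sqrt(gm.covariances_.ravel())
        alt = int(np.argmin(means))          # alternative = lower-mean comp
        null = 1 - alt
        mu1[c], sigma1[c] = means[alt], sds[alt]
        mu0[c], sigma0[c] = means[null], sds[null]
        post_alt = gm.predict_proba(col[:, None])[:, alt]
        hard[mask[:, c], c] = (post_alt > 0.5).astype(float)
    return mu0, sigma0, mu1, sigma1, hard


def _initial_params(z, mask, K, rng, restart):
    """Data-driven start: per-column mixtures give the emission components;
    K-means on the hard per-column DM indicators gives cluster structure.
    Restarts beyond the first perturb Q with small uniform noise."""
    seed = int(rng.integers(0, 2**31 - 1))
    mu0, sigma0, mu1, sigma1, hard = _column_mixture_init(z, mask, seed)
    K_eff = min(K, max(1, np.unique(hard, axis=0).shape[0]))
    km = KMeans(n_clusters=K_eff, n_init=10, random_state=seed)
    labels = km.fit_predict(hard)
    pi = np.full(K, 1.0 / K)
    Q = np.full((K, z.shape[1]), 0.5)
    for k in range(K_eff):
        in_k = labels == k
        if in_k.sum() == 0:
            continue
        pi[k] = in_k.mean()
        Q[k] = hard[in_k].mean(axis=0)
    pi = pi / pi.sum()
    if restart > 0:
        Q = Q + rng.uniform(-0.1, 0.1, size=Q.shape)
        pi = pi + rng.uniform(0, 0.05, size=K)
        pi = pi / pi.sum()
    Q = np.clip(Q, Q_CLAMP, 1.0 - Q_CLAMP)
    return PanDMParams(pi=pi, Q=Q, mu0=mu0, sigma0=sigma0, mu1=mu1,
                       sigma1=sigma1)


try:  # fused EM iteration; pure-numpy e_step/m_step remain the reference
    from numba import njit
except ImportError:  # pragma: no cover
    njit = None


def _em_sweep_py(z, mask, pi, Q, log_n0, ratio):
    """One E-step pass plus M-step sufficient statistics (numpy fallback)."""
    G, C = z.shape
    K = pi.shape[0]
    inner = (1.0 - Q)[None, :, :] + Q[None, :, :] * ratio[:, None, :]
    log_mix = np.where(mask[:, None, :], log_n0[:, None, :] + np.log(inner),
                       0.0)
    log_unnorm = np.log(pi)[None, :] + log_mix.sum(axis=2)
    m = log_unnorm.max(axis=1)
    member = np.exp(log_unnorm - m[:, None])
    norm = member.sum(axis=1)
    loglik = float((m + np.log(norm)).sum())
    member /= norm[:, None]
    with np.errstate(invalid="ignore"):
        cond = Q[None, :, :] * ratio[:, None, :] / inner
    w1 = np.einsum("gk,gkc->gc", member, cond)
    w1 = np.where(mask, w1, 0.0)
    obs = mask.astype(np.float64)
    q_num = np.einsum("gk,gkc,gc->kc", member, cond, obs)
    q_den = np.einsum("gk,gc->kc", member, obs)
    w0 = obs - w1
    stats = np.empty((2, 3, C))
    for j, w in enumerate((w0, w1)):
        stats[j, 0] = w.sum(axis=0)
        stats[j, 1] = (w * z).sum(axis=0)
        stats[j, 2] = (w * z * z).sum(axis=0)
    return loglik, member.sum(axis=0), q_num, q_den, stats


if njit is not None:
    @njit(cache=False)
    def _em_sweep_jit(z, mask, pi, Q, log_n0, ratio):  # pragma: no cover
        G, C = z.shape
        K = pi.shape[0]
        log_pi = np.log(pi)
        pi_acc = np.zeros(K)
        q_num = np.zeros((K, C))
        q_den = np.zeros((K, C))
        stats = np.zeros((2, 3, C))
        loglik = 0.0
        lu = np.empty(K)
        member = np.empty(K)
        cond = np.empty((K, C))
        for g in range(G):
            for k in range(K):
                s = log_pi[k]
                for c in range(C):
                    if mask[g, c]:
                        inner = (1.0 - Q[k, c]) + Q[k, c] * ratio[g, c]
                        s += log_n0[g, c] + np.log(inner)
                        cond[k, c] = Q[k, c] * ratio[g, c] / inner
                lu[k] = s
            m = lu[0]
            for k in range(1, K):
                if lu[k] > m:
                    m = lu[k]
            norm = 0.0
            for k in range(K):
                member[k] = np.exp(lu[k] - m)
                norm += member[k]
            loglik += m + np.log(norm)
            for k in range(K):
                member[k] /= norm
                pi_acc[k] += member[k]
            for c in range(C):
                if not mask[g, c]:
                    continue
                w1 = 0.0
                for k in range(K):
                    jnt = member[k] * cond[k, c]
                    q_num[k, c] += jnt
                    q_den[k, c] += member[k]
                    w1 += jnt
                w0 = 1.0 - w1
                zz = z[g, c]
                stats[1, 0, c] += w1
                stats[1, 1, c] += w1 * zz
                stats[1, 2, c] += w1 * zz * zz
                stats[0, 0, c] += w0
                stats[0, 1, c] += w0 * zz
                stats[0, 2, c] += w0 * zz * zz
        return loglik, pi_acc, q_num, q_den, stats
else:  # pragma: no cover
    _em_sweep_jit = None


def _em_iterate(z, mask, params, use_jit=True):
    """One EM iteration via the fused sweep; returns (new params, loglik of
    the incoming params)."""
    log_n0, log_n1 = _log_emissions(z, mask, params)
    ratio = np.exp(np.minimum(log_n1 - log_n0, _LOG_RATIO_CAP))
    sweep = _em_sweep_jit if (use_jit and _em_sweep_jit is not None) \
        else _em_sweep_py
    zf = np.ascontiguousarray(np.where(mask, z, 0.0))
    loglik, pi_acc, q_num, q_den, stats = sweep(
        zf, np.ascontiguousarray(mask), params.pi, params.Q, log_n0, ratio)
    if not np.isfinite(loglik):
        raise NumericalError("non-finite likelihood in EM sweep")
    G = z.shape[0]
    pi = pi_acc / G
    with np.errstate(invalid="ignore", divide="ignore"):
        Q = q_num / q_den
    Q = np.clip(Q, Q_CLAMP, 1.0 - Q_CLAMP)
    degenerate = pi_acc < _DEGENERATE_FRAC * G
    if degenerate.any():
        warnings.warn(
            f"degenerate cluster(s) {np.flatnonzero(degenerate) + 1}: "
            "membership mass ~ 0; holding previous pattern row",
            RuntimeWarning,
        )
        Q[degenerate] = params.Q[degenerate]

    def _moments(tot, s1, s2, prev_mu, prev_sigma):
        with np.errstate(invalid="ignore", divide="ignore"):
            mu = s1 / tot
            var = s2 / tot - mu ** 2
        mu = np.where(tot > 0, mu, prev_mu)
        var = np.where(tot > 0, var, prev_sigma ** 2)
        return mu, np.sqrt(np.maximum(var, SIGMA_MIN ** 2))

    mu0, sigma0 = _moments(stats[0, 0], stats[0, 1], stats[0, 2],
                           params.mu0, params.sigma0)
    mu1, sigma1 = _moments(stats[1, 0], stats[1, 1], stats[1, 2],
                           params.mu1, params.sigma1)
    swap = mu1 > mu0
    if swap.any():
        mu0_s, mu1_s = np.where(swap, mu1, mu0), np.where(swap, mu0, mu1)
        s0_s = np.where(swap, sigma1, sigma0)
        s1_s = np.where(swap, sigma0, sigma1)
        Q = np.where(swap[None, :], 1.0 - Q, Q)
        mu0, mu1, sigma0, sigma1 = mu0_s, mu1_s, s0_s, s1_s
    new = PanDMParams(pi=pi, Q=Q, mu0=mu0, sigma0=sigma0, mu1=mu1,
                      sigma1=sigma1)
    return new, loglik


def _run_em(z, mask, params, tol, max_iter):
    view = _MaskedView(z, mask)
    trace = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        new_params, loglik = _em_iterate(z, mask, params)
        trace.append(loglik)
        delta = np.max(np.abs(new_params.flat() - params.flat()))
        params = new_params
        if delta < tol:
            converged = True
            break
    trace.append(observed_loglik(view, params))
    return params, np.asarray(trace), n_iter, converged


class PanDM(ClusterMixin, BaseEstimator):
    """Joint mixture model of pan-cancer DM patterns over a z-value matrix.

    Parameters
    ----------
    n_patterns : int
        Number of latent DM patterns K.
    tol : float
        Convergence bound on the infinity norm of the concatenated parameter
        vector between EM iterations.
    max_iter : int
        EM iteration cap per restart.
    n_restarts : int
        Number of EM starts; the first is the deterministic data-driven
        initialization, later ones perturb it.  Best final observed
        log-likelihood wins.
    random_state : int
        Seed controlling initialization (and nothing else; EM is
        deterministic given a start).

    Attributes
    ----------
    pi_, Q_, mu0_, sigma0_, mu1_, sigma1_ : fitted parameters
    loglik_trace_ : per-iteration observed log-likelihood of the best restart
    bic_ : Bayesian information criterion of the fit
    n_iter_, converged_, restarts_used_ : EM diagnostics
    labels_ : 0-based hard cluster labels of the training sites
    """

    def __init__(self, n_patterns: int = 2, tol: float = 1e-4,
                 max_iter: int = 1000, n_restarts: int = 1,
                 random_state: int = 0):
        self.n_patterns = n_patterns
        self.tol = tol
        self.max_iter = max_iter
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, X, y=None):
        if self.n_patterns < 1:
            raise ValueError("n_patterns must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        z, mask = _as_arrays(X)
        if not mask.any(axis=1).all():
            g_bad = int(np.flatnonzero(~mask.any(axis=1))[0])
            raise ValidationError(f"row {g_bad} has no observed values")
        rng = np.random.default_rng(self.random_state)
        best = None
        failures = []
        for restart in range(max(1, self.n_restarts)):
            try:
                params0 = _initial_params(z, mask, self.n_patterns, rng,
                                          restart)
                params, trace, n_iter, converged = _run_em(
                    z, mask, params0, self.tol, self.max_iter)
            except (NumericalError, FloatingPointError) as exc:
                failures.append(exc)
                continue
            if best is None or trace[-1] > best[1][-1]:
                best = (params, trace, n_iter, converged)
        if best is None:
            raise NumericalError(
                f"all {self.n_restarts} restart(s) failed numerically: "
                f"{failures[-1]}"
            )
        params, trace, n_iter, converged = best
        G = z.shape[0]
        self.pi_, self.Q_ = params.pi, params.Q
        self.mu0_, self.sigma0_ = params.mu0, params.sigma0
        self.mu1_, self.sigma1_ = params.mu1, params.sigma1
        self.params_ = params
        self.loglik_trace_ = trace
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.restarts_used_ = max(1, self.n_restarts)
        self.bic_ = bic_value(trace[-1], self.n_patterns, z.shape[1], G)
        self.labels_ = self.predict(_MaskedView(z, mask))
        return self

    def predict(self, X):
        """Hard cluster labels (0-based; ties go to the lowest index)."""
        check_is_fitted(self, "params_")
        return e_step(X, self.params_).membership.argmax(axis=1)

    def predict_proba(self, X):
        """Posterior cluster membership matrix, G x K."""
        check_is_fitted(self, "params_")
        return e_step(X, self.params_).membership

    def dm_proba(self, X):
        """Posterior per-site, per-cancer DM probability, G x C."""
        check_is_fitted(self, "params_")
        return e_step(X, self.params_).dm_prob

    def posteriors(self, X) -> Posteriors:
        """Full E-step posteriors under the fitted parameters."""
        check_is_fitted(self, "params_")
        return e_step(X, self.params_)

    def score(self, X, y=None):
        """Observed-data log-likelihood of X under the fitted parameters."""
        check_is_fitted(self, "params_")
        return observed_loglik(X, self.params_)

    def fit_record(self) -> FitRecord:
        """Package the fitted state as a FitRecord."""
        check_is_fitted(self, "params_")
        return FitRecord(params=self.params_, loglik_trace=self.loglik_trace_,
                         bic=self.bic_, n_iter=self.n_iter_,
                         converged=self.converged_, seed=self.random_state,
                         restarts_used=self.restarts_used_)


def fit_em(Z, K: int, tol: float = 1e-4, max_iter: int = 1000,
           n_restarts: int = 1, seed: int = 0) -> FitRecord:
    """Fit the model at a fixed K; thin wrapper over the PanDM estimator."""
    est = PanDM(n_patterns=K, tol=tol, max_iter=max_iter,
                n_restarts=n_restarts, random_state=seed)
    est.fit(Z)
    return est.fit_record()
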