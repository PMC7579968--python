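"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's vectorized code paths:
posterior quantities are recomputed by brute-force enumeration over all
K * 2^C latent configurations per site, and the EM objective (the expected
complete-data log-likelihood) is evaluated by scalar loops.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.stats import norm

from pandm.model import PanDMParams, Posteriors
from pandm.simulate import default_scenario, simulate_dataset

# ---------------------------------------------------------------- oracles


def enum_posteriors(z: np.ndarray, mask: np.ndarray, params: PanDMParams):
    """Brute-force posteriors by enumerating every (cluster, DM-config) pair.

    Returns (membership, joint, dm_prob, loglik); missing entries get the
    cluster-weighted prior DM probability, matching the model contract.
    """
    G, C = z.shape
    K = params.K
    membership = np.zeros((G, K))
    joint = np.zeros((G, K, C))
    loglik = 0.0
    for g in range(G):
        obs = [c for c in range(C) if mask[g, c]]
        mem = np.zeros(K)
        jnt = np.zeros((K, C))
        for k in range(K):
            for bits in itertools.product((0, 1), repeat=len(obs)):
                prob = params.pi[k]
                for c, h in zip(obs, bits):
                    if h:
                        prob *= params.Q[k, c] * norm.pdf(
                            z[g, c], params.mu1[c], params.sigma1[c])
                    else:
                        prob *= (1.0 - params.Q[k, c]) * norm.pdf(
                            z[g, c], params.mu0[c], params.sigma0[c])
                mem[k] += prob
                for c, h in zip(obs, bits):
                    if h:
                        jnt[k, c] += prob
        total = mem.sum()
        loglik += np.log(total)
        membership[g] = mem / total
        jnt /= total
        for c in range(C):
            if not mask[g, c]:
                jnt[:, c] = membership[g] * params.Q[:, c]
        joint[g] = jnt
    return membership, joint, joint.sum(axis=1), loglik


def q_function(z: np.ndarray, mask: np.ndarray, post: Posteriors,
               params: PanDMParams) -> float:
    """Expected complete-data log-likelihood, evaluated by scalar loops."""
    G, C = z.shape
    val = 0.0
    for g in range(G):
        for k in range(params.K):
            val += post.membership[g, k] * np.log(params.pi[k])
            for c in range(C):
                if not mask[g, c]:
                    continue
                jgk = post.joint[g, k, c]
                val += jgk * (np.log(params.Q[k, c]) + norm.logpdf(
                    z[g, c], params.mu1[c], params.sigma1[c]))
                val += (post.membership[g, k] - jgk) * (
                    np.log1p(-params.Q[k, c]) + norm.logpdf(
                        z[g, c], params.mu0[c], params.sigma0[c]))
    return val


def best_permutation_error(Q_true: np.ndarray, Q_fit: np.ndarray) -> float:
    """Max-abs error of the fitted pattern matrix after the best row
    permutation (exhaustive; K is small)."""
    best = np.inf
    for perm in itertools.permutations(range(Q_fit.shape[0])):
        err = np.abs(Q_true - Q_fit[list(perm)]).max()
        best = min(best, err)
    return best


def random_small_instance(seed: int, G: int = 8, C: int = 2, K: int = 2,
                          missing_rate: float = 0.0):
    """A small random (z, mask, params) triple for oracle comparisons."""
    rng = np.random.default_rng(seed)
    pi = rng.dirichlet(np.ones(K) * 3)
    Q = rng.uniform(0.1, 0.9, size=(K, C))
    mu0 = rng.normal(0, 0.3, C)
    mu1 = mu0 - rng.uniform(1.5, 3.0, C)
    sigma0 = rng.uniform(0.8, 1.2, C)
    sigma1 = rng.uniform(0.8, 1.2, C)
    params = PanDMParams(pi=pi, Q=Q, mu0=mu0, sigma0=sigma0, mu1=mu1,
                         sigma1=sigma1).validate()
    z = rng.normal(-1.0, 2.0, size=(G, C))
    mask = np.ones((G, C), dtype=bool)
    if missing_rate > 0:
        mask = rng.random((G, C)) > missing_rate
        mask[~mask.any(axis=1), 0] = True  # every site keeps >= 1 value
    z = np.where(mask, z, np.nan)
    return z, mask, params


# ---------------------------------------------------------------- fixtures


@pytest.fixture(scope="session")
def fast_scenario():
    """Default study design at the reduced problem size."""
    params, G = default_scenario("fast")
    return params, G


@pytest.fixture(scope="session")
def fast_dataset(fast_scenario):
    """One simulated dataset from the default scenario (seed 1)."""
    params, G = fast_scenario
    z, truth = simulate_dataset(params, G, seed=1)
    return z, truth


@pytest.fixture(scope="session")
def fast_fit(fast_dataset):
    """The K=5 model fitted to the seed-1 dataset, with posteriors."""
    from pandm.model import e_step, fit_em

    z, truth = fast_dataset
    record = fit_em(z, 5, seed=1)
    post = e_step(z, record.params)
    return record, post
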