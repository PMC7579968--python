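"""Synthetic pan-cancer DM data with known ground truth.

The generator follows the model's own generative story: cluster labels from
the categorical distribution pi, per-site/per-cancer DM indicators
H_gc ~ Ber(q_{a_g, c}), and z-values from the per-cancer alternative normal
when H_gc = 1 and the empirical-null normal otherwise.  Ground truth (labels
and indicators) is returned so power, FDR and pattern-recovery properties can
be measured exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrices import ZMatrix
from .model import PanDMParams

__all__ = ["SimTruth", "simulate_dataset", "default_scenario"]


@dataclass
class SimTruth:
    """Ground truth for one synthetic dataset: 1-based cluster labels A,
    binary DM indicators H, and the generating parameters."""

    A: np.ndarray        # (G,) labels in 1..K
    H: np.ndarray        # (G, C) binary
    params: PanDMParams


def simulate_dataset(params: PanDMParams, G: int, seed: int = 0
                     ) -> tuple[ZMatrix, SimTruth]:
    """Draw a G-site dataset from the generative model; reproducible by seed."""
    if G < 1:
        raise ValueError("G must be >= 1")
    params.validate()
    rng = np.random.default_rng(seed)
    a = rng.choice(params.K, size=G, p=params.pi)          # 0-based internally
    h = (rng.random((G, params.C)) < params.Q[a]).astype(int)
    mu = np.where(h == 1, params.mu1, params.mu0)
    sigma = np.where(h == 1, params.sigma1, params.sigma0)
    z = rng.normal(mu, sigma)
    zmat = ZMatrix(
        values=z,
        cpg_ids=np.array([f"cpg_{i + 1:06d}" for i in range(G)]),
        cancer_ids=np.array([f"cancer_{j + 1:02d}" for j in range(params.C)]),
    )
    return zmat, SimTruth(A=a + 1, H=h, params=params)


def default_scenario(scale: str = "full") -> tuple[PanDMParams, int]:
    """The study design used throughout the tests: C = 9 cancers, K = 5
    well-separated block patterns, unequal cluster proportions.

    The five patterns: an all-non-DM background (largest cluster), an all-DM
    pattern, and three patterns each DM in a different block of three
    cancers.  DM probabilities contrast 0.9 against 0.05, null components
    sit near N(0, 1) with small per-cancer offsets, and alternative means
    are clearly negative (around -2) per the p-to-z convention: strong
    enough for pattern recovery, overlapping enough that per-cancer
    rankings stay noisy and joint modeling has signal to recover.

    ``scale='full'`` pairs the parameters with G = 100,000 sites;
    ``scale='fast'`` with G = 20,000 for quicker experiments.
    """
    if scale not in ("full", "fast"):
        raise ValueError("scale must be 'full' or 'fast'")
    lo, hi = 0.05, 0.9
    Q = np.full((5, 9), lo)
    Q[1, :] = hi          # DM everywhere
    Q[2, 0:3] = hi        # DM in cancers 1-3
    Q[3, 3:6] = hi        # DM in cancers 4-6
    Q[4, 6:9] = hi        # DM in cancers 7-9
    params = PanDMParams(
        pi=np.array([0.35, 0.20, 0.175, 0.15, 0.125]),
        Q=Q,
        mu0=np.array([0.0, 0.1, -0.1, 0.05, 0.0, -0.05, 0.1, 0.0, -0.1]),
        sigma0=np.array([1.0, 1.05, 0.95, 1.0, 1.1, 1.0, 0.9, 1.0, 1.05]),
        mu1=np.array([-2.0, -1.8, -2.2, -1.9, -2.1, -2.0, -1.8, -2.2, -2.0]),
        sigma1=np.array([1.0, 0.9, 1.1, 1.0, 0.95, 1.05, 1.0, 0.9, 1.0]),
    ).validate()
    return params, (100_000 if scale == "full" else 20_000)
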