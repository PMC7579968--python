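"""p-value to z-value transform under the empirical-null convention.

Each observed p-value is mapped through the standard normal quantile function,
z = Phi^{-1}(p), so that small p-values (strong DM evidence) land on the far
negative side of the z axis while the bulk of null sites forms a near-standard
normal around zero.  Boundary values p = 0 and p = 1 would map to infinite z
and break the likelihood, so p is first clipped into [clip, 1 - clip].
"""

from __future__ import annotations

from scipy.stats import norm

from .matrices import PValueMatrix, ZMatrix

__all__ = ["p_to_z", "z_to_p", "DEFAULT_CLIP"]

DEFAULT_CLIP = 1e-15


def p_to_z(p: PValueMatrix, clip: float = DEFAULT_CLIP) -> ZMatrix:
    """Transform a p-value matrix to z-values, z = Phi^{-1}(clipped p).

    Missing entries stay missing.  ``clip`` must lie in (0, 0.5); observed
    output values are always finite.
    """
    if not 0.0 < clip < 0.5:
        raise ValueError(f"clip must be in (0, 0.5), got {clip!r}")
    z = norm.ppf(p.values.clip(clip, 1.0 - clip))
    return ZMatrix(values=z, cpg_ids=p.cpg_ids, cancer_ids=p.cancer_ids)


def z_to_p(z: ZMatrix) -> PValueMatrix:
    """Inverse transform, p = Phi(z); used when exporting simulated data."""
    return PValueMatrix(values=norm.cdf(z.values), cpg_ids=z.cpg_ids,
                        cancer_ids=z.cancer_ids)
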