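"""Summary-statistic matrix containers.

The whole pipeline operates on a G x C matrix of per-CpG, per-cancer summary
statistics: p-values from any upstream single-cancer differential-methylation
caller, or their z-value transforms.  Rows are CpG sites (opaque string ids),
columns are cancer types.  Missing entries are carried as NaN and tracked by
``observed_mask``; the model marginalizes over them rather than dropping rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PValueMatrix", "ZMatrix", "ValidationError"]


class ValidationError(ValueError):
    """Raised when an input matrix violates its declared invariants."""


def _check_ids(ids: np.ndarray, what: str) -> np.ndarray:
    ids = np.asarray(ids, dtype=object)
    if ids.ndim != 1:
        raise ValidationError(f"{what} must be a 1-D sequence")
    uniq, counts = np.unique(ids.astype(str), return_counts=True)
    dups = uniq[counts > 1]
    if dups.size:
        raise ValidationError(f"duplicate {what}: {', '.join(map(str, dups[:5]))}")
    return ids.astype(str)


@dataclass
class _SummaryMatrix:
    values: np.ndarray
    cpg_ids: np.ndarray
    cancer_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D array")
        self.cpg_ids = _check_ids(np.asarray(self.cpg_ids), "CpG ids")
        self.cancer_ids = _check_ids(np.asarray(self.cancer_ids), "cancer ids")
        g, c = self.values.shape
        if self.cpg_ids.shape[0] != g:
            raise ValidationError(
                f"{self.cpg_ids.shape[0]} CpG ids for {g} rows"
            )
        if self.cancer_ids.shape[0] != c:
            raise ValidationError(
                f"{self.cancer_ids.shape[0]} cancer ids for {c} columns"
            )
        self._validate_values()

    def _validate_values(self) -> None:  # pragma: no cover - overridden
        pass

    @property
    def observed_mask(self) -> np.ndarray:
        """Boolean G x C mask, True where a value is present."""
        return ~np.isnan(self.values)

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    @property
    def n_cancers(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class PValueMatrix(_SummaryMatrix):
    """G x C matrix of per-cancer DM p-values; NaN marks a missing entry."""

    def _validate_values(self) -> None:
        bad = (self.values < 0.0) | (self.values > 1.0)
        bad &= ~np.isnan(self.values)
        if bad.any():
            g, c = np.argwhere(bad)[0]
            raise ValidationError(
                f"p-value out of [0, 1] at CpG '{self.cpg_ids[g]}', "
                f"cancer '{self.cancer_ids[c]}': {self.values[g, c]!r}"
            )


@dataclass
class ZMatrix(_SummaryMatrix):
    """G x C matrix of z-values (normal-quantile transforms of p-values)."""

    def _validate_values(self) -> None:
        bad = np.isinf(self.values)
        if bad.any():
            g, c = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-finite z-value at CpG '{self.cpg_ids[g]}', "
                f"cancer '{self.cancer_ids[c]}'"
            )
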