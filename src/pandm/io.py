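"""Reading and writing the delimited-text tables the tool exchanges.

Input is a delimited text matrix: first column CpG ids, header row cancer ids,
entries p-values (or z-values).  "NA", "NaN" and empty fields are read as
missing; missing values are written back as "NA".  The delimiter is inferred
from the file extension (.tsv -> tab, .csv -> comma) unless given explicitly.

Results are written as plain tables (6 significant digits) plus one JSON model
descriptor holding every parameter at full double precision, so a fit can be
archived and reloaded losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .matrices import PValueMatrix, ValidationError, ZMatrix

if TYPE_CHECKING:  # pragma: no cover
    from .inference import DMCalls, Posteriors
    from .model import FitRecord

__all__ = [
    "read_pvalue_matrix",
    "read_zvalue_matrix",
    "write_matrix",
    "write_results",
    "read_q_matrix",
    "FormatError",
]

MISSING_TOKENS = ("NA", "NaN", "nan", "")
_TABLE_FMT = "%.6g"


class FormatError(ValueError):
    """Raised when a file cannot be parsed as a summary matrix."""


def _infer_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def _read_table(path, delimiter, missing_token) -> pd.DataFrame:
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    na_values = list(MISSING_TOKENS)
    if missing_token is not None:
        na_values.append(missing_token)
    try:
        frame = pd.read_csv(
            path, sep=sep, index_col=0, na_values=na_values,
            keep_default_na=False, dtype=str,
        )
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if frame.shape[1] == 0:
        raise FormatError(f"{path}: no data columns found (wrong delimiter?)")
    try:
        frame = frame.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric entry: {exc}") from exc
    return frame


def read_pvalue_matrix(path, delimiter: str | None = None,
                       missing_token: str | None = None) -> PValueMatrix:
    """Read a CpG-by-cancer p-value table from delimited text."""
    frame = _read_table(path, delimiter, missing_token)
    return PValueMatrix(
        values=frame.to_numpy(dtype=float),
        cpg_ids=frame.index.to_numpy(),
        cancer_ids=frame.columns.to_numpy(),
    )


def read_zvalue_matrix(path, delimiter: str | None = None,
                       missing_token: str | None = None) -> ZMatrix:
    """Read a CpG-by-cancer z-value table from delimited text."""
    frame = _read_table(path, delimiter, missing_token)
    return ZMatrix(
        values=frame.to_numpy(dtype=float),
        cpg_ids=frame.index.to_numpy(),
        cancer_ids=frame.columns.to_numpy(),
    )


def _to_frame(mat) -> pd.DataFrame:
    return pd.DataFrame(mat.values, index=pd.Index(mat.cpg_ids, name="cpg_id"),
                        columns=mat.cancer_ids)


def write_matrix(mat, path, delimiter: str | None = None,
                 float_format: str = "%.17g") -> None:
    """Write a PValueMatrix/ZMatrix to delimited text (missing -> "NA")."""
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    _to_frame(mat).to_csv(path, sep=sep, na_rep="NA", float_format=float_format)


def read_q_matrix(path, delimiter: str | None = None) -> pd.DataFrame:
    """Read back a pattern-probability (Q) table written by write_results."""
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    return pd.read_csv(path, sep=sep, index_col=0)


def write_results(fit: "FitRecord", posteriors: "Posteriors", calls: "DMCalls",
                  out_dir, cpg_ids=None, cancer_ids=None) -> dict[str, Path]:
    """Write the full result set for one fitted model.

    Produces five files in ``out_dir``: cluster membership per site, the K x C
    pattern-probability matrix Q, the local-fdr matrix, the binary DM-call
    matrix, and a JSON model descriptor (parameters, BIC, log-likelihood
    trace, seed, convergence flag).  Cluster labels are written 1-based.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc

    params = fit.params
    g, c = posteriors.dm_prob.shape
    if cpg_ids is None:
        cpg_ids = [f"cpg_{i + 1:06d}" for i in range(g)]
    if cancer_ids is None:
        cancer_ids = [f"cancer_{j + 1:02d}" for j in range(c)]
    cpg_index = pd.Index(np.asarray(cpg_ids, dtype=str), name="cpg_id")
    cancer_ids = list(np.asarray(cancer_ids, dtype=str))
    cluster_labels = [f"pattern_{k + 1}" for k in range(params.K)]

    paths: dict[str, Path] = {}

    labels = posteriors.membership.argmax(axis=1)  # ties -> lowest index
    membership = pd.DataFrame(
        {
            "cluster": labels + 1,
            "posterior": posteriors.membership[np.arange(g), labels],
        },
        index=cpg_index,
    )
    paths["membership"] = out_dir / "membership.tsv"
    membership.to_csv(paths["membership"], sep="\t", float_format=_TABLE_FMT)

    q_frame = pd.DataFrame(params.Q, index=pd.Index(cluster_labels, name="pattern"),
                           columns=cancer_ids)
    paths["q_matrix"] = out_dir / "q_matrix.tsv"
    q_frame.to_csv(paths["q_matrix"], sep="\t", float_format=_TABLE_FMT)

    fdr_frame = pd.DataFrame(calls.fdr_local, index=cpg_index, columns=cancer_ids)
    paths["local_fdr"] = out_dir / "local_fdr.tsv"
    fdr_frame.to_csv(paths["local_fdr"], sep="\t", na_rep="NA",
                     float_format=_TABLE_FMT)

    call_frame = pd.DataFrame(calls.calls.astype(int), index=cpg_index,
                              columns=cancer_ids)
    paths["dm_calls"] = out_dir / "dm_calls.tsv"
    call_frame.to_csv(paths["dm_calls"], sep="\t")

    descriptor = {
        "K": int(params.K),
        "pi": params.pi.tolist(),
        "Q": params.Q.tolist(),
        "mu0": params.mu0.tolist(),
        "sigma0": params.sigma0.tolist(),
        "mu1": params.mu1.tolist(),
        "sigma1": params.sigma1.tolist(),
        "cancer_ids": cancer_ids,
        "bic": float(fit.bic),
        "loglik_trace": [float(v) for v in fit.loglik_trace],
        "n_iter": int(fit.n_iter),
        "converged": bool(fit.converged),
        "seed": int(fit.seed),
        "restarts_used": int(fit.restarts_used),
        "fdr_level": float(calls.level),
        "fdr_tau": float(calls.tau),
        "achieved_fdr": float(calls.achieved_fdr),
    }
    paths["model"] = out_dir / "model.json"
    paths["model"].write_text(json.dumps(descriptor, indent=2))
    return paths
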