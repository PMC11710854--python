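"""Tissue-specificity (tau) scoring of expression profiles.

tau = sum_i (1 - x_i / max_j x_j) / (n - 1) over n >= 2 tissues: 0 for a
uniformly expressed gene, 1 for single-tissue expression.  Computed on
linear TPM after averaging replicates per tissue; a log2(x+1) transform is
available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TissueSpecificityResult",
    "tau",
    "average_replicates",
    "specificity_table",
    "classify_specific",
]


@dataclass(frozen=True)
class TissueSpecificityResult:
    gene: str
    tau: float
    top_tissue: str | None
    is_specific: bool
    threshold: float


def tau(values: Sequence[float]) -> float:
    """Tissue-specificity index of one replicate-averaged profile.

    Returns NaN for an all-zero profile (specificity undefined); raises
    for fewer than two tissues or negative values.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("tau needs a 1-D profile over >= 2 tissues")
    if (x < 0).any():
        raise ValueError("expression values must be non-negative")
    m = x.max()
    if m == 0:
        return float("nan")
    return float(np.sum(1.0 - x / m) / (len(x) - 1))


def average_replicates(matrix: pd.DataFrame) -> pd.DataFrame:
    """Average ``tissue.replicate`` columns into one column per tissue.

    Columns without a ``.`` are taken as already tissue-level.
    """
    tissues = [c.split(".")[0] for c in matrix.columns]
    return matrix.T.groupby(tissues, sort=False).mean().T


def classify_specific(
    gene: str,
    profile: pd.Series,
    tissue: str = "testis",
    threshold: float = 0.8,
    log_transform: bool = False,
) -> TissueSpecificityResult:
    """Flag a gene as specific to ``tissue``: tau >= threshold (inclusive)
    AND the named tissue is the unique expression maximum; ties for the
    top tissue are treated as non-specific."""
    vals = profile.astype(float)
    if log_transform:
        vals = np.log2(vals + 1.0)
    t = tau(vals.to_numpy())
    if np.isnan(t):
        return TissueSpecificityResult(gene, t, None, False, threshold)
    m = vals.max()
    top = vals.index[vals.to_numpy() == m]
    top_tissue = str(top[0]) if len(top) == 1 else None
    is_specific = bool(t >= threshold and top_tissue == tissue)
    return TissueSpecificityResult(gene, t, top_tissue or str(top[0]), is_specific, threshold)


def specificity_table(
    matrix: pd.DataFrame,
    tissue: str = "testis",
    threshold: float = 0.8,
    log_transform: bool = False,
) -> pd.DataFrame:
    """Per-gene tau / top tissue / specificity flag for a genes x samples
    matrix (replicates averaged per tissue first)."""
    avg = average_replicates(matrix)
    rows = []
    for gene in avg.index:
        r = classify_specific(gene, avg.loc[gene], tissue, threshold, log_transform)
        rows.append((r.gene, r.tau, r.top_tissue, r.is_specific))
    return pd.DataFrame(rows, columns=["gene", "tau", "top_tissue", "is_specific"]
                        ).set_index("gene")
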