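"""Per-cell quality-control filters producing the analysis cell set.

Three filters compose by conjunction: an IQR fence on genes detected per
cell (cells below Q1-IQR or above Q3+IQR removed, boundaries inclusive
for keeping), a mitochondrial-fraction cap (cells with more than 10%
mitochondrial RNA removed), and removal of externally flagged doublets.
Quartiles use linear interpolation between order statistics (the common
"type 7" convention); the choice is recorded in run logs so results are
reproducible. The fence is applied once to the full table, not per
cluster. An IQR fence on UMI counts is available but off by default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "MITO_MAX_FRACTION",
    "iqr_gene_filter",
    "iqr_fence",
    "mito_filter",
    "combine_qc",
]

MITO_MAX_FRACTION = 0.10

_METRIC_COLUMNS = ("cell_id", "n_genes", "mito_fraction", "doublet")


def iqr_fence(values: pd.Series | np.ndarray) -> tuple[float, float]:
    """Keep-window [Q1-IQR, Q3+IQR] with linearly interpolated quartiles."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 4:
        raise ValueError("too few cells for IQR filter (need >= 4)")
    q1, q3 = np.percentile(arr, [25, 75])  # linear interpolation (type 7)
    iqr = q3 - q1
    return q1 - iqr, q3 + iqr


def iqr_gene_filter(metrics: pd.DataFrame, column: str = "n_genes") -> pd.Series:
    """Boolean keep-mask: cells inside [Q1-IQR, Q3+IQR] on genes per cell.

    Removal is strict ("lower than" / "higher than"), so cells exactly on
    a fence boundary are kept; with a degenerate distribution (IQR 0) all
    cells at the common value pass.
    """
    low, high = iqr_fence(metrics[column])
    vals = metrics[column].astype(float)
    return ((vals >= low) & (vals <= high)).rename("iqr_pass")


def mito_filter(
    metrics: pd.DataFrame, max_fraction: float = MITO_MAX_FRACTION
) -> pd.Series:
    """Keep-mask: mitochondrial fraction at most ``max_fraction`` (strictly
    greater is removed, so exactly 10% passes)."""
    frac = metrics["mito_fraction"].astype(float)
    if ((frac < 0) | (frac > 1)).any():
        raise ValueError("mito_fraction must lie in [0, 1]")
    return (frac <= max_fraction).rename("mito_pass")


def combine_qc(
    metrics: pd.DataFrame,
    max_mito_fraction: float = MITO_MAX_FRACTION,
    umi_fence: bool = False,
) -> pd.DataFrame:
    """Apply all filters and return the metrics table with a ``qc_pass`` column.

    ``qc_pass`` is the conjunction of the gene-count fence, the
    mitochondrial cap and the negated doublet flag (doublet calls are
    consumed as an input column, not computed here). Setting ``umi_fence``
    additionally fences ``n_umis``.
    """
    missing = [c for c in _METRIC_COLUMNS if c not in metrics.columns]
    if missing:
        raise ValueError(f"metrics table missing column(s) {missing}")
    out = metrics.copy()
    out["iqr_pass"] = iqr_gene_filter(metrics)
    out["mito_pass"] = mito_filter(metrics, max_mito_fraction)
    out["qc_pass"] = out["iqr_pass"] & out["mito_pass"] & ~out["doublet"].astype(bool)
    if umi_fence:
        if "n_umis" not in metrics.columns:
            raise ValueError("umi_fence requested but no n_umis column")
        out["umi_pass"] = iqr_gene_filter(metrics, column="n_umis").values
        out["qc_pass"] &= out["umi_pass"]
    return out
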