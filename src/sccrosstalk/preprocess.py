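"""Quality control and ERCC-aware renormalization of Smart-seq2 TPM matrices.

The pipeline QC follows common Smart-seq2 practice: cells with fewer than 1500
detected genes or more than 20% mitochondrial expression are removed (both
inequalities strict, so a cell at exactly the threshold survives), genes seen
in fewer than 3 cells are dropped, ERCC spike-in rows are stripped and the
remaining endogenous TPMs rescaled so each cell sums to one million, and the
matrix is finally log(TPM + 1)-transformed (natural log).

Mitochondrial fraction is computed on the raw TPM scale, before spike-in
removal — i.e. on the values as quantified — and "expressed" means strictly
greater than zero throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, TPM_TOTAL

logger = logging.getLogger(__name__)

__all__ = [
    "QCThresholds",
    "compute_qc_metrics",
    "filter_cells",
    "filter_genes",
    "strip_spikeins_rescale",
    "log_transform",
    "run_qc",
]


@dataclass(frozen=True)
class QCThresholds:
    """Cell- and gene-level QC cutoffs.

    ``require_both`` keeps the literal reading of the exclusion rule in which
    a cell must fail both the gene-count and the mitochondrial condition to
    be removed; the default removes a cell failing either, the universal
    scRNA-seq convention.
    """

    min_detected_genes: int = 1500
    max_mito_fraction: float = 0.20
    min_cells_per_gene: int = 3
    require_both: bool = False

    def __post_init__(self):
        if self.min_detected_genes < 0:
            raise ValueError("min_detected_genes must be >= 0")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must be in [0, 1]")
        if self.min_cells_per_gene < 0:
            raise ValueError("min_cells_per_gene must be >= 0")


def compute_qc_metrics(matrix: ExpressionMatrix,
                       mito_prefix: str = "mt-") -> pd.DataFrame:
    """Per-cell QC metrics: detected genes, mitochondrial fraction, total TPM.

    ``mito_fraction`` is the share of the cell's total expression carried by
    genes whose name starts with ``mito_prefix``; a cell with zero total
    expression gets fraction 0.
    """
    vals = matrix.values
    detected = (vals > 0).sum(axis=0)
    total = vals.sum(axis=0)
    mito_rows = matrix.genes_with_prefix(mito_prefix)
    if not mito_rows:
        logger.warning("no genes with prefix %r: mito_fraction set to 0",
                       mito_prefix)
        mito_sum = np.zeros(matrix.n_cells)
    else:
        mito_sum = matrix.data.loc[mito_rows].to_numpy().sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito_sum / np.where(total > 0, total, 1.0),
                             0.0)
    return pd.DataFrame(
        {"detected_genes": detected.astype(int),
         "mito_fraction": mito_frac,
         "total_tpm": total},
        index=matrix.cells,
    )


def filter_cells(matrix: ExpressionMatrix, metrics: pd.DataFrame,
                 thresholds: QCThresholds = QCThresholds()) -> ExpressionMatrix:
    """Remove low-quality cells.

    A cell is removed when ``detected_genes < min_detected_genes`` or
    ``mito_fraction > max_mito_fraction`` (strict comparisons: exactly 1500
    detected genes or exactly 20% mitochondrial content survives).  Column
    order of the survivors is preserved.
    """
    metrics = metrics.loc[matrix.cells]
    low_genes = metrics["detected_genes"] < thresholds.min_detected_genes
    high_mito = metrics["mito_fraction"] > thresholds.max_mito_fraction
    bad = (low_genes & high_mito) if thresholds.require_both else (low_genes | high_mito)
    keep = [c for c, b in zip(matrix.cells, bad) if not b]
    if not keep:
        raise ValueError(
            f"all {matrix.n_cells} cells removed by QC (min_detected_genes="
            f"{thresholds.min_detected_genes}, max_mito_fraction="
            f"{thresholds.max_mito_fraction})")
    return matrix.subset_cells(keep)


def filter_genes(matrix: ExpressionMatrix,
                 min_cells_per_gene: int = 3) -> ExpressionMatrix:
    """Keep genes expressed (value > 0) in at least ``min_cells_per_gene`` cells."""
    n_expressing = (matrix.values > 0).sum(axis=1)
    keep = [g for g, n in zip(matrix.genes, n_expressing)
            if n >= min_cells_per_gene]
    return matrix.subset_genes(keep)


def strip_spikeins_rescale(matrix: ExpressionMatrix,
                           ercc_prefix: str = "ERCC-") -> ExpressionMatrix:
    """Drop ERCC spike-in rows and rescale each cell back to 1e6 total TPM.

    Within-cell proportions among endogenous genes are preserved; all-zero
    columns stay all-zero.
    """
    ercc = set(matrix.genes_with_prefix(ercc_prefix))
    keep = [g for g in matrix.genes if g not in ercc]
    out = matrix.data.loc[keep].copy()
    sums = out.to_numpy().sum(axis=0)
    nz = sums > 0
    arr = out.to_numpy()
    arr[:, nz] *= TPM_TOTAL / sums[nz]
    out.iloc[:, :] = arr
    return ExpressionMatrix(out)


def log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise natural log(x + 1)."""
    return ExpressionMatrix(np.log1p(matrix.data))


def run_qc(matrix: ExpressionMatrix,
           thresholds: QCThresholds = QCThresholds(),
           mito_prefix: str = "mt-",
           ercc_prefix: str = "ERCC-",
           log: bool = True) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Full preprocessing chain: QC metrics -> cell filter -> gene filter ->
    spike-in removal/rescale -> log transform.

    Returns the processed matrix and the per-cell metrics of the input.
    """
    metrics = compute_qc_metrics(matrix, mito_prefix=mito_prefix)
    out = filter_cells(matrix, metrics, thresholds)
    out = filter_genes(out, thresholds.min_cells_per_gene)
    out = strip_spikeins_rescale(out, ercc_prefix=ercc_prefix)
    if log:
        out = log_transform(out)
    return out, metrics
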