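"""Readers and writers for the package's on-disk formats.

Expression matrices travel as MatrixMarket MTX (genes x cells) with
``genes.tsv`` / ``cells.tsv`` sidecars, or as dense TSV (genes in rows).
Simulation ground truth is JSON; interaction databases and cell-cycle pair
tables are CSV (parsed in their owning modules).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .matrix import ExpressionMatrix
from .simulate import SimTruth

__all__ = ["write_mtx", "read_mtx", "write_dense_tsv", "read_dense_tsv",
           "write_truth", "read_truth"]


def write_mtx(matrix: ExpressionMatrix, outdir) -> Path:
    """Write ``matrix.mtx`` + ``genes.tsv`` + ``cells.tsv`` under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(outdir / "matrix.mtx", sparse.csr_matrix(matrix.values))
    pd.Series(matrix.genes).to_csv(outdir / "genes.tsv", sep="\t",
                                   index=False, header=False)
    pd.Series(matrix.cells).to_csv(outdir / "cells.tsv", sep="\t",
                                   index=False, header=False)
    return outdir


def read_mtx(indir) -> ExpressionMatrix:
    indir = Path(indir)
    vals = spio.mmread(indir / "matrix.mtx")
    if sparse.issparse(vals):
        vals = vals.toarray()
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0].tolist()
    cells = pd.read_csv(indir / "cells.tsv", sep="\t", header=None)[0].tolist()
    return ExpressionMatrix(np.asarray(vals, dtype=float),
                            genes=genes, cells=cells)


def write_dense_tsv(matrix: ExpressionMatrix, path) -> Path:
    path = Path(path)
    matrix.data.to_csv(path, sep="\t")
    return path


def read_dense_tsv(path) -> ExpressionMatrix:
    return ExpressionMatrix(pd.read_csv(path, sep="\t", index_col=0))


def write_truth(truth: SimTruth, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(truth.to_dict(), indent=1))
    return path


def read_truth(path) -> SimTruth:
    return SimTruth.from_dict(json.loads(Path(path).read_text()))
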