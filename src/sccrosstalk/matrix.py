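"""Core in-memory container: a genes x cells expression matrix on the TPM scale.

The whole pipeline trades in :class:`ExpressionMatrix`, a thin wrapper around a
pandas DataFrame whose rows are genes and whose columns are cells.  Values are
non-negative; depending on the stage they are raw TPM or log(TPM + 1).
Mitochondrial genes and ERCC spike-in controls are recognised by gene-name
prefix (``mt-`` and ``ERCC-`` by convention).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

TPM_TOTAL = 1e6

__all__ = ["ExpressionMatrix", "TPM_TOTAL"]


class ExpressionMatrix:
    """Genes x cells non-negative expression matrix.

    Parameters
    ----------
    data
        DataFrame indexed by gene name with one column per cell, or a 2-D
        array combined with explicit ``genes`` and ``cells`` labels.
    """

    def __init__(self, data, genes: Sequence[str] | None = None,
                 cells: Sequence[str] | None = None,
                 allow_negative: bool = False):
        if isinstance(data, pd.DataFrame):
            df = data.copy()
        else:
            arr = np.asarray(data, dtype=float)
            if arr.ndim != 2:
                raise ValueError("expression data must be 2-D (genes x cells)")
            if genes is None or cells is None:
                raise ValueError("genes and cells labels required for array input")
            df = pd.DataFrame(arr, index=list(genes), columns=list(cells))
        if df.index.has_duplicates:
            raise ValueError("duplicate gene names")
        if df.columns.has_duplicates:
            raise ValueError("duplicate cell names")
        vals = df.to_numpy(dtype=float, copy=False)
        if not np.isfinite(vals).all():
            raise ValueError("expression values must be finite")
        if not allow_negative and (vals < 0).any():
            # residual matrices (e.g. after covariate regression) may opt out
            raise ValueError("expression values must be non-negative")
        self._df = df.astype(float)

    # -- basic accessors ---------------------------------------------------
    @property
    def data(self) -> pd.DataFrame:
        """The underlying genes x cells DataFrame (not a copy)."""
        return self._df

    @property
    def values(self) -> np.ndarray:
        return self._df.to_numpy()

    @property
    def genes(self) -> pd.Index:
        return self._df.index

    @property
    def cells(self) -> pd.Index:
        return self._df.columns

    @property
    def n_genes(self) -> int:
        return self._df.shape[0]

    @property
    def n_cells(self) -> int:
        return self._df.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self._df.copy())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ExpressionMatrix({self.n_genes} genes x {self.n_cells} cells)"

    # -- subsetting --------------------------------------------------------
    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = list(genes)
        missing = set(genes) - set(self._df.index)
        if missing:
            raise KeyError(f"unknown genes: {sorted(missing)[:5]}")
        return ExpressionMatrix(self._df.loc[genes])

    def subset_cells(self, cells: Iterable[str]) -> "ExpressionMatrix":
        cells = list(cells)
        missing = set(cells) - set(self._df.columns)
        if missing:
            raise KeyError(f"unknown cells: {sorted(missing)[:5]}")
        return ExpressionMatrix(self._df[cells])

    def genes_with_prefix(self, prefix: str) -> list[str]:
        """Gene names starting with ``prefix`` (e.g. ``mt-`` or ``ERCC-``)."""
        return [g for g in self._df.index if str(g).startswith(prefix)]

    # -- interop -----------------------------------------------------------
    def to_anndata(self):
        """Convert to an :class:`anndata.AnnData` (cells x genes) view-copy."""
        import anndata as ad

        return ad.AnnData(
            X=self._df.to_numpy().T.copy(),
            obs=pd.DataFrame(index=self._df.columns.astype(str)),
            var=pd.DataFrame(index=self._df.index.astype(str)),
        )

    @classmethod
    def from_anndata(cls, adata) -> "ExpressionMatrix":
        X = adata.X
        if hasattr(X, "toarray"):
            X = X.toarray()
        return cls(np.asarray(X).T, genes=list(adata.var_names),
                   cells=list(adata.obs_names))
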