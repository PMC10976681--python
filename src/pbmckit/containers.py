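"""Core data container shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp


@dataclass
class CellMatrix:
    """Sparse cells x genes UMI count matrix with aligned metadata.

    Attributes
    ----------
    X : scipy.sparse.csr_matrix
        Integer UMI counts, one row per cell.
    cells : pandas.DataFrame
        Per-cell metadata indexed by barcode. Conventional columns:
        ``sample``, ``batch``, ``disease`` (0/1), ``sex`` (0 female / 1
        male), ``doublet`` (bool), ``cell_type`` (annotation or truth).
    genes : pandas.DataFrame
        Per-gene metadata indexed by gene symbol; may carry ``chrom``
        and ``pos``.
    """

    X: sp.csr_matrix
    cells: pd.DataFrame
    genes: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = sp.csr_matrix(self.X)
        if self.genes is None:
            self.genes = pd.DataFrame(
                index=pd.Index([f"G{i:05d}" for i in range(self.X.shape[1])], name="gene")
            )
        if self.X.shape[0] != len(self.cells):
            raise ValueError(
                f"matrix has {self.X.shape[0]} rows but metadata describes "
                f"{len(self.cells)} cells"
            )
        if self.X.shape[1] != len(self.genes):
            raise ValueError(
                f"matrix has {self.X.shape[1]} columns but metadata describes "
                f"{len(self.genes)} genes"
            )

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    @property
    def gene_names(self) -> pd.Index:
        return self.genes.index

    @property
    def barcodes(self) -> pd.Index:
        return self.cells.index

    def subset_cells(self, mask) -> "CellMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CellMatrix(self.X[idx], self.cells.iloc[idx].copy(), self.genes.copy())

    def subset_genes(self, mask) -> "CellMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CellMatrix(self.X[:, idx], self.cells.copy(), self.genes.iloc[idx].copy())

    def copy(self) -> "CellMatrix":
        return CellMatrix(self.X.copy(), self.cells.copy(), self.genes.copy())

    def depth(self) -> np.ndarray:
        """Total UMI per cell."""
        return np.asarray(self.X.sum(axis=1)).ravel()

    def nodg(self) -> np.ndarray:
        """Number of detected genes (count > 0) per cell."""
        return np.diff(self.X.indptr)
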