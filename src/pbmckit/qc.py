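"""Cell and gene quality filters plus the sex-concordance sanity check."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from pbmckit.containers import CellMatrix
from pbmckit.project import normalize_cells

DEFAULT_MITO_PREFIXES = ("MT-",)


@dataclass
class NodgWindows:
    """Exclusive per-cluster bounds on the number of detected genes."""

    windows: Dict[str, Tuple[int, int]] = field(default_factory=dict)
    default_window: Tuple[int, int] = (500, 2500)

    def __post_init__(self) -> None:
        for label, (lo, hi) in {**self.windows, "default": self.default_window}.items():
            if lo <= 0 or hi <= 0 or lo >= hi:
                raise ValueError(f"invalid NODG window for {label!r}: ({lo}, {hi})")

    def window_for(self, label) -> Tuple[int, int]:
        return self.windows.get(label, self.default_window)


def mito_fraction(cm: CellMatrix,
                  prefixes: Sequence[str] = DEFAULT_MITO_PREFIXES) -> np.ndarray:
    """Per-cell fraction of counts from genes matching any mito prefix."""
    mask = np.zeros(cm.n_genes, dtype=bool)
    for p in prefixes:
        mask |= np.asarray(cm.gene_names.str.startswith(p))
    if not mask.any():
        raise ValueError(
            f"no mitochondrial genes found with prefixes {list(prefixes)}"
        )
    depth = cm.depth().astype(float)
    depth[depth == 0] = 1.0
    mito = np.asarray(cm.X[:, mask].sum(axis=1)).ravel()
    return mito / depth


def filter_genes_by_prevalence(cm: CellMatrix, min_frac: float = 0.001) -> CellMatrix:
    """Keep genes detected (count > 0) in at least ceil(min_frac * n_cells) cells."""
    if not 0.0 <= min_frac < 1.0:
        raise ValueError("min_frac must be in [0, 1)")
    if cm.n_cells == 0 or cm.n_genes == 0:
        raise ValueError("empty matrix")
    n_min = math.ceil(min_frac * cm.n_cells)
    n_cells_per_gene = np.asarray((cm.X > 0).sum(axis=0)).ravel()
    return cm.subset_genes(n_cells_per_gene >= n_min)


def filter_cells(cm: CellMatrix, mito_max: float = 0.07,
                 windows: Optional[NodgWindows] = None,
                 drop_doublets: bool = True,
                 cluster_col: str = "cell_type",
                 mito_prefixes: Sequence[str] = DEFAULT_MITO_PREFIXES):
    """Apply mito, NODG-window and doublet filters.

    NODG bounds are strict on both sides. Returns ``(filtered, report)``
    where the report counts cells removed per criterion (a cell can
    fail several).
    """
    windows = windows or NodgWindows()
    frac = mito_fraction(cm, mito_prefixes)
    nodg = cm.nodg()
    labels = (
        cm.cells[cluster_col]
        if cluster_col in cm.cells.columns
        else pd.Series("default", index=cm.cells.index)
    )
    lo = np.array([windows.window_for(l)[0] for l in labels])
    hi = np.array([windows.window_for(l)[1] for l in labels])

    fail_mito = frac > mito_max
    fail_nodg = ~((nodg > lo) & (nodg < hi))
    if drop_doublets and "doublet" in cm.cells.columns:
        fail_doublet = cm.cells["doublet"].to_numpy().astype(bool)
    else:
        fail_doublet = np.zeros(cm.n_cells, dtype=bool)

    keep = ~(fail_mito | fail_nodg | fail_doublet)
    report = pd.Series({
        "n_input": cm.n_cells,
        "removed_mito": int(fail_mito.sum()),
        "removed_nodg": int(fail_nodg.sum()),
        "removed_doublet": int(fail_doublet.sum()),
        "n_kept": int(keep.sum()),
    }, name="qc_report")
    out = cm.subset_cells(keep)
    out.cells = out.cells.assign(mito_frac=frac[keep], nodg=nodg[keep])
    return out, report


def sex_concordance(cm: CellMatrix, y_genes: Sequence[str],
                    x_genes: Sequence[str], sex_col: str = "sex",
                    sample_col: str = "sample") -> pd.DataFrame:
    """Per-sample mean summed nlog expression of Y and X genes vs annotated sex.

    The Y score is compared against the midpoint of the two annotated
    sex groups' means; samples on the wrong side are flagged. With a
    single annotated sex the threshold is undefined and no flags are
    produced.
    """
    y_genes = [g for g in y_genes if g in cm.gene_names]
    x_genes = [g for g in x_genes if g in cm.gene_names]
    if not y_genes or not x_genes:
        raise ValueError("Y and X gene lists must be nonempty and present in matrix")
    nlog = normalize_cells(cm)
    yi = cm.gene_names.get_indexer(y_genes)
    xi = cm.gene_names.get_indexer(x_genes)
    y_cell = np.asarray(nlog[:, yi].sum(axis=1)).ravel()
    x_cell = np.asarray(nlog[:, xi].sum(axis=1)).ravel()
    df = pd.DataFrame({
        "y_score": y_cell,
        "x_score": x_cell,
        "sample": cm.cells[sample_col].to_numpy(),
        "sex": cm.cells[sex_col].to_numpy(),
    })
    rep = df.groupby("sample").agg(
        y_score=("y_score", "mean"),
        x_score=("x_score", "mean"),
        sex=("sex", "first"),
    )
    rep["flagged"] = False
    sexes = rep["sex"].unique()
    if len(sexes) < 2:
        warnings.warn("single-sex cohort: concordance threshold undefined")
        return rep
    mid = (rep.loc[rep.sex == 1, "y_score"].mean()
           + rep.loc[rep.sex == 0, "y_score"].mean()) / 2.0
    rep["flagged"] = np.where(
        rep["sex"] == 1, rep["y_score"] <= mid, rep["y_score"] > mid
    )
    return rep
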