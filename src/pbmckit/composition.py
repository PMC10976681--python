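"""Cell-composition statistics and the kNN case-enrichment field."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import svds
from sklearn.neighbors import NearestNeighbors
from statsmodels.regression.linear_model import OLS


@dataclass
class CompositionTable:
    """Samples x cell types proportions (% of PBMC) plus covariates."""

    proportions: pd.DataFrame
    covariates: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        p = self.proportions.to_numpy(dtype=float)
        finite = np.nan_to_num(p)
        if (finite < -1e-9).any():
            raise ValueError("proportions must be nonnegative")


def compute_proportions(labels: pd.Series, sample_of_cell: pd.Series,
                        ratios: Optional[Sequence[Tuple[str, str]]] = None,
                        covariates: Optional[pd.DataFrame] = None) -> CompositionTable:
    """Per-sample cell-type proportions (percent), optionally with ratio columns.

    ``ratios`` are (numerator, denominator) type pairs; a zero
    denominator yields a missing value. Samples with zero cells are
    excluded with a warning.
    """
    df = pd.DataFrame({"type": labels, "sample": sample_of_cell}).dropna()
    counts = df.groupby(["sample", "type"], observed=True).size().unstack(fill_value=0)
    totals = counts.sum(axis=1)
    empty = totals == 0
    if empty.any():
        warnings.warn(f"excluding {int(empty.sum())} samples with 0 cells")
        counts = counts.loc[~empty]
        totals = totals.loc[~empty]
    prop = 100.0 * counts.div(totals, axis=0)
    if ratios:
        for num, den in ratios:
            name = f"{num}/{den}"
            n = counts.get(num, pd.Series(0, index=counts.index))
            d = counts.get(den, pd.Series(0, index=counts.index))
            prop[name] = (n / d.replace(0, np.nan)).astype(float)
    cov = covariates.loc[prop.index] if covariates is not None else None
    return CompositionTable(prop, cov)


def composition_regression(tbl: CompositionTable,
                           covariate_cols: Sequence[str]) -> pd.DataFrame:
    """Per-cell-type OLS of proportion on covariates with partial F-tests.

    A Gaussian-response additive model with linear terms only reduces
    to ordinary least squares; each coefficient's partial F-test
    (1 numerator df) supplies the p-value, flagged at p < 0.05.
    """
    if tbl.covariates is None:
        raise ValueError("composition table has no covariates")
    cov = tbl.covariates[list(covariate_cols)].astype(float)
    X = np.column_stack([np.ones(len(cov)), cov.to_numpy()])
    names = ["intercept"] + list(covariate_cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by greedy QR-style elimination
        bad = []
        keep: list = []
        for j in range(X.shape[1]):
            trial = X[:, keep + [j]]
            if np.linalg.matrix_rank(trial) == len(keep) + 1:
                keep.append(j)
            else:
                bad.append(names[j])
        raise ValueError(f"collinear design columns: {bad}")
    if len(cov) < len(covariate_cols) + 2:
        raise ValueError("need at least covariates + 2 complete samples")

    rows = []
    for ct in tbl.proportions.columns:
        y = tbl.proportions[ct].astype(float)
        ok = y.notna() & cov.notna().all(axis=1).reindex(y.index, fill_value=False)
        if ok.sum() < len(covariate_cols) + 2:
            continue
        fit = OLS(y[ok].to_numpy(), X[ok.to_numpy()]).fit()
        for i, term in enumerate(names):
            if term == "intercept":
                continue
            # partial F for one coefficient: F = t^2 on (1, df_resid)
            t = fit.tvalues[i]
            from scipy.stats import f as fdist
            p = float(fdist.sf(t * t, 1, fit.df_resid))
            rows.append({
                "cell_type": ct, "term": term,
                "coef": float(fit.params[i]), "se": float(fit.bse[i]),
                "F": float(t * t), "p": p, "significant": p < 0.05,
            })
    return pd.DataFrame(rows)


def pca_embedding(norm_expr, n_components: int = 30,
                  seed: int = 0) -> np.ndarray:
    """Top principal components of the normalized matrix via truncated SVD."""
    X = norm_expr.astype(float)
    mean = np.asarray(X.mean(axis=0)).ravel()
    k = min(n_components, min(X.shape) - 1)
    u, s, vt = svds(
        sp.csr_matrix(X) if not sp.issparse(X) else X,
        k=k, random_state=seed,
    )
    order = np.argsort(s)[::-1]
    u, s, vt = u[:, order], s[order], vt[order]
    # center scores post-hoc: (X - 1 mean') V = XV - 1 (mean'V)
    scores = u * s - np.ones((X.shape[0], 1)) @ (mean[None, :] @ vt.T)
    return scores


def neighborhood_enrichment(embedding: np.ndarray, case_flag,
                            k: int = 50, pseudocount: float = 0.5) -> np.ndarray:
    """Per-cell log2 enrichment of case cells among k nearest neighbors.

    e = log2(((n_case + c)/(n_ctrl + c)) / (N_case/N_ctrl)) over each
    cell's k Euclidean nearest neighbors (self excluded); the global
    case:control ratio centers the null at 0.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    case = np.asarray(case_flag).astype(bool)
    n = len(case)
    if k >= n:
        raise ValueError("k must be smaller than the number of cells")
    n_case_tot, n_ctrl_tot = int(case.sum()), int((~case).sum())
    if n_case_tot == 0 or n_ctrl_tot == 0:
        raise ValueError("both classes must be present")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    neigh = idx[:, 1:]  # drop self
    n_case = case[neigh].sum(axis=1)
    n_ctrl = k - n_case
    global_ratio = n_case_tot / n_ctrl_tot
    c = pseudocount
    return np.log2(((n_case + c) / (n_ctrl + c)) / global_ratio)
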