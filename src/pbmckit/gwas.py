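"""Genetic-risk conditioning of differential-expression programs.

Per cell type, the evidence score (|log2FC| * -log10 q) of significant
genes is min-max normalized and used as a gene-level covariate in a
one-sided regression against external gene risk scores; effector genes
sit in both the top risk ranks and the upper tail of the normalized
evidence score.
"""

from __future__ import annotations

import warnings
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from pbmckit._stats import bh_adjust


def validate_risk_table(risk: pd.DataFrame) -> pd.DataFrame:
    """Check the gene risk table contract: unique genes, scores >= 0,
    positive integer positions."""
    if risk.index.duplicated().any():
        raise ValueError("duplicate genes in risk table")
    if (risk["score"] < 0).any():
        raise ValueError("risk scores must be nonnegative")
    if (risk["pos"] <= 0).any():
        raise ValueError("positions must be positive")
    return risk


def prepare_des(deg_table: pd.DataFrame, q_keep: float = 0.1) -> Dict[str, pd.Series]:
    """Per cell type: retain genes with q < q_keep and min-max normalize
    their evidence scores to [0, 1].

    Cell types with fewer than 2 retained genes are skipped; a
    degenerate (constant) score vector normalizes to all zeros with a
    warning.
    """
    out: Dict[str, pd.Series] = {}
    t = deg_table.dropna(subset=["q", "des"])
    for ct, sub in t.groupby("cell_type"):
        kept = sub[sub["q"] < q_keep]
        if len(kept) < 2:
            warnings.warn(f"cell type {ct!r}: fewer than 2 retained genes; skipped")
            continue
        des = kept.set_index("gene")["des"].astype(float)
        lo, hi = des.min(), des.max()
        if hi == lo:
            warnings.warn(f"cell type {ct!r}: constant evidence scores; all zero")
            out[ct] = des * 0.0
        else:
            out[ct] = (des - lo) / (hi - lo)
    return out


def _region_mask(risk: pd.DataFrame,
                 region: Optional[Tuple[object, int, int]]) -> pd.Series:
    if region is None:
        return pd.Series(False, index=risk.index)
    chrom, start, end = region
    return (
        (risk["chrom"].astype(str) == str(chrom))
        & (risk["pos"] >= start) & (risk["pos"] <= end)
    )


def heritability_covariate_test(norm_des: Dict[str, pd.Series],
                                risk: pd.DataFrame,
                                exclude_region: Optional[Tuple[object, int, int]] = None,
                                min_genes: int = 50) -> pd.DataFrame:
    """One-sided regression of gene risk score on normalized evidence score.

    Per cell type, OLS slope of risk ~ normalized score over the shared
    gene set (optionally excluding a genomic region); p is the upper
    t-tail (positive association), BH-corrected across cell types.
    """
    risk = validate_risk_table(risk)
    excl = _region_mask(risk, exclude_region)
    usable = risk.loc[~excl, "score"]
    rows = []
    for ct, des in norm_des.items():
        shared = des.index.intersection(usable.index)
        if len(shared) == 0:
            raise ValueError(f"cell type {ct!r}: no genes shared with risk table")
        if len(shared) < min_genes:
            warnings.warn(
                f"cell type {ct!r}: only {len(shared)} shared genes; skipped"
            )
            continue
        x = des.loc[shared].to_numpy(float)
        y = usable.loc[shared].to_numpy(float)
        if np.std(x) == 0:
            rows.append({"cell_type": ct, "beta": 0.0, "t": 0.0,
                         "p": 1.0, "n_genes": len(shared)})
            continue
        res = stats.linregress(x, y)
        df = len(shared) - 2
        p_one = float(stats.t.sf(res.slope / res.stderr, df))
        rows.append({
            "cell_type": ct, "beta": float(res.slope), "t": float(res.slope / res.stderr),
            "p": p_one, "n_genes": len(shared),
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_adjust(out["p"])
        out = out.sort_values("p").reset_index(drop=True)
    return out


def select_effector_genes(norm_des: Dict[str, pd.Series], risk: pd.DataFrame,
                          top_n: int = 200,
                          des_percentile: float = 70.0) -> Dict[str, list]:
    """Effectors per cell type: top-``top_n`` genes by risk score that are
    at or above the ``des_percentile``-th percentile of the normalized
    evidence score within the cell type."""
    risk = validate_risk_table(risk)
    if top_n <= 0:
        return {ct: [] for ct in norm_des}
    top_risk = set(risk["score"].nlargest(top_n).index)
    out = {}
    for ct, des in norm_des.items():
        if len(des) == 0:
            out[ct] = []
            continue
        thresh = np.percentile(des.to_numpy(float), des_percentile)
        high = set(des.index[des >= thresh])
        out[ct] = sorted(top_risk & high)
    return out
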