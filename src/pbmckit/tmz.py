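"""Metagene z-scores per cell type, molecular subtyping, clinical
association, and projection of external bulk expression onto the
cohort's score distribution."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.regression.linear_model import OLS

from pbmckit._stats import log2_cpm
from pbmckit.de import PseudobulkSet

SUBTYPE_NAMES = ["low", "intermediate", "high"]


@dataclass
class TmzMatrix:
    """Samples x cell types metagene z-scores with an average column."""

    scores: pd.DataFrame  # samples x cell types, NaN where missing
    average: pd.Series = field(init=False)
    subtype: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        self.average = self.scores.mean(axis=1, skipna=True).rename("average")


@dataclass
class CompartmentDegSets:
    """Up/down DEG sets unioned into major compartments.

    Genes landing in both the up and the down union of a compartment
    are dropped from both (sign ambiguity).
    """

    sets: Dict[str, Dict[str, List[str]]]

    @classmethod
    def from_cell_types(cls, deg_sets: Dict[str, Dict[str, List[str]]],
                        compartment_of: Dict[str, str]) -> "CompartmentDegSets":
        agg: Dict[str, Dict[str, set]] = {}
        for ct, ud in deg_sets.items():
            comp = compartment_of.get(ct)
            if comp is None:
                continue
            entry = agg.setdefault(comp, {"up": set(), "down": set()})
            entry["up"].update(ud["up"])
            entry["down"].update(ud["down"])
        out = {}
        for comp, entry in agg.items():
            both = entry["up"] & entry["down"]
            if both:
                warnings.warn(
                    f"compartment {comp!r}: dropping {len(both)} genes in "
                    "both up and down sets"
                )
            out[comp] = {
                "up": sorted(entry["up"] - both),
                "down": sorted(entry["down"] - both),
            }
        empty = [c for c, e in out.items() if not e["up"] and not e["down"]]
        if empty:
            warnings.warn(f"empty compartments: {empty}")
        return cls(out)


def _score_expression(expr: pd.DataFrame, up: Sequence[str],
                      down: Sequence[str],
                      gene_stats: Optional[pd.DataFrame] = None) -> pd.Series:
    """mean(z over up) - mean(z over down) on a samples x genes frame.

    z-scores are across samples; with fewer than 3 samples (or when
    ``gene_stats`` is given) genes are standardized against reference
    means/sds instead.
    """
    up = [g for g in up if g in expr.columns]
    down = [g for g in down if g in expr.columns]
    if gene_stats is not None or len(expr) < 3:
        if gene_stats is None:
            raise ValueError(
                "fewer than 3 samples: reference gene statistics required"
            )
        gs = gene_stats
        up = [g for g in up if g in gs.index and gs.loc[g, "sd"] > 0]
        down = [g for g in down if g in gs.index and gs.loc[g, "sd"] > 0]
        z = (expr[up + down] - gs.loc[up + down, "mean"]) / gs.loc[up + down, "sd"]
    else:
        sd = expr[up + down].std(axis=0, ddof=0)
        keepable = sd[sd > 0].index
        dropped = len(up) + len(down) - len(keepable)
        if dropped:
            warnings.warn(f"dropping {dropped} zero-variance genes from scoring")
        up = [g for g in up if g in keepable]
        down = [g for g in down if g in keepable]
        sub = expr[up + down]
        z = (sub - sub.mean(axis=0)) / sub.std(axis=0, ddof=0)
    up_part = z[up].mean(axis=1) if up else pd.Series(0.0, index=expr.index)
    down_part = z[down].mean(axis=1) if down else pd.Series(0.0, index=expr.index)
    return up_part - down_part


def compute_tmz(pbs: PseudobulkSet,
                deg_sets: Dict[str, Dict[str, List[str]]]) -> TmzMatrix:
    """Per (sample, cell type) score: mean z of up-DEGs minus mean z of
    down-DEGs, on log2-CPM pseudo-bulk z-transformed across samples.

    Pairs excluded during pseudo-bulk construction are missing; the
    average column is the mean over non-missing cell types.
    """
    cols = {}
    for ct, pb in pbs.per_type.items():
        sets = deg_sets.get(ct)
        if not sets or (not sets["up"] and not sets["down"]):
            continue
        if len(pb.counts) < 3:
            warnings.warn(f"cell type {ct!r}: fewer than 3 samples; skipped")
            continue
        expr = pb.log2_cpm()
        cols[ct] = _score_expression(expr, sets["up"], sets["down"])
    scores = pd.DataFrame(cols)
    all_samples = sorted(
        {s for pb in pbs.per_type.values() for s in pb.counts.index}
    )
    scores = scores.reindex(all_samples)
    return TmzMatrix(scores)


def subtype_samples(tm: TmzMatrix, k: int = 3, restarts: int = 20,
                    seed: int = 0) -> pd.Series:
    """k-means over score vectors; clusters named by ascending mean average
    score (low/intermediate/high for k=3).

    Missing entries are imputed with the sample's own mean over
    non-missing cell types; all-missing samples are excluded.
    """
    S = tm.scores.copy()
    all_missing = S.isna().all(axis=1)
    if all_missing.any():
        warnings.warn(
            f"excluding {int(all_missing.sum())} all-missing samples from subtyping"
        )
        S = S.loc[~all_missing]
    if len(S) < k:
        raise ValueError("fewer scoreable samples than clusters")
    row_mean = S.mean(axis=1)
    M = S.to_numpy(dtype=float)
    M = np.where(np.isnan(M), row_mean.to_numpy()[:, None], M)
    if np.unique(M, axis=0).shape[0] < k:
        warnings.warn("fewer distinct score vectors than clusters; single cluster")
        labels = pd.Series(SUBTYPE_NAMES[0], index=S.index, name="subtype")
        tm.subtype = labels.reindex(tm.scores.index)
        return tm.subtype
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed).fit(M)
    avg = tm.average.loc[S.index].to_numpy()
    order = np.argsort([avg[km.labels_ == c].mean() for c in range(k)])
    names = SUBTYPE_NAMES if k == 3 else [f"tier{r + 1}" for r in range(k)]
    name_of = {c: names[r] for r, c in enumerate(order)}
    labels = pd.Series(
        [name_of[c] for c in km.labels_], index=S.index, name="subtype"
    )
    tm.subtype = labels.reindex(tm.scores.index)
    return tm.subtype


def tmz_association(tm: TmzMatrix, covariates: pd.DataFrame,
                    gada_col: str = "gada",
                    hla_col: str = "hla_count") -> Dict[str, pd.DataFrame]:
    """Clinical associations of the scores.

    Returns {"regression": OLS coefficients with partial F-test p per
    cell type, "spearman": rank correlation vs the GADA column,
    "kruskal": Kruskal-Wallis across HLA-count categories}. Constant
    covariates are dropped with a warning; a single HLA category yields
    a missing test.
    """
    cols = list(tm.scores.columns) + ["average"]
    frame = tm.scores.copy()
    frame["average"] = tm.average
    cov = covariates.loc[frame.index.intersection(covariates.index)]
    frame = frame.loc[cov.index]

    terms = [c for c in cov.columns if c not in ()]
    keep_terms = []
    for c in terms:
        if cov[c].nunique(dropna=True) < 2:
            warnings.warn(f"dropping constant covariate {c!r}")
        else:
            keep_terms.append(c)

    reg_rows, sp_rows, kw_rows = [], [], []
    for ct in cols:
        y = frame[ct]
        ok = y.notna() & cov[keep_terms].notna().all(axis=1)
        if ok.sum() >= len(keep_terms) + 2 and keep_terms:
            X = np.column_stack([
                np.ones(int(ok.sum())), cov.loc[ok, keep_terms].to_numpy(float)
            ])
            fit = OLS(y[ok].to_numpy(), X).fit()
            for i, term in enumerate(keep_terms, start=1):
                t = fit.tvalues[i]
                p = float(stats.f.sf(t * t, 1, fit.df_resid))
                reg_rows.append({
                    "cell_type": ct, "term": term,
                    "coef": float(fit.params[i]), "se": float(fit.bse[i]),
                    "p": p,
                })
        if gada_col in cov.columns:
            ok_g = y.notna() & cov[gada_col].notna()
            if ok_g.sum() >= 3:
                rho, p = stats.spearmanr(y[ok_g], cov.loc[ok_g, gada_col])
                sp_rows.append({"cell_type": ct, "rho": float(rho), "p": float(p)})
        if hla_col in cov.columns:
            ok_h = y.notna() & cov[hla_col].notna()
            groups = [
                y[ok_h][cov.loc[ok_h, hla_col] == lvl]
                for lvl in sorted(cov.loc[ok_h, hla_col].unique())
            ]
            groups = [g for g in groups if len(g) > 0]
            if len(groups) >= 2:
                h, p = stats.kruskal(*groups)
                kw_rows.append({"cell_type": ct, "H": float(h), "p": float(p)})
            else:
                kw_rows.append({"cell_type": ct, "H": np.nan, "p": np.nan})
    return {
        "regression": pd.DataFrame(reg_rows),
        "spearman": pd.DataFrame(sp_rows),
        "kruskal": pd.DataFrame(kw_rows),
    }


def project_bulk_tmz(bulk_expr: pd.DataFrame, cds: CompartmentDegSets,
                     reference: pd.DataFrame,
                     gene_stats: Optional[pd.DataFrame] = None,
                     min_genes: int = 10) -> pd.DataFrame:
    """Score external bulk samples and map onto the reference distribution.

    ``bulk_expr`` is samples x genes (log scale recommended);
    ``reference`` is the cohort's samples x compartments score frame.
    Raw compartment scores (z across the bulk batch when n >= 3, else z
    against ``gene_stats`` reference means/sds) are quantile-mapped:
    the score at empirical quantile q of the bulk batch goes to the q-th
    quantile of the reference scores, preserving ranks. Compartments
    with fewer than ``min_genes`` overlapping genes are skipped.
    """
    out = {}
    for comp, sets in cds.sets.items():
        if comp not in reference.columns:
            continue
        genes = [g for g in sets["up"] + sets["down"] if g in bulk_expr.columns]
        if len(genes) < min_genes:
            warnings.warn(
                f"compartment {comp!r}: only {len(genes)} overlapping genes; skipped"
            )
            continue
        raw = _score_expression(bulk_expr, sets["up"], sets["down"], gene_stats)
        ref = reference[comp].dropna().to_numpy()
        ranks = stats.rankdata(raw, method="average")
        qq = (ranks - 0.5) / len(raw)
        out[comp] = pd.Series(
            np.quantile(ref, qq, method="linear"), index=raw.index
        )
    return pd.DataFrame(out)


def paired_score_test(pre: pd.Series, post: pd.Series):
    """Paired t-test of projected scores (e.g., pre vs post treatment)."""
    common = pre.index.intersection(post.index)
    t, p = stats.ttest_rel(pre.loc[common], post.loc[common])
    return float(t), float(p)
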