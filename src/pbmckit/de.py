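"""Pseudo-bulk negative-binomial differential expression.

A minimal NB-Wald pipeline: median-of-ratios size factors, per-gene
method-of-moments dispersions shrunk toward a mean-dispersion trend,
NB GLM (log link, intercept + condition) fit by vectorized IRLS, Wald
tests with BH correction, evidence scores, DEG calling, and a
cell-level NB GLM marker test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from pbmckit._stats import bh_adjust, log2_cpm, neglog10_q
from pbmckit.containers import CellMatrix

LN2 = np.log(2.0)
MIN_PHI, MAX_PHI = 1e-8, 10.0
DEFAULT_LFC_MIN = np.log2(1.3)


@dataclass
class Pseudobulk:
    """samples x genes summed UMI for one cell type."""

    cell_type: str
    counts: pd.DataFrame  # samples x genes, ints
    cell_counts: pd.Series  # cells per retained sample
    condition: pd.Series  # 0/1 per retained sample

    def log2_cpm(self) -> pd.DataFrame:
        return pd.DataFrame(
            log2_cpm(self.counts.to_numpy()),
            index=self.counts.index, columns=self.counts.columns,
        )


@dataclass
class PseudobulkSet:
    per_type: Dict[str, Pseudobulk]
    excluded_pairs: pd.DataFrame  # (sample, cell_type, n_cells) below min_cells
    skipped_types: List[str] = field(default_factory=list)

    def types(self) -> List[str]:
        return list(self.per_type)


def make_pseudobulk(cm: CellMatrix, labels: pd.Series,
                    condition: Optional[pd.Series] = None,
                    min_cells: int = 5, min_sample_frac: float = 0.05,
                    sample_col: str = "sample",
                    merge_map: Optional[Dict[str, str]] = None) -> PseudobulkSet:
    """Sum UMI per (sample, cell type), applying the exclusion rules.

    Pairs built from fewer than ``min_cells`` cells are dropped; within
    each cell type, genes with nonzero summed count in less than
    ``min_sample_frac`` of the retained samples are dropped. Types left
    with fewer than 3 samples in either condition group are skipped
    with a warning. ``merge_map`` collapses labels before grouping.
    """
    lab = labels.reindex(cm.barcodes)
    if merge_map:
        lab = lab.replace(merge_map)
    samples = cm.cells[sample_col]
    if condition is None:
        condition = (
            cm.cells.groupby(sample_col)["disease"].first()
            if "disease" in cm.cells.columns else None
        )

    per_type: Dict[str, Pseudobulk] = {}
    excluded = []
    skipped = []
    for ct in sorted(lab.dropna().unique()):
        in_type = (lab == ct).to_numpy()
        samp = samples[in_type]
        cell_idx = np.flatnonzero(in_type)
        groups = pd.Series(cell_idx, index=samp.to_numpy()).groupby(level=0)
        sums, kept_samples, kept_counts = [], [], []
        for s, idx in groups:
            n = len(idx)
            if n < min_cells:
                excluded.append({"sample": s, "cell_type": ct, "n_cells": n})
                continue
            sums.append(np.asarray(cm.X[idx.to_numpy()].sum(axis=0)).ravel())
            kept_samples.append(s)
            kept_counts.append(n)
        if not sums:
            skipped.append(ct)
            continue
        counts = pd.DataFrame(
            np.vstack(sums), index=pd.Index(kept_samples, name="sample"),
            columns=cm.gene_names, dtype=np.int64,
        )
        frac_detected = (counts > 0).mean(axis=0)
        counts = counts.loc[:, frac_detected >= min_sample_frac]
        cond = (
            condition.reindex(counts.index)
            if condition is not None
            else pd.Series(np.nan, index=counts.index)
        )
        two_groups = condition is not None and condition.nunique() > 1
        if two_groups:
            n_per_group = cond.value_counts()
            if (n_per_group.reindex([0, 1]).fillna(0) < 3).any():
                warnings.warn(
                    f"cell type {ct!r}: fewer than 3 retained samples in a "
                    "group; skipped"
                )
                skipped.append(ct)
                continue
        per_type[ct] = Pseudobulk(
            cell_type=ct, counts=counts,
            cell_counts=pd.Series(kept_counts, index=counts.index),
            condition=cond,
        )
    return PseudobulkSet(
        per_type=per_type,
        excluded_pairs=pd.DataFrame(
            excluded, columns=["sample", "cell_type", "n_cells"]
        ),
        skipped_types=skipped,
    )


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors against the geometric-mean reference.

    Genes with a zero in any sample are excluded from the reference
    (log geometric mean undefined); falls back to library-size ratios
    if no gene survives.
    """
    counts = np.asarray(counts, dtype=float)
    with np.errstate(divide="ignore"):
        logc = np.log(counts)
    usable = np.isfinite(logc).all(axis=0)
    if not usable.any():
        warnings.warn("no all-positive genes; using library-size factors")
        sf = counts.sum(axis=1)
        return sf / np.exp(np.mean(np.log(sf)))
    ref = logc[:, usable].mean(axis=0)
    sf = np.exp(np.median(logc[:, usable] - ref, axis=1))
    return sf / np.exp(np.mean(np.log(sf)))


def _dispersion_trend(mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Robust fit of phi ~ a0 + a1/mu; returns trend values per gene."""
    informative = phi > 2 * MIN_PHI
    if informative.sum() < 10:
        return np.full_like(mu, max(np.median(phi), MIN_PHI))
    m, p = mu[informative], phi[informative]
    hi = m > np.median(m)
    a0 = max(np.median(p[hi]) if hi.any() else np.median(p), MIN_PHI)
    a1 = max(np.median((p - a0) * m), 0.0)
    return np.clip(a0 + a1 / np.maximum(mu, 1e-8), MIN_PHI, MAX_PHI)


def estimate_dispersions(norm_counts: np.ndarray, condition: np.ndarray,
                         sf: np.ndarray):
    """Method-of-moments gene dispersions, geometric 50/50 trend shrinkage."""
    q = norm_counts
    n = q.shape[0]
    groups = [condition == 0, condition == 1]
    resid_ss = np.zeros(q.shape[1])
    for g in groups:
        if g.sum() > 0:
            resid_ss += ((q[g] - q[g].mean(axis=0)) ** 2).sum(axis=0)
    v = resid_ss / max(n - 2, 1)
    mu = q.mean(axis=0)
    # Var(K/s) ~ mu/s + phi mu^2 -> subtract the Poisson part
    shot = mu * np.mean(1.0 / sf)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_mom = (v - shot) / np.maximum(mu, 1e-8) ** 2
    phi_mom = np.clip(np.nan_to_num(phi_mom, nan=MIN_PHI), MIN_PHI, MAX_PHI)
    trend = _dispersion_trend(mu, phi_mom)
    phi = np.exp(0.5 * np.log(phi_mom) + 0.5 * np.log(trend))
    return np.clip(phi, MIN_PHI, MAX_PHI), phi_mom, trend


def _nb_irls_two_group(K: np.ndarray, x: np.ndarray, log_sf: np.ndarray,
                       phi: np.ndarray, max_iter: int = 50, tol: float = 1e-8):
    """Vectorized IRLS for log mu = b0 + b1 x + offset, NB variance.

    K: samples x genes, x: 0/1 condition, phi: per-gene dispersion.
    Returns (b0, b1, se1, converged).
    """
    n, G = K.shape
    x = x.astype(float)
    # moment start from group means of normalized counts
    qn = K / np.exp(log_sf)[:, None]
    m0 = np.maximum(qn[x == 0].mean(axis=0), 1e-8)
    m1 = np.maximum(qn[x == 1].mean(axis=0), 1e-8)
    b0 = np.log(m0)
    b1 = np.log(m1) - b0
    converged = np.zeros(G, dtype=bool)
    for _ in range(max_iter):
        eta = b0[None, :] + np.outer(x, b1) + log_sf[:, None]
        mu = np.exp(np.clip(eta, -30.0, 30.0))
        w = mu / (1.0 + phi[None, :] * mu)
        z = eta - log_sf[:, None] + (K - mu) / mu
        sw = w.sum(axis=0)
        swx = (w * x[:, None]).sum(axis=0)
        swxx = swx  # x is 0/1 so x^2 == x
        swz = (w * z).sum(axis=0)
        swxz = (w * x[:, None] * z).sum(axis=0)
        det = sw * swxx - swx * swx
        det = np.where(np.abs(det) < 1e-12, np.nan, det)
        nb0 = (swxx * swz - swx * swxz) / det
        nb1 = (sw * swxz - swx * swz) / det
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            step = np.nanmax(
                np.abs(np.vstack([nb0 - b0, nb1 - b1])), axis=0
            )
        bad = ~np.isfinite(nb0) | ~np.isfinite(nb1)
        nb0 = np.where(bad, b0, nb0)
        nb1 = np.where(bad, b1, nb1)
        b0, b1 = nb0, nb1
        converged = converged | (np.nan_to_num(step, nan=np.inf) < tol)
        if converged.all():
            break
    eta = b0[None, :] + np.outer(x, b1) + log_sf[:, None]
    mu = np.exp(np.clip(eta, -30.0, 30.0))
    w = mu / (1.0 + phi[None, :] * mu)
    sw = w.sum(axis=0)
    swx = (w * x[:, None]).sum(axis=0)
    det = sw * swx - swx * swx
    with np.errstate(divide="ignore", invalid="ignore"):
        se1 = np.sqrt(sw / det)
    return b0, b1, se1, converged


def nb_de_test(pb: Pseudobulk, shrink_lfc: bool = False) -> pd.DataFrame:
    """NB-Wald differential expression for one cell type's pseudo-bulk.

    Returns per-gene log2FC (case vs control), SE, Wald p, BH q and the
    evidence score des = |log2FC| * -log10(q). Unconverged genes get
    missing p/q and are excluded from scoring.
    """
    cond = pb.condition.to_numpy()
    if pd.isna(cond).any():
        raise ValueError("condition labels required for the DE test")
    for g in (0, 1):
        if (cond == g).sum() < 3:
            raise ValueError("need >= 3 samples per group")
    K = pb.counts.to_numpy(dtype=float)
    sf = size_factors(K)
    qn = K / sf[:, None]
    phi, _, _ = estimate_dispersions(qn, cond, sf)
    b0, b1, se1, converged = _nb_irls_two_group(K, cond, np.log(sf), phi)

    with np.errstate(divide="ignore", invalid="ignore"):
        wald = b1 / se1
    p = 2.0 * stats.norm.sf(np.abs(wald))
    p = np.where(converged & np.isfinite(p), p, np.nan)
    q = bh_adjust(p)
    lfc = b1 / LN2
    se_lfc = se1 / LN2
    if shrink_lfc:
        ok = np.isfinite(lfc) & np.isfinite(se_lfc)
        tau2 = max(np.mean(lfc[ok] ** 2) - np.mean(se_lfc[ok] ** 2), 1e-6)
        lfc_shrunk = lfc * tau2 / (tau2 + se_lfc ** 2)
    else:
        lfc_shrunk = lfc
    des = np.abs(lfc_shrunk) * neglog10_q(q)
    return pd.DataFrame({
        "gene": pb.counts.columns,
        "cell_type": pb.cell_type,
        "base_mean": qn.mean(axis=0),
        "lfc": lfc_shrunk,
        "lfc_mle": lfc,
        "se": se_lfc,
        "p": p,
        "q": q,
        "des": np.where(np.isfinite(p), des, np.nan),
        "converged": converged,
    }).set_index("gene")


def de_all_types(pbs: PseudobulkSet, shrink_lfc: bool = False) -> pd.DataFrame:
    frames = []
    for ct, pb in pbs.per_type.items():
        try:
            frames.append(nb_de_test(pb, shrink_lfc=shrink_lfc).reset_index())
        except ValueError as e:
            warnings.warn(f"skipping {ct!r}: {e}")
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def call_degs(deg_table: pd.DataFrame, lfc_min: float = DEFAULT_LFC_MIN,
              q_max: float = 0.1) -> Dict[str, Dict[str, List[str]]]:
    """Up/down DEG sets per cell type: |lfc| >= lfc_min and q <= q_max.

    Both thresholds are inclusive. Returns {cell_type: {"up": [...],
    "down": [...]}} with direction given by the lfc sign.
    """
    out: Dict[str, Dict[str, List[str]]] = {}
    t = deg_table.dropna(subset=["q"])
    sig = t[t["q"] <= q_max]
    for ct, sub in sig.groupby("cell_type"):
        up = sorted(sub.loc[sub["lfc"] >= lfc_min, "gene"])
        down = sorted(sub.loc[sub["lfc"] <= -lfc_min, "gene"])
        out[ct] = {"up": up, "down": down}
    for ct in deg_table["cell_type"].unique():
        out.setdefault(ct, {"up": [], "down": []})
    return out


def _nb_irls_multi(K: np.ndarray, X: np.ndarray, offset: np.ndarray,
                   phi: np.ndarray, max_iter: int = 30, tol: float = 1e-6):
    """IRLS with a general design, vectorized over genes via stacked solves."""
    n, p = X.shape
    G = K.shape[1]
    beta = np.zeros((G, p))
    beta[:, 0] = np.log(np.maximum(
        (K / np.exp(offset)[:, None]).mean(axis=0), 1e-8))
    converged = np.zeros(G, dtype=bool)
    for _ in range(max_iter):
        eta = X @ beta.T + offset[:, None]
        mu = np.exp(np.clip(eta, -30.0, 30.0))
        w = mu / (1.0 + phi[None, :] * mu)
        z = eta - offset[:, None] + (K - mu) / mu
        XtWX = np.einsum("ip,ig,iq->gpq", X, w, X)
        XtWz = np.einsum("ip,ig,ig->gp", X, w, z)[..., None]
        try:
            new = np.linalg.solve(XtWX, XtWz)[..., 0]
        except np.linalg.LinAlgError:
            new = np.linalg.solve(
                XtWX + 1e-8 * np.eye(p)[None], XtWz
            )[..., 0]
        bad = ~np.isfinite(new).all(axis=1)
        new[bad] = beta[bad]
        step = np.abs(new - beta).max(axis=1)
        beta = new
        converged |= step < tol
        if converged.all():
            break
    eta = X @ beta.T + offset[:, None]
    mu = np.exp(np.clip(eta, -30.0, 30.0))
    w = mu / (1.0 + phi[None, :] * mu)
    XtWX = np.einsum("ip,ig,iq->gpq", X, w, X)
    cov = np.linalg.pinv(XtWX)
    se = np.sqrt(np.maximum(cov[:, np.arange(p), np.arange(p)], 0.0))
    return beta, se, converged


def marker_genes(cm: CellMatrix, labels: pd.Series,
                 covariate_cols: Sequence[str] = ("batch", "disease"),
                 min_pct: float = 0.25, lfc_min_nlog: float = 0.25,
                 q_max: float = 0.05, dispersion: float = 0.5) -> pd.DataFrame:
    """Cell-level NB GLM marker test of each type against the rest.

    Genes must be detected in >= ``min_pct`` of cells in the type or in
    the rest; markers need mean-nlog fold-change above ``lfc_min_nlog``
    and BH q below ``q_max``. Batch/disease covariates are regressed
    out as indicator terms.
    """
    from pbmckit.project import normalize_cells

    lab = labels.reindex(cm.barcodes)
    types = sorted(lab.dropna().unique())
    if len(types) < 2:
        raise ValueError("marker test needs at least 2 cell types")
    nlog = normalize_cells(cm)
    nlog_d = np.asarray(nlog.todense())
    detected = (cm.X > 0).toarray()
    depth = np.maximum(cm.depth().astype(float), 1.0)
    offset = np.log(depth)

    cov_blocks = []
    for c in covariate_cols:
        if c not in cm.cells.columns:
            continue
        d = pd.get_dummies(cm.cells[c], prefix=c, drop_first=True)
        if d.shape[1]:
            cov_blocks.append(d.to_numpy(dtype=float))
    cov_mat = np.hstack(cov_blocks) if cov_blocks else np.zeros((cm.n_cells, 0))

    rows = []
    K_all = np.asarray(cm.X.todense(), dtype=float)
    for ct in types:
        in_type = (lab == ct).to_numpy()
        pct_in = detected[in_type].mean(axis=0)
        pct_out = detected[~in_type].mean(axis=0)
        testable = np.flatnonzero((pct_in >= min_pct) | (pct_out >= min_pct))
        if testable.size == 0:
            continue
        X = np.column_stack([
            np.ones(cm.n_cells), in_type.astype(float), cov_mat
        ])
        phi = np.full(testable.size, dispersion)
        beta, se, conv = _nb_irls_multi(
            K_all[:, testable], X, offset, phi
        )
        wald = beta[:, 1] / np.where(se[:, 1] > 0, se[:, 1], np.nan)
        p = 2.0 * stats.norm.sf(np.abs(wald))
        p = np.where(conv & np.isfinite(p), p, np.nan)
        q = bh_adjust(p)
        nlog_fc = nlog_d[in_type][:, testable].mean(axis=0) \
            - nlog_d[~in_type][:, testable].mean(axis=0)
        for j, gi in enumerate(testable):
            rows.append({
                "gene": cm.gene_names[gi], "cell_type": ct,
                "nlog_fc": nlog_fc[j], "p": p[j], "q": q[j],
                "pct_in": pct_in[gi], "pct_out": pct_out[gi],
                "is_marker": bool(
                    np.isfinite(q[j]) and nlog_fc[j] > lfc_min_nlog
                    and q[j] < q_max
                ),
            })
    return pd.DataFrame(rows)
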