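"""Reference-panel projection, clustering and multi-resolution annotation.

Cells are normalized, correlated with reference cell-type profiles
over shared feature genes, the correlation sharpened by a
sign-preserving power and row-z-transformed; cells are then clustered
on the transformed projection and clusters labelled by their dominant
reference type, with an explicit ambiguity rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

AMBIGUOUS = "ambiguous"


@dataclass
class ReferencePanel:
    """Cell types x feature genes matrix of log10 reference expression."""

    name: str
    matrix: pd.DataFrame
    parent_compartment: Optional[Dict[str, str]] = None

    def __post_init__(self) -> None:
        if self.matrix.index.duplicated().any():
            raise ValueError("duplicate cell type names in panel")
        if self.matrix.shape[1] == 0:
            raise ValueError("panel has no feature genes")
        if not np.isfinite(self.matrix.to_numpy()).all():
            raise ValueError("panel contains non-finite entries")

    @property
    def types(self) -> List[str]:
        return list(self.matrix.index)

    @property
    def feature_genes(self) -> List[str]:
        return list(self.matrix.columns)


@dataclass
class ProjectionMatrix:
    """Cell types x cells transformed-correlation scores."""

    scores: pd.DataFrame  # types x cells
    power: int = 4
    z_scored: bool = True
    undefined_cells: List[str] = field(default_factory=list)
    flat_rows: List[str] = field(default_factory=list)


def normalize_cells(cm, target_depth: Optional[float] = None) -> sp.csr_matrix:
    """Depth scaling followed by natural log1p ('nlog' expression).

    Each cell is scaled to ``target_depth`` total counts (the cohort
    median depth when not given, in which case the output depends on
    the cohort's depth scale). Replaces an external variance-stabilizing
    normalization with a deterministic depth-invariant transform;
    all-zero cells come out as zero vectors (warned).
    """
    depth = cm.depth().astype(float)
    zero = depth == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero cells normalized to zero vectors")
    if target_depth is not None:
        target = float(target_depth)
    else:
        target = np.median(depth[~zero]) if (~zero).any() else 1.0
    scale = np.divide(target, depth, out=np.zeros_like(depth), where=~zero)
    X = sp.diags(scale) @ cm.X
    X.data = np.log1p(X.data)
    return sp.csr_matrix(X)


def project_to_panel(norm_expr, gene_names: pd.Index, panel: ReferencePanel,
                     power: int = 4, cell_ids: Optional[pd.Index] = None) -> ProjectionMatrix:
    """Pearson-correlate each cell with each panel row over shared feature genes.

    r is transformed sign(r) * |r|^power and then z-scored within each
    panel row across cells. Cells that are constant over the shared
    feature genes have undefined correlation; their scores are NaN and
    the cells are listed in ``undefined_cells``.
    """
    shared = [g for g in panel.feature_genes if g in gene_names]
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} shared feature genes between cells and panel "
            f"{panel.name!r}; need >= 3"
        )
    gi = gene_names.get_indexer(shared)
    E = norm_expr[:, gi]
    E = E.toarray() if sp.issparse(E) else np.asarray(E, dtype=float)
    P = panel.matrix[shared].to_numpy()  # types x shared

    Ec = E - E.mean(axis=1, keepdims=True)
    Pc = P - P.mean(axis=1, keepdims=True)
    e_sd = np.sqrt((Ec ** 2).sum(axis=1))
    p_sd = np.sqrt((Pc ** 2).sum(axis=1))
    defined = e_sd > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Pc @ Ec.T) / np.outer(p_sd, e_sd)  # types x cells
    r[:, ~defined] = np.nan

    t = np.sign(r) * np.abs(r) ** power
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(t, axis=1, keepdims=True)
        sd = np.nanstd(t, axis=1, keepdims=True)
    flat = (sd.ravel() == 0) | ~np.isfinite(sd.ravel())
    sd_safe = np.where(flat[:, None], 1.0, sd)
    z = (t - mu) / sd_safe
    z[flat, :] = 0.0
    z[:, ~defined] = np.nan

    if cell_ids is None:
        cell_ids = pd.RangeIndex(E.shape[0])
    return ProjectionMatrix(
        scores=pd.DataFrame(z, index=panel.matrix.index, columns=cell_ids),
        power=power,
        z_scored=True,
        undefined_cells=list(np.asarray(cell_ids)[~defined]),
        flat_rows=list(np.asarray(panel.matrix.index)[flat]),
    )


def _corr_distance(cols: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between projection columns (cells)."""
    c = cols - cols.mean(axis=0, keepdims=True)
    sd = np.sqrt((c ** 2).sum(axis=0))
    sd[sd == 0] = 1.0
    corr = (c.T @ c) / np.outer(sd, sd)
    d = 1.0 - np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0


def _mean_silhouette(dist: np.ndarray, labels: np.ndarray) -> float:
    if len(np.unique(labels)) < 2:
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(silhouette_score(dist, labels, metric="precomputed"))


def cluster_by_projection(proj: ProjectionMatrix, min_cluster_size: int = 20,
                          n_clusters: Optional[int] = None) -> pd.Series:
    """Average-linkage clustering on correlation distance with a dynamic cut.

    The dynamic cut recursively splits dendrogram branches while both
    children hold at least ``min_cluster_size`` cells and the split
    improves the global mean silhouette (a single cluster scores 0).
    Passing ``n_clusters`` switches to a plain fixed-k cut.
    """
    Z = proj.scores.to_numpy()
    defined = ~np.isnan(Z).any(axis=0)
    cols = np.flatnonzero(defined)
    cells = proj.scores.columns[cols]
    n = len(cols)
    if n < 2:
        raise ValueError("need at least 2 cells with defined projections")
    dist = _corr_distance(Z[:, cols])
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")

    if n_clusters is not None:
        flat = hierarchy.fcluster(link, t=n_clusters, criterion="maxclust")
        return pd.Series(flat, index=cells, name="cluster")

    labels = np.zeros(n, dtype=int)
    if n < max(2 * min_cluster_size, 2):
        return pd.Series(labels, index=cells, name="cluster")

    tree = hierarchy.to_tree(link)
    next_label = [1]

    def leaves(node):
        return node.pre_order(lambda x: x.id)

    def split(node, score):
        if node.is_leaf():
            return
        left, right = leaves(node.get_left()), leaves(node.get_right())
        if len(left) < min_cluster_size or len(right) < min_cluster_size:
            return
        trial = labels.copy()
        trial[right] = next_label[0]
        new_score = _mean_silhouette(dist, trial)
        if new_score > score:
            labels[right] = next_label[0]
            next_label[0] += 1
            split(node.get_left(), new_score)
            split(node.get_right(), new_score)

    split(tree, 0.0)
    return pd.Series(labels, index=cells, name="cluster")


def annotate_clusters(proj: ProjectionMatrix, labels: pd.Series,
                      z_min: float = 0.75, margin: float = 0.5) -> pd.Series:
    """Assign each cluster the panel type with the highest mean z-score.

    A cluster is ``ambiguous`` when its best type's mean z is below
    ``z_min`` or within ``margin`` of the runner-up.
    """
    out = {}
    S = proj.scores
    for cl in labels.unique():
        cells = labels.index[labels == cl]
        mean_z = S[cells].mean(axis=1)
        order = mean_z.sort_values(ascending=False)
        best = order.iloc[0]
        second = order.iloc[1] if len(order) > 1 else -np.inf
        if best >= z_min and (best - second) >= margin:
            out[cl] = order.index[0]
        else:
            out[cl] = AMBIGUOUS
    return pd.Series(out, name="annotation")


def annotate_cells(norm_expr, gene_names: pd.Index, panel: ReferencePanel,
                   cell_ids: pd.Index, power: int = 4,
                   min_cluster_size: int = 20, z_min: float = 0.75,
                   margin: float = 0.5):
    """project -> cluster -> annotate; returns (per-cell labels, cluster mean z)."""
    proj = project_to_panel(norm_expr, gene_names, panel, power, cell_ids)
    clusters = cluster_by_projection(proj, min_cluster_size)
    ann = annotate_clusters(proj, clusters, z_min, margin)
    per_cell = clusters.map(ann)
    cluster_best_z = {
        cl: proj.scores[clusters.index[clusters == cl]].mean(axis=1).max()
        for cl in clusters.unique()
    }
    per_cell_z = clusters.map(cluster_best_z)
    return per_cell, per_cell_z


def multiresolution_annotate(cm, major_panel: ReferencePanel,
                             subpanels: Optional[Dict[str, Sequence[ReferencePanel]]] = None,
                             power: int = 4, min_cluster_size: int = 20,
                             z_min: float = 0.75, margin: float = 0.5,
                             z_fix: float = 0.75) -> pd.Series:
    """Hierarchical annotation mirroring sequential panel projection.

    Cells are first annotated against the major panel; each compartment
    with subpanels is then re-projected panel by panel — cells whose
    cluster matches a subpanel type with mean z >= ``z_fix`` are fixed,
    the rest passed to the next subpanel (the last subpanel annotates
    whatever remains). Ambiguous cells are NA.
    """
    subpanels = subpanels or {}
    seen: set = set()
    for comp, panels in subpanels.items():
        if comp in seen:
            raise ValueError(f"cycle or duplicate compartment {comp!r} in hierarchy")
        seen.add(comp)

    norm = normalize_cells(cm)
    labels, _ = annotate_cells(
        norm, cm.gene_names, major_panel, cm.barcodes,
        power, min_cluster_size, z_min, margin,
    )
    final = labels.copy().astype(object)
    final[final == AMBIGUOUS] = pd.NA

    for comp, panels in subpanels.items():
        cell_mask = final == comp
        remaining = final.index[cell_mask]
        for j, panel in enumerate(panels):
            if len(remaining) < 2:
                break
            ridx = cm.barcodes.get_indexer(remaining)
            sub_labels, sub_z = annotate_cells(
                norm[ridx], cm.gene_names, panel, remaining,
                power, min_cluster_size, z_min, margin,
            )
            is_last = j == len(panels) - 1
            assigned = sub_labels[
                (sub_labels != AMBIGUOUS) & (is_last | (sub_z >= z_fix))
            ]
            final.loc[assigned.index] = assigned
            if is_last:
                dropped = sub_labels.index[sub_labels == AMBIGUOUS]
                final.loc[dropped] = pd.NA
            remaining = remaining.difference(assigned.index, sort=False)
    return final.rename("cell_type")
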