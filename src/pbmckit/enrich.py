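"""DEG modules, gene-set overlap, over-representation and preranked GSEA."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from pbmckit._stats import bh_adjust


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a universe, with size bounds."""

    sets: Dict[str, List[str]]
    universe: List[str]
    min_size: int = 10
    max_size: int = 500

    def __post_init__(self) -> None:
        if self.min_size <= 0 or self.max_size <= 0:
            raise ValueError("size bounds must be positive")
        uni = set(self.universe)
        self.sets = {name: sorted(set(g) & uni) for name, g in self.sets.items()}

    def eligible(self) -> Dict[str, List[str]]:
        return {
            n: g for n, g in self.sets.items()
            if self.min_size <= len(g) <= self.max_size
        }


def read_gmt(path, universe: Sequence[str], min_size: int = 10,
             max_size: int = 500) -> GeneSetCollection:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = parts[2:]
    return GeneSetCollection(sets, list(universe), min_size, max_size)


def kmeans_deg_modules(lfc_matrix: pd.DataFrame, k: int = 8,
                       restarts: int = 10, seed: int = 0):
    """k-means of DEGs on their per-cell-type fold-change vectors.

    Missing entries (gene untested in a cell type) are imputed with 0
    before clustering. Returns (labels, module mean profiles, inertia).
    """
    if k <= 1:
        raise ValueError("k must be > 1")
    if k >= len(lfc_matrix):
        raise ValueError("k must be smaller than the number of DEGs")
    M = lfc_matrix.fillna(0.0).to_numpy(dtype=float)
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed).fit(M)
    labels = pd.Series(km.labels_, index=lfc_matrix.index, name="module")
    centers = pd.DataFrame(
        km.cluster_centers_, columns=lfc_matrix.columns,
        index=pd.RangeIndex(k, name="module"),
    )
    return labels, centers, float(km.inertia_)


def overlap_test(set_a: Iterable[str], set_b: Iterable[str],
                 universe: Iterable[str]) -> Tuple[float, float]:
    """One-sided Fisher exact test for enrichment of the overlap.

    Returns (odds ratio, p). Sets are intersected with the universe
    first; the p-value is the hypergeometric upper tail P[X >= overlap].
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    a = set(set_a) & uni
    b = set(set_b) & uni
    n_ab = len(a & b)
    table = [
        [n_ab, len(a) - n_ab],
        [len(b) - n_ab, len(uni) - len(a) - len(b) + n_ab],
    ]
    odds, p = stats.fisher_exact(table, alternative="greater")
    return float(odds), float(p)


def overlap_tests(pairs: Sequence[Tuple[str, Iterable[str], Iterable[str]]],
                  universe: Iterable[str]) -> pd.DataFrame:
    """Fisher tests for many (name, setA, setB) pairs with BH across pairs."""
    uni = list(universe)
    rows = []
    for name, a, b in pairs:
        odds, p = overlap_test(a, b, uni)
        rows.append({
            "pair": name, "odds_ratio": odds, "p": p,
            "overlap": len(set(a) & set(b) & set(uni)),
        })
    df = pd.DataFrame(rows)
    df["q"] = bh_adjust(df["p"])
    return df


def ora(query: Iterable[str], collection: GeneSetCollection) -> pd.DataFrame:
    """Hypergeometric over-representation of the query in each eligible set."""
    uni = set(collection.universe)
    q = set(query) & uni
    if not q:
        raise ValueError("empty query set")
    N, n = len(uni), len(q)
    rows = []
    for name, genes in collection.eligible().items():
        K = len(genes)
        k = len(q & set(genes))
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({
            "set": name, "set_size": K, "overlap": k, "p": p,
            "jaccard": k / len(q | set(genes)),
        })
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = bh_adjust(df["p"])
    return df


def gsea_es(hit_positions: np.ndarray, n_genes: int) -> float:
    """Unweighted (exponent 0) enrichment score from 0-based hit positions.

    Running sum gains 1/|S| at each hit and loses 1/(N - |S|) at each
    miss; ES is the extremum of largest magnitude. A set covering the
    whole list has no misses and the sum climbs monotonically to 1.
    """
    m = len(hit_positions)
    if m == 0:
        return 0.0
    if m == n_genes:
        return 1.0
    pos = np.sort(np.asarray(hit_positions))
    i = np.arange(1, m + 1)
    hit_step = i / m
    miss_before = (pos + 1 - i) / (n_genes - m)
    peaks = hit_step - miss_before  # value just after each hit
    dips = (i - 1) / m - (pos - (i - 1)) / (n_genes - m)  # just before each hit
    # interleave in walk order so ties (within float noise) resolve to the
    # earliest extreme of the running sum
    candidates = np.empty(2 * m)
    candidates[0::2] = dips
    candidates[1::2] = peaks
    mags = np.abs(candidates)
    first = np.flatnonzero(mags >= mags.max() - 1e-9)[0]
    return float(candidates[first])


def _null_es(n_genes: int, set_size: int, n_perm: int,
             rng: np.random.Generator) -> np.ndarray:
    """Vectorized null ES for random hit-position sets of a given size."""
    m = set_size
    if m == n_genes:
        return np.ones(n_perm)
    pos = np.argsort(rng.random((n_perm, n_genes)), axis=1)[:, :m]
    pos.sort(axis=1)
    i = np.arange(1, m + 1)
    peaks = i / m - (pos + 1 - i) / (n_genes - m)
    dips = (i - 1) / m - (pos - (i - 1)) / (n_genes - m)
    cand = np.empty((n_perm, 2 * m))
    cand[:, 0::2] = dips
    cand[:, 1::2] = peaks
    return cand[np.arange(n_perm), np.argmax(np.abs(cand), axis=1)]


def preranked_gsea(ranking: pd.Series, collection: GeneSetCollection,
                   exponent: float = 0.0, n_perm: int = 10000,
                   seed: int = 0) -> pd.DataFrame:
    """Unweighted preranked GSEA with a gene-label permutation null.

    ``ranking`` maps gene -> signed score; genes are ordered by
    descending score. Only exponent 0 (unweighted running sum) is
    implemented. NES = ES / mean |null ES of the matching sign|;
    p-values use the matching-sign tail with a +1 correction; BH q
    across scored sets.
    """
    if exponent != 0.0:
        raise NotImplementedError("only the unweighted (exponent 0) statistic")
    if ranking.index.duplicated().any():
        raise ValueError("duplicate genes in ranking")
    ordered = ranking.sort_values(ascending=False, kind="mergesort")
    gene_pos = {g: i for i, g in enumerate(ordered.index)}
    N = len(ordered)
    rng = np.random.default_rng(seed)

    rows = []
    null_cache: Dict[int, np.ndarray] = {}
    for name, genes in collection.sets.items():
        hits = np.array([gene_pos[g] for g in genes if g in gene_pos])
        if not (collection.min_size <= len(hits) <= collection.max_size):
            continue
        es = gsea_es(hits, N)
        m = len(hits)
        if m not in null_cache:
            null_cache[m] = _null_es(N, m, n_perm, rng)
        null = null_cache[m]
        same_sign = null >= 0 if es >= 0 else null < 0
        null_s = np.abs(null[same_sign])
        if null_s.size == 0:
            p, nes = np.nan, np.nan
        else:
            p = (1.0 + (null_s >= abs(es)).sum()) / (1.0 + null_s.size)
            denom = null_s.mean()
            nes = es / denom if denom > 0 else np.nan
        rows.append({
            "set": name, "size": m, "es": es, "nes": nes, "p": p,
        })
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = bh_adjust(df["p"])
    return df
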