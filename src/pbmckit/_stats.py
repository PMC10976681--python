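"""Small shared statistical helpers."""

from __future__ import annotations

import numpy as np

_Q_FLOOR = 1e-300  # avoid -log10(0) in evidence scores


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j on the sorted p-values; NaN
    entries are passed through and do not count toward m.
    """
    p = np.asarray(pvals, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[ok] = out
    return q


def log2_cpm(counts: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """log2 counts-per-million along rows (samples x genes)."""
    counts = np.asarray(counts, dtype=float)
    depth = counts.sum(axis=1, keepdims=True)
    depth[depth == 0] = 1.0
    return np.log2(counts / depth * 1e6 + pseudocount)


def zscore_columns(mat: np.ndarray, ddof: int = 0):
    """Column-wise z-scores; returns (z, keep_mask) dropping zero-variance columns."""
    mat = np.asarray(mat, dtype=float)
    mu = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=ddof)
    keep = sd > 0
    z = np.zeros_like(mat)
    z[:, keep] = (mat[:, keep] - mu[keep]) / sd[keep]
    return z, keep


def neglog10_q(q) -> np.ndarray:
    return -np.log10(np.maximum(np.asarray(q, dtype=float), _Q_FLOOR))
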