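"""Weighted graph properties of unthresholded PLV networks.

Implements the brain-connectivity-toolbox (Rubinov & Sporns 2010)
weighted formulations:

* clustering coefficient — Onnela geometric-mean variant on weights
  normalized by the off-diagonal maximum;
* characteristic path length and global efficiency — Dijkstra shortest
  paths over connection lengths ``1/w`` (zero weight = no edge);
* local efficiency — BCT weighted variant on each node's neighbor
  subgraph.

The full weighted matrix is consumed without thresholding; the PLV=1
diagonal is removed before every computation. Disconnected pairs are
excluded from CPL (count logged) and contribute 0 to efficiency; PLV
graphs are almost surely complete, so this is a degenerate-input
safeguard only.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra

from .connectivity import PLVMatrix
from .errors import ValidationError

logger = logging.getLogger(__name__)


def _as_weight_matrix(plv) -> np.ndarray:
    w = plv.values.copy() if isinstance(plv, PLVMatrix) else np.asarray(plv, dtype=float).copy()
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValidationError("weight matrix must be square")
    if not np.allclose(w, w.T, atol=1e-10):
        raise ValidationError("weight matrix must be symmetric")
    if (w < 0).any():
        raise ValidationError("weights must be non-negative")
    np.fill_diagonal(w, 0.0)
    return w


def weighted_clustering(plv) -> tuple[np.ndarray, float]:
    """Onnela weighted clustering coefficient per node, and its mean.

    Weights are normalized by the off-diagonal maximum; for node i with
    degree k_i (count of nonzero weights),
    ``C_i = sum_{j,h} (ŵ_ij ŵ_ih ŵ_jh)^{1/3} / (k_i (k_i − 1))``.
    Nodes with k_i < 2 get C_i = 0.
    """
    w = _as_weight_matrix(plv)
    wmax = w.max()
    if wmax == 0:
        return np.zeros(w.shape[0]), 0.0
    wh = np.cbrt(w / wmax)
    k = (w > 0).sum(axis=1)
    cyc3 = np.diagonal(wh @ wh @ wh)
    denom = k * (k - 1)
    cc = np.zeros(w.shape[0])
    ok = denom > 0
    cc[ok] = cyc3[ok] / denom[ok]
    if (~ok).any():
        logger.info("weighted_clustering: %d node(s) with degree < 2 set to 0",
                    int((~ok).sum()))
    return cc, float(cc.mean())


def _distance_matrix(w: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path distances over lengths 1/w."""
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / w, 0.0)
    return dijkstra(lengths, directed=False)


def path_metrics(plv) -> tuple[float, float]:
    """Characteristic path length and global efficiency.

    CPL is the mean shortest-path distance over connected ordered pairs
    i≠j; GE is the mean of 1/d over all ordered pairs i≠j, disconnected
    pairs contributing 0.
    """
    w = _as_weight_matrix(plv)
    n = w.shape[0]
    if n < 2:
        raise ValidationError("path metrics require at least 2 nodes")
    d = _distance_matrix(w)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    n_disconnected = int(off.sum() - finite.sum())
    if n_disconnected:
        logger.info("path_metrics: %d ordered pair(s) disconnected", n_disconnected)
    cpl = float(d[finite].mean()) if finite.any() else float("inf")
    inv = np.zeros_like(d)
    inv[finite] = 1.0 / d[finite]
    ge = float(inv[off].mean())
    return cpl, ge


def local_efficiency(plv) -> tuple[np.ndarray, float]:
    """BCT weighted local efficiency per node, and its mean.

    For node i with neighbors N(i) (nonzero weights) and normalized
    weights ŵ = w / max(w),
    ``E_loc(i) = sum_{j,h ∈ N(i), j≠h} (ŵ_ij ŵ_ih / d_jh(N_i))^{1/3}
    / (k_i (k_i − 1))``, where d_jh(N_i) is the shortest path between j
    and h within the subgraph induced by N(i), computed on normalized
    lengths 1/ŵ. Nodes with k_i < 2 get 0.
    """
    w = _as_weight_matrix(plv)
    n = w.shape[0]
    wmax = w.max()
    if wmax == 0:
        return np.zeros(n), 0.0
    wn = w / wmax
    le = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(wn[i] > 0)
        k = nbrs.size
        if k < 2:
            continue
        sub = wn[np.ix_(nbrs, nbrs)]
        d = _distance_matrix(sub)
        with np.errstate(divide="ignore"):
            inv_d = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
        wi = wn[i, nbrs]
        outer = np.multiply.outer(wi, wi)
        terms = np.cbrt(outer * inv_d)
        np.fill_diagonal(terms, 0.0)
        le[i] = terms.sum() / (k * (k - 1))
    return le, float(le.mean())


@dataclass
class NetworkMetrics:
    """Scalar weighted-network properties of one PLV matrix."""

    cc: float
    cpl: float
    ge: float
    le: float
    per_node_cc: np.ndarray
    per_node_le: np.ndarray
    meta: dict = field(default_factory=dict)

    def to_tidy(self) -> pd.DataFrame:
        rows = [{"metric": m, "value": getattr(self, m)}
                for m in ("cc", "cpl", "ge", "le")]
        out = pd.DataFrame(rows)
        for k, v in self.meta.items():
            out[k] = v
        return out


def network_metrics(plv) -> NetworkMetrics:
    """All four weighted network properties of a PLV matrix."""
    per_cc, cc = weighted_clustering(plv)
    cpl, ge = path_metrics(plv)
    per_le, le = local_efficiency(plv)
    meta = dict(plv.meta) if isinstance(plv, PLVMatrix) else {}
    if isinstance(plv, PLVMatrix):
        meta.setdefault("band", plv.band.name)
    return NetworkMetrics(cc=cc, cpl=cpl, ge=ge, le=le,
                          per_node_cc=per_cc, per_node_le=per_le, meta=meta)
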