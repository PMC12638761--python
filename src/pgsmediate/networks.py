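"""Group-level edge pruning and weighted graph metrics.

Metrics follow the Brain Connectivity Toolbox conventions for weighted
undirected graphs with weights in [0, 1]:

* nodal efficiency ``E_i = (1/(n-1)) * sum_{j != i} 1/d_ij`` where ``d`` is
  the shortest-path length over edge lengths ``1/w`` (Dijkstra), with
  unreachable pairs contributing zero; global efficiency ``E = mean(E_i)``;
* local clustering ``C_i = 2 t_i / (k_i (k_i - 1))`` with the Onnela
  geometric-mean triangle intensity
  ``t_i = 0.5 * sum_{j,h} (w_ij w_ih w_jh)^(1/3)``, ``C_i = 0`` for degree
  below 2; global clustering ``C = mean(C_i)``.

Edge screening is Holm-Bonferroni pruning: every upper-triangle edge's mean
weight across participants is tested one-tailed against zero with the pooled
variance of all upper-triangle weights of all participants, and edges whose
step-down adjusted p exceeds alpha are zeroed in every participant's network.
On real coherence data all weights are strictly positive and nothing is
removed; the screen matters for signed or noise-dominated inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra
from sklearn.base import BaseEstimator, TransformerMixin

from .connectivity import WeightedNetwork

__all__ = [
    "PruneResult",
    "HolmBonferroniPruner",
    "holm_prune",
    "GraphMetricSet",
    "shortest_paths",
    "efficiency",
    "clustering",
    "graph_metrics",
    "remove_outliers",
]


# ---------------------------------------------------------------------------
# pruning


@dataclass
class PruneResult:
    """Outcome of group-level Holm-Bonferroni edge screening."""

    keep_mask: np.ndarray  # symmetric boolean n x n, diagonal False
    edge_mean: np.ndarray  # n x n, mean weight across participants
    statistic: np.ndarray  # n x n z statistic
    p_raw: np.ndarray  # n x n one-tailed p
    p_adjusted: np.ndarray  # n x n Holm-adjusted p

    @property
    def n_removed(self) -> int:
        iu = np.triu_indices_from(self.keep_mask, k=1)
        return int((~self.keep_mask[iu]).sum())


def _stack(cohort_networks) -> np.ndarray:
    mats = [
        net.w if isinstance(net, WeightedNetwork) else np.asarray(net, dtype=float)
        for net in cohort_networks
    ]
    arr = np.stack(mats)
    if arr.ndim != 3 or arr.shape[1] != arr.shape[2]:
        raise ValueError("expected a stack of square matrices")
    return arr


def holm_adjust(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    adj[order] = np.maximum.accumulate((m - np.arange(m)) * p[order])
    return np.minimum(adj, 1.0)


class HolmBonferroniPruner(TransformerMixin, BaseEstimator):
    """Group-level edge screen: keep edges whose mean weight exceeds zero.

    ``fit`` learns a single symmetric keep-mask from the whole cohort;
    ``transform`` zeroes the failing edges in every participant's network.
    The per-edge test is a one-tailed z-test of H0: mean weight <= 0 whose
    standard error uses the pooled variance of *all* upper-triangle weights
    across all participants (a whole-network noise level, not a per-edge
    one), Holm-corrected over the n(n-1)/2 edges.

    Parameters
    ----------
    alpha : familywise error rate of the screen (default 0.01, one-tailed).
    """

    def __init__(self, alpha: float = 0.01):
        self.alpha = alpha

    def fit(self, X, y=None) -> "HolmBonferroniPruner":
        arr = _stack(X)
        n_sub, n = arr.shape[0], arr.shape[1]
        if n_sub < 2:
            raise ValueError("pruning needs at least 2 participants")
        iu = np.triu_indices(n, k=1)
        weights = arr[:, iu[0], iu[1]]  # (n_sub, n_edges)
        pooled_var = weights.var(ddof=1)
        if pooled_var <= 0:
            raise ValueError("zero pooled variance across upper-triangle weights")
        mean = weights.mean(axis=0)
        z = mean / np.sqrt(pooled_var / n_sub)
        p_raw = stats.norm.sf(z)
        p_adj = holm_adjust(p_raw)
        keep = p_adj <= self.alpha

        def square(vec, fill=0.0):
            out = np.full((n, n), fill, dtype=float)
            out[iu] = vec
            out[(iu[1], iu[0])] = vec
            return out

        mask = np.zeros((n, n), dtype=bool)
        mask[iu] = keep
        mask |= mask.T
        self.result_ = PruneResult(
            keep_mask=mask,
            edge_mean=square(mean),
            statistic=square(z),
            p_raw=square(p_raw, fill=1.0),
            p_adjusted=square(p_adj, fill=1.0),
        )
        self.keep_mask_ = mask
        self.n_features_in_ = n
        return self

    def transform(self, X):
        mask = self.keep_mask_
        out = []
        for net in X:
            if isinstance(net, WeightedNetwork):
                w = np.where(mask, net.w, 0.0)
                out.append(
                    WeightedNetwork(
                        w=w, roi_labels=net.roi_labels, band=net.band, session=net.session
                    )
                )
            else:
                out.append(np.where(mask, np.asarray(net, dtype=float), 0.0))
        return out


def holm_prune(cohort_networks, alpha: float = 0.01) -> PruneResult:
    """Functional form of :class:`HolmBonferroniPruner` (fit only)."""
    return HolmBonferroniPruner(alpha=alpha).fit(cohort_networks).result_


# ---------------------------------------------------------------------------
# graph metrics


@dataclass
class GraphMetricSet:
    """Global and nodal efficiency/clustering for one network."""

    E: float
    E_i: np.ndarray
    C: float
    C_i: np.ndarray
    k_i: np.ndarray
    t_i_w: np.ndarray


def _as_matrix(network) -> np.ndarray:
    w = network.w if isinstance(network, WeightedNetwork) else np.asarray(network, dtype=float)
    w = np.array(w, dtype=float, copy=True)
    np.fill_diagonal(w, 0.0)
    return w


def shortest_paths(network) -> np.ndarray:
    """All-pairs shortest-path lengths over edge lengths 1/w (Dijkstra).

    Absent edges (w = 0) are no direct connection; unreachable pairs get
    ``inf``.
    """
    w = _as_matrix(network)
    if np.any(w < 0):
        raise ValueError("negative weight")
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / w, 0.0)
    return _csgraph_dijkstra(lengths, directed=False, unweighted=False)


def efficiency(network) -> tuple[float, np.ndarray]:
    """Global and nodal efficiency from inverse shortest-path lengths."""
    d = shortest_paths(network)
    n = d.shape[0]
    if n < 2:
        raise ValueError("efficiency needs at least 2 nodes")
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    np.fill_diagonal(inv, 0.0)
    e_i = inv.sum(axis=1) / (n - 1)
    return float(e_i.mean()), e_i


def _clustering_full(network, max_normalize: bool = False):
    w = _as_matrix(network)
    if max_normalize:
        top = w.max()
        if top > 0:
            w = w / top
    elif np.any(w > 1.0 + 1e-12):
        raise ValueError("weights above 1; pass max_normalize=True to rescale")
    k = (w > 0).sum(axis=1)
    cube = np.cbrt(w)
    t = np.diag(cube @ cube @ cube) / 2.0
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c_i = np.where(denom > 0, 2.0 * t / denom, 0.0)
    return float(c_i.mean()), c_i, k, t


def clustering(network, max_normalize: bool = False) -> tuple[float, np.ndarray]:
    """Weighted local and global clustering (Onnela triangle intensity)."""
    c, c_i, _, _ = _clustering_full(network, max_normalize=max_normalize)
    return c, c_i


def graph_metrics(network) -> GraphMetricSet:
    """Full efficiency/clustering profile of one weighted network."""
    e, e_i = efficiency(network)
    c, c_i, k, t = _clustering_full(network)
    return GraphMetricSet(E=e, E_i=e_i, C=c, C_i=c_i, k_i=k, t_i_w=t)


# ---------------------------------------------------------------------------
# participant-level outlier screen


def remove_outliers(
    values: pd.DataFrame, n_iqr: float = 3.0
) -> tuple[pd.Index, pd.Index]:
    """Drop participants deviating more than ``n_iqr`` IQRs from the median.

    ``values`` holds one row per participant and one column per screened
    variable (per-band global efficiency and clustering, and g).  A
    participant is an outlier if *any* column value lies farther than
    ``n_iqr`` interquartile ranges from that column's median.  Returns
    (kept index, removed index).
    """
    if values.empty:
        raise ValueError("empty input")
    med = values.median(axis=0)
    iqr = values.quantile(0.75, axis=0) - values.quantile(0.25, axis=0)
    # zero-IQR columns (constant) can never flag anyone
    limit = n_iqr * iqr
    flagged = ((values - med).abs() > limit).any(axis=1)
    return values.index[~flagged], values.index[flagged]
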