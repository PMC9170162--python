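"""Small-world and degree-distribution statistics of a functional network.

A network is summarized by its mean shortest path length L (over connected
node pairs) and global clustering coefficient C_raw (transitivity,
3 × triangles / connected triplets). Both are referenced against randomized
networks in which the active node set is re-drawn uniformly among all
analyzed cells and the full correlation pipeline is rerun: λ = L / L_R,
C = C_raw / C_R, and the small-world coefficient σ = C / λ. σ > 1 indicates
small-world organization. The degree distribution P(k) is fitted on a
log-log scale by ordinary least squares; its slope γ is negative for
scale-free graphs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csgraph

from .network import build_network, pairwise_coupling


@dataclass(frozen=True)
class NetworkMetrics:
    """Bundle of raw and reference-normalized network statistics."""

    L: float
    C_raw: float
    L_R: float
    C_R: float
    lam: float
    C: float
    sigma: float
    degree_hist: pd.Series
    gamma: float
    n_nodes: int
    n_edges: int
    n_reference_iter: int = 0
    reference_L: np.ndarray = field(default_factory=lambda: np.array([]))
    reference_C: np.ndarray = field(default_factory=lambda: np.array([]))

    def to_dict(self) -> dict:
        return {
            "L": self.L, "C_raw": self.C_raw, "L_R": self.L_R,
            "C_R": self.C_R, "lambda": self.lam, "C": self.C,
            "sigma": self.sigma, "gamma": self.gamma,
            "n_nodes": self.n_nodes, "n_edges": self.n_edges,
            "n_reference_iter": self.n_reference_iter,
            "degree_hist": {int(k): int(v)
                            for k, v in self.degree_hist.items()},
        }


def mean_shortest_path(graph: nx.Graph) -> float:
    """Mean shortest path length over all connected, distinct node pairs.

    Disconnected pairs are excluded from the mean. Returns NaN for a graph
    with no edges (undefined); raises on an empty graph.
    """
    n = graph.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")
    if graph.number_of_edges() == 0:
        return float("nan")
    A = nx.to_scipy_sparse_array(graph, format="csr")
    D = csgraph.shortest_path(A, method="D", unweighted=True, directed=False)
    mask = np.isfinite(D) & ~np.eye(n, dtype=bool)
    return float(D[mask].mean())


def global_clustering(graph: nx.Graph) -> float:
    """Transitivity: 3 × triangles / connected triplets (0 if no triplets)."""
    if graph.number_of_nodes() < 3:
        return 0.0
    return float(nx.transitivity(graph))


def degree_distribution(graph: nx.Graph) -> pd.Series:
    """Counts of nodes per degree k, indexed by k (ascending)."""
    degs = [d for _, d in graph.degree()]
    if not degs:
        return pd.Series(dtype=int)
    vals, counts = np.unique(degs, return_counts=True)
    return pd.Series(counts, index=vals, name="count")


def fit_power_law_slope(degree_hist: pd.Series, min_degree: int = 1) -> float:
    """OLS slope of log10 P(k) on log10 k over observed degrees >= min_degree.

    The fit uses the unbinned probability mass at each observed degree.
    Returns NaN when fewer than two degrees support the fit.
    """
    h = degree_hist[degree_hist.index >= min_degree]
    h = h[h > 0]
    if len(h) < 2:
        return float("nan")
    total = degree_hist.sum()
    logk = np.log10(h.index.to_numpy(dtype=float))
    logp = np.log10(h.to_numpy(dtype=float) / total)
    slope = np.polyfit(logk, logp, 1)[0]
    return float(slope)


def small_world(L: float, C_raw: float, L_R: float, C_R: float):
    """λ = L/L_R, C = C_raw/C_R, σ = C/λ (exact arithmetic)."""
    if L_R <= 0:
        raise ValueError("L_R must be positive")
    if C_R == 0:
        warnings.warn("degenerate reference: C_R = 0, sigma undefined",
                      stacklevel=2)
        return L / L_R, float("nan"), float("nan")
    lam = L / L_R
    C = C_raw / C_R
    return lam, C, C / lam


def random_reference(X, pool_size: int, n_active: int, cutoff: float,
                     n_iter: int = 100, seed=None, fs: float = 10.0,
                     window_len: float = 60.0, n_windows: int = 2,
                     max_lag: float = 2.5, lag_step: float = 0.1):
    """Reference L_R and C_R from randomized active-node selections.

    Per iteration ``n_active`` cells are drawn uniformly without replacement
    from the ``pool_size`` analyzed (non-boundary) cells whose binary trains
    are the rows of ``X``; the correlation network among them is rebuilt at
    the observed cutoff and its L and C_raw recorded. Returns the grand
    means (NaN-skipping for L, since an edgeless draw leaves L undefined)
    plus the per-iteration arrays.
    """
    if n_active > pool_size:
        raise ValueError("n_active exceeds the analyzed pool")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    Ls = np.empty(n_iter)
    Cs = np.empty(n_iter)
    for it in range(n_iter):
        ids = rng.choice(pool_size, size=n_active, replace=False)
        coef, _, _ = pairwise_coupling(
            X[np.sort(ids)], fs=fs, window_len=window_len,
            n_windows=n_windows, max_lag=max_lag, lag_step=lag_step,
        )
        net = build_network(coef, cutoff, np.arange(n_active))
        Ls[it] = mean_shortest_path(net.graph)
        Cs[it] = global_clustering(net.graph)
    if np.isnan(Ls).all():
        warnings.warn("all reference networks were edgeless; L_R undefined",
                      stacklevel=2)
        L_R = float("nan")
    else:
        L_R = float(np.nanmean(Ls))
    return L_R, float(np.mean(Cs)), Ls, Cs


def summarize_network(graph: nx.Graph, L_R: float, C_R: float,
                      n_reference_iter: int = 0,
                      reference_L=None, reference_C=None) -> NetworkMetrics:
    """Assemble NetworkMetrics for an observed graph given reference means."""
    L = mean_shortest_path(graph)
    C_raw = global_clustering(graph)
    lam, C, sigma = small_world(L, C_raw, L_R, C_R)
    hist = degree_distribution(graph)
    gamma = fit_power_law_slope(hist)
    return NetworkMetrics(
        L=L, C_raw=C_raw, L_R=L_R, C_R=C_R, lam=lam, C=C, sigma=sigma,
        degree_hist=hist, gamma=gamma, n_nodes=graph.number_of_nodes(),
        n_edges=graph.number_of_edges(),
        n_reference_iter=n_reference_iter,
        reference_L=np.asarray(reference_L if reference_L is not None else []),
        reference_C=np.asarray(reference_C if reference_C is not None else []),
    )
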