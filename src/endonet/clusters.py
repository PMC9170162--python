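"""Spatial clustering of agonist-sensitive cells on the structural lattice.

Active (responding) cells are projected onto the structural adjacency
graph: components are connected sets of active cells including singletons,
clusters are components of size >= 2, and the active degree is the mean
number of active neighbours per active cell. Observed statistics are tested
against a permutation null in which an equal-sized active set is re-drawn
uniformly among non-boundary cells (default 1,000 permutations), with
add-one-corrected two-sided empirical p-values. A separate helper reports
the overlap between the populations recruited by two different agonists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse import csgraph

from .tissue import TissueMap


@dataclass(frozen=True)
class ClusterSummary:
    """Cluster statistics for one active set (optionally with null fields)."""

    n_components: int
    n_clusters: int
    clusters_per_100: float
    cells_per_cluster: float
    active_degree: float
    n_total_cells: int
    n_active: int
    table: pd.DataFrame | None = None   # statistic, observed, null_mean, null_sd, p
    n_perm: int = 0


def active_subgraph(tissue: TissueMap, active) -> nx.Graph:
    """Structural subgraph induced by the active cells.

    Nodes are the active cells; edges are structural-adjacency pairs with
    both ends active. Active cells must be non-boundary cells of the tissue.
    """
    active = np.asarray(sorted(int(a) for a in active))
    if active.size and (active.min() < 0 or active.max() >= tissue.n_cells):
        raise ValueError("active cell id not present in the tissue")
    if tissue.is_boundary[active].any():
        raise ValueError("active set includes boundary cells")
    g = nx.Graph()
    g.add_nodes_from(int(a) for a in active)
    aset = set(int(a) for a in active)
    for a in active:
        for b in tissue.neighbors[a]:
            if b in aset and a < b:
                g.add_edge(int(a), int(b))
    return g


def _stats_from_sizes(sizes: np.ndarray, n_edges: int, n_active: int,
                      n_total: int):
    n_components = sizes.size
    big = sizes[sizes >= 2]
    n_clusters = big.size
    cells_per_cluster = float(big.mean()) if n_clusters else float("nan")
    active_degree = 2.0 * n_edges / n_active if n_active else 0.0
    return (
        float(n_components),
        float(n_clusters),
        100.0 * n_clusters / n_total,
        cells_per_cluster,
        active_degree,
    )


_STAT_NAMES = ("n_components", "n_clusters", "clusters_per_100",
               "cells_per_cluster", "active_degree")


def cluster_stats(graph: nx.Graph, n_total_cells: int) -> ClusterSummary:
    """Component/cluster statistics of an active subgraph."""
    sizes = np.array([len(c) for c in nx.connected_components(graph)])
    vals = _stats_from_sizes(sizes, graph.number_of_edges(),
                             graph.number_of_nodes(), n_total_cells)
    return ClusterSummary(
        n_components=int(vals[0]), n_clusters=int(vals[1]),
        clusters_per_100=vals[2], cells_per_cluster=vals[3],
        active_degree=vals[4], n_total_cells=n_total_cells,
        n_active=graph.number_of_nodes(),
    )


def _edge_arrays(tissue: TissueMap):
    u, v = [], []
    for i, nbs in enumerate(tissue.neighbors):
        for j in nbs:
            if i < j:
                u.append(i)
                v.append(j)
    return np.asarray(u, dtype=np.int64), np.asarray(v, dtype=np.int64)


def _stats_for_mask(mask, u, v, n_total):
    act = np.flatnonzero(mask)
    m = act.size
    idx = np.full(mask.size, -1, dtype=np.int64)
    idx[act] = np.arange(m)
    keep = mask[u] & mask[v]
    eu, ev = idx[u[keep]], idx[v[keep]]
    A = sparse.csr_matrix(
        (np.ones(eu.size), (eu, ev)), shape=(m, m)
    )
    _, labels = csgraph.connected_components(A, directed=False)
    sizes = np.bincount(labels)
    return _stats_from_sizes(sizes, eu.size, m, n_total)


def permutation_null(tissue: TissueMap, active, n_perm: int = 1000,
                     seed=None) -> ClusterSummary:
    """Observed cluster statistics with a label-permutation null.

    Per permutation an active set of equal size is drawn uniformly without
    replacement among non-boundary cells. Two-sided empirical p-values use
    the add-one rule: p = 2 * min over tails of
    (1 + #{null >=/<= observed}) / (n_perm + 1), capped at 1, so p is never
    zero. NaN-valued statistics (e.g. cells_per_cluster with no clusters)
    yield NaN p-values.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    active = np.asarray(sorted(int(a) for a in active))
    n_total = tissue.n_cells
    pool = tissue.interior_ids
    if active.size > pool.size:
        raise ValueError("more active cells than non-boundary cells")
    u, v = _edge_arrays(tissue)

    mask = np.zeros(n_total, dtype=bool)
    mask[active] = True
    if tissue.is_boundary[active].any():
        raise ValueError("active set includes boundary cells")
    obs = np.array(_stats_for_mask(mask, u, v, n_total))

    null = np.empty((n_perm, len(_STAT_NAMES)))
    for it in range(n_perm):
        draw = rng.choice(pool, size=active.size, replace=False)
        m = np.zeros(n_total, dtype=bool)
        m[draw] = True
        null[it] = _stats_for_mask(m, u, v, n_total)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        null_mean = np.nanmean(null, axis=0)
        null_sd = np.nanstd(null, axis=0)
    pvals = np.empty(len(_STAT_NAMES))
    for k, o in enumerate(obs):
        col = null[:, k]
        ok = np.isfinite(col)
        if not np.isfinite(o) or not ok.any():
            pvals[k] = float("nan")
            continue
        hi = (1 + np.sum(col[ok] >= o)) / (ok.sum() + 1)
        lo = (1 + np.sum(col[ok] <= o)) / (ok.sum() + 1)
        pvals[k] = min(1.0, 2.0 * min(hi, lo))

    table = pd.DataFrame({
        "statistic": _STAT_NAMES,
        "observed": obs,
        "null_mean": null_mean,
        "null_sd": null_sd,
        "p": pvals,
    })
    return ClusterSummary(
        n_components=int(obs[0]), n_clusters=int(obs[1]),
        clusters_per_100=obs[2], cells_per_cluster=obs[3],
        active_degree=obs[4], n_total_cells=n_total, n_active=active.size,
        table=table, n_perm=n_perm,
    )


def agonist_overlap(active_a, active_b, n_total: int,
                    name_a: str = "A", name_b: str = "B") -> dict:
    """Percent of cells recruited by each agonist and their overlap.

    Returns the percentage of all cells active for each agonist and the
    conditional overlaps |A∩B|/|A| and |A∩B|/|B| as percentages. Empty sets
    give 0% overlap with a warning.
    """
    a, b = set(map(int, active_a)), set(map(int, active_b))
    inter = len(a & b)
    out = {
        f"pct_active_{name_a}": 100.0 * len(a) / n_total,
        f"pct_active_{name_b}": 100.0 * len(b) / n_total,
    }
    for name, s in ((name_a, a), (name_b, b)):
        if not s:
            warnings.warn(f"empty active set for {name}; overlap set to 0",
                          stacklevel=2)
            out[f"pct_of_{name}_also_other"] = 0.0
        else:
            out[f"pct_of_{name}_also_other"] = 100.0 * inter / len(s)
    return out
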