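"""Global and nodal graph measures of integration and segregation.

Weighted measures follow the conventions standard for streamline-count
connectomes: weights are rescaled to (0, 1] by division by the maximum
weight; shortest-path lengths use the reciprocal of the rescaled weight;
the weighted clustering coefficient is the Onnela geometric-mean form
(as implemented by networkx). Efficiency is computed from all-pairs
shortest paths via scipy's sparse graph routines, with disconnected
pairs contributing zero.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .core import Connectome
from .nulls import rewire_binary

__all__ = [
    "degree_strength",
    "clustering",
    "efficiency",
    "local_efficiency",
    "characteristic_path_length",
    "small_world_index",
    "global_metrics",
]


def degree_strength(C: Connectome) -> tuple[np.ndarray, np.ndarray]:
    """Binary degree and weighted strength per node."""
    return C.degrees(), C.strengths()


def _to_graph(W: np.ndarray, weighted: bool) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(range(W.shape[0]))
    i, j = np.nonzero(np.triu(W, k=1))
    if weighted:
        G.add_weighted_edges_from(zip(i.tolist(), j.tolist(), W[i, j].tolist()))
    else:
        G.add_edges_from(zip(i.tolist(), j.tolist()))
    return G


def clustering(C: Connectome, mode: str = "binary") -> tuple[np.ndarray, float]:
    """Per-node clustering coefficients and their global mean.

    ``binary``: triangles over possible triangles around each node.
    ``weighted``: geometric mean of max-normalized triangle weights
    (Onnela form). Nodes with degree < 2 contribute 0 to the global mean.
    """
    if mode not in ("binary", "weighted"):
        raise ValueError("mode must be 'binary' or 'weighted'")
    G = _to_graph(C.W, weighted=(mode == "weighted"))
    cc = nx.clustering(G, weight="weight" if mode == "weighted" else None)
    nodal = np.array([cc[i] for i in range(C.n_nodes)])
    return nodal, float(nodal.mean()) if C.n_nodes else (nodal, 0.0)


def _length_matrix(W: np.ndarray, weighted: bool) -> csr_matrix:
    # weight-to-length: l = 1 / (w / max(w)); binary graphs use unit lengths
    A = (W > 0)
    if not weighted or W.max() == 0:
        L = A.astype(float)
    else:
        L = np.zeros_like(W)
        L[A] = W.max() / W[A]
    return csr_matrix(L)


def efficiency(C: Connectome, weighted: bool = False) -> float:
    """Global efficiency: mean over ordered node pairs of 1 / d(i, j).

    Disconnected pairs contribute 0; a graph with N < 2 has efficiency 0.
    """
    n = C.n_nodes
    if n < 2:
        return 0.0
    D = shortest_path(_length_matrix(C.W, weighted), method="D", directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def local_efficiency(C: Connectome, weighted: bool = False) -> np.ndarray:
    """Per-node local efficiency: global efficiency of each node's
    neighbor-induced subgraph. Nodes with fewer than 2 neighbors score 0."""
    out = np.zeros(C.n_nodes)
    A = C.W > 0
    for v in range(C.n_nodes):
        nbrs = np.flatnonzero(A[v])
        if len(nbrs) < 2:
            continue
        sub = Connectome(C.subject_id, C.group, C.W[np.ix_(nbrs, nbrs)], binary=C.binary)
        out[v] = efficiency(sub, weighted=weighted)
    return out


def characteristic_path_length(C: Connectome, weighted: bool = False) -> float:
    """Mean shortest-path length over pairs of the largest connected component."""
    A = C.W > 0
    n = C.n_nodes
    from scipy.sparse.csgraph import connected_components

    ncomp, labels = connected_components(csr_matrix(A), directed=False)
    sizes = np.bincount(labels)
    comp = np.flatnonzero(labels == np.argmax(sizes))
    if len(comp) < 2:
        return np.inf
    Wc = C.W[np.ix_(comp, comp)]
    D = shortest_path(_length_matrix(Wc, weighted), method="D", directed=False)
    m = len(comp)
    return float(D[~np.eye(m, dtype=bool)].mean())


def small_world_index(C: Connectome, n_nulls: int = 100, seed: int = 0,
                      n_swaps_per_edge: int = 10) -> float:
    """Small-world index sigma = (C / C_rand) / (L / L_rand).

    Clustering and characteristic path length are measured on the largest
    connected component of the binary network; the reference values are
    averages over ``n_nulls`` degree-preserving rewirings. sigma > 1
    indicates small-world topology.
    """
    A = C.binarized()
    c_emp = clustering(A, "binary")[1]
    l_emp = characteristic_path_length(A)
    rng_seeds = np.random.SeedSequence(seed).spawn(n_nulls)
    c_rand, l_rand = [], []
    for ss in rng_seeds:
        null = rewire_binary(A, n_swaps_per_edge=n_swaps_per_edge, seed=ss)
        c_rand.append(clustering(null, "binary")[1])
        l_rand.append(characteristic_path_length(null))
    c_bar, l_bar = float(np.mean(c_rand)), float(np.mean(l_rand))
    if c_bar == 0 or l_bar == 0 or not np.isfinite(l_bar) or l_emp == 0:
        raise ValueError("graph too sparse or disconnected for small-world index")
    return (c_emp / c_bar) / (l_emp / l_bar)


def global_metrics(C: Connectome, n_nulls_sw: int = 100, seed: int = 0,
                   weighted: bool = True) -> dict[str, float]:
    """Bundle of whole-network measures used for group comparison."""
    return {
        "global_clustering": clustering(C, "weighted" if weighted else "binary")[1],
        "global_efficiency": efficiency(C, weighted=weighted),
        "char_path_length": characteristic_path_length(C, weighted=weighted),
        "small_world_index": small_world_index(C, n_nulls=n_nulls_sw, seed=seed),
    }
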