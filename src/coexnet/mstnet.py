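"""Graph branch: correlation network, extreme-tail sparsification, Prim MST
backbone, community detection, centralities and control-vs-case differential
centrality.

The backbone is a minimum spanning tree over signed correlation weights, so
the strongest negative (repressor-like) correlations are preferred edges and
the tree isolates mutually exclusive regulatory states; an absolute-weight
mode (key 1 - |w|, strongest magnitude preferred) is also provided.
Communities and centralities are computed on the unweighted tree.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "correlation_network",
    "sparsify_network",
    "mst_prim",
    "detect_communities",
    "compute_centralities",
    "differential_centrality",
    "SpanningTree",
    "CommunityPartition",
]

MEASURES = ("degree", "betweenness", "closeness", "eigenvector")


def correlation_network(X: pd.DataFrame, method: str = "spearman") -> pd.DataFrame:
    """Dense symmetric gene-gene correlation matrix (genes x genes).

    Spearman is Pearson on average ranks; rejects zero-variance genes.
    """
    if X.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    v = X.var(axis=1, ddof=1)
    if (v == 0).any():
        bad = list(X.index[v == 0])
        raise ValueError(f"zero-variance genes (run variance_filter): {bad[:10]}")
    M = X.to_numpy()
    if method == "spearman":
        M = stats.rankdata(M, axis=1)
    elif method != "pearson":
        raise ValueError("method must be 'spearman' or 'pearson'")
    C = np.corrcoef(M)
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    return pd.DataFrame(C, index=X.index, columns=X.index)


def sparsify_network(C: pd.DataFrame, f: float = 0.8) -> nx.Graph:
    """Keep only the extreme correlation tails, then the largest component.

    An edge (i, j) survives iff w >= f * max positive off-diagonal weight or
    w <= f * min negative off-diagonal weight (closed comparisons). Isolated
    nodes and all but the largest connected component are dropped (component
    size ties broken by smallest lexicographic member).
    """
    if not 0.0 < f < 1.0:
        raise ValueError("tail fraction f must be in (0, 1)")
    W = C.to_numpy().copy()
    np.fill_diagonal(W, np.nan)
    pos = W[W > 0]
    neg = W[W < 0]
    if pos.size == 0 and neg.size == 0:
        raise ValueError("no nonzero off-diagonal weights to threshold")
    hi = f * pos.max() if pos.size else np.inf
    lo = f * neg.min() if neg.size else -np.inf
    iu, ju = np.triu_indices(W.shape[0], k=1)
    w = W[iu, ju]
    keep = (w >= hi) | (w <= lo)
    g = nx.Graph()
    genes = list(C.index)
    for i, j, wij in zip(iu[keep], ju[keep], w[keep]):
        g.add_edge(genes[i], genes[j], weight=float(wij))
    if g.number_of_nodes() == 0:
        raise ValueError("sparsification removed every edge")
    comp = max(nx.connected_components(g), key=lambda c: (len(c), min(c)))
    return g.subgraph(comp).copy()


@dataclass
class SpanningTree:
    """MST backbone with its signed edge weights."""

    graph: nx.Graph
    weight_mode: str
    total_weight: float

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges


def _edge_key(w: float, weight_mode: str) -> float:
    return w if weight_mode == "signed" else 1.0 - abs(w)


def mst_prim(G: nx.Graph | pd.DataFrame, weight_mode: str = "signed") -> SpanningTree:
    """Prim's algorithm from the lexicographically smallest node.

    signed mode minimizes the raw signed weight (most-negative edges
    preferred); absolute mode minimizes 1 - |w| (strongest magnitude
    preferred). Ties broken by (key, endpoint ids), so output is
    deterministic.
    """
    if weight_mode not in ("signed", "absolute"):
        raise ValueError("weight_mode must be 'signed' or 'absolute'")
    if isinstance(G, pd.DataFrame):
        g = nx.Graph()
        genes = list(G.index)
        W = G.to_numpy()
        iu, ju = np.triu_indices(len(genes), k=1)
        for i, j in zip(iu, ju):
            g.add_edge(genes[i], genes[j], weight=float(W[i, j]))
        G = g
    if G.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if not nx.is_connected(G):
        raise ValueError("disconnected input; sparsify_network keeps the "
                         "largest component first")
    start = min(G.nodes, key=str)
    tree = nx.Graph()
    tree.add_node(start)
    visited = {start}
    heap: list[tuple[float, str, str, object, object]] = []

    def push_edges(u):
        for v in G.neighbors(u):
            if v not in visited:
                w = G[u][v]["weight"]
                heapq.heappush(
                    heap, (_edge_key(w, weight_mode), str(v), str(u), v, u)
                )

    push_edges(start)
    total = 0.0
    while len(visited) < G.number_of_nodes():
        key, _, _, v, u = heapq.heappop(heap)
        if v in visited:
            continue
        w = G[u][v]["weight"]
        tree.add_edge(u, v, weight=float(w))
        total += float(w)
        visited.add(v)
        push_edges(v)
    return SpanningTree(graph=tree, weight_mode=weight_mode, total_weight=total)


@dataclass
class CommunityPartition:
    labels: dict[str, int]        # node -> community id, contiguous from 1
    method: str
    modularity: float

    def members(self, cid: int) -> list[str]:
        return sorted(n for n, c in self.labels.items() if c == cid)

    @property
    def n_communities(self) -> int:
        return max(self.labels.values()) if self.labels else 0


def _contiguous(parts: list[set]) -> dict[str, int]:
    ordered = sorted(parts, key=lambda c: (-len(c), min(map(str, c))))
    return {n: i + 1 for i, c in enumerate(ordered) for n in c}


def detect_communities(
    T: SpanningTree | nx.Graph, method: str = "louvain", seed: int = 0
) -> CommunityPartition:
    """Community detection on the unweighted view of the graph.

    ``edge_betweenness`` is Girvan-Newman, returning the partition along the
    removal sequence that maximizes Newman-Girvan modularity; ``louvain`` is
    two-phase modularity optimization at resolution 1 with the node sweep
    order set by ``seed``.
    """
    g = T.graph if isinstance(T, SpanningTree) else T
    if g.number_of_nodes() < 2:
        raise ValueError("need at least 2 nodes")
    u = nx.Graph()
    u.add_nodes_from(g.nodes)
    u.add_edges_from(g.edges)  # unweighted view
    if method == "louvain":
        parts = nx.community.louvain_communities(u, weight=None, seed=seed)
        parts = [set(c) for c in parts]
    elif method == "edge_betweenness":
        best = [set(u.nodes)]
        best_q = nx.community.modularity(u, best) if u.number_of_edges() else 0.0
        for parts_i in nx.community.girvan_newman(u):
            q = nx.community.modularity(u, parts_i)
            if q > best_q:
                best_q = q
                best = [set(c) for c in parts_i]
        parts = best
    else:
        raise ValueError("method must be 'edge_betweenness' or 'louvain'")
    labels = _contiguous(parts)
    q = nx.community.modularity(u, [set(c) for c in _group(labels).values()])
    return CommunityPartition(labels=labels, method=method, modularity=q)


def _group(labels: dict[str, int]) -> dict[int, set]:
    out: dict[int, set] = {}
    for n, c in labels.items():
        out.setdefault(c, set()).add(n)
    return out


def compute_centralities(
    T: SpanningTree | nx.Graph, partition: CommunityPartition | None = None
) -> pd.DataFrame:
    """Degree, betweenness, closeness, eigenvector centralities on the
    unweighted graph, each raw and min-max scaled to [0, 1].

    Betweenness is the unordered-pair count of shortest paths through each
    node; closeness is (n - 1) / sum of distances; eigenvector is the
    principal adjacency eigenvector scaled to max entry 1. Adds a
    ``community`` and per-measure ``representative`` flag when a partition
    is given (the community's max-raw-score gene per measure).
    """
    g = T.graph if isinstance(T, SpanningTree) else T
    if not nx.is_connected(g):
        raise ValueError("centralities require a connected graph")
    u = nx.Graph()
    u.add_nodes_from(g.nodes)
    u.add_edges_from(g.edges)
    deg = dict(u.degree())
    btw = nx.betweenness_centrality(u, normalized=False)
    clo = nx.closeness_centrality(u)
    try:
        eig = nx.eigenvector_centrality(u, max_iter=10_000, tol=1e-10)
    except nx.PowerIterationFailedConvergence:
        eig = nx.eigenvector_centrality_numpy(u)
    mx = max(eig.values())
    eig = {n: v / mx for n, v in eig.items()}

    df = pd.DataFrame(
        {"degree": deg, "betweenness": btw, "closeness": clo, "eigenvector": eig}
    ).astype(float)
    df = df.sort_index()
    for m in MEASURES:
        col = df[m]
        rng = col.max() - col.min()
        df[f"{m}_scaled"] = 0.0 if rng == 0 else (col - col.min()) / rng
    if partition is not None:
        df["community"] = [partition.labels[n] for n in df.index]
        for m in MEASURES:
            # community representative = argmax raw score, ties -> smaller id
            reps = set()
            for cid, sub in df.groupby("community"):
                best = sub[m].max()
                reps.add(min(sub.index[sub[m] == best]))
            df[f"{m}_representative"] = [n in reps for n in df.index]
    return df


def differential_centrality(
    ctrl: pd.DataFrame,
    case: pd.DataFrame,
    hi: float = 0.5,
    lo: float = 0.3,
) -> pd.DataFrame:
    """Per-gene scaled-centrality difference between case and control trees.

    Genes absent from one tree score 0 on all scaled measures there. The
    composite is the mean over the four measures; classes:

    * pathology_specific: case composite >= hi and control composite <= lo
    * control_specific:   mirrored
    * shared_central:     both composites >= hi
    * peripheral:         everything else
    """
    if ctrl.empty or case.empty:
        raise ValueError("empty centrality tables")
    genes = sorted(set(ctrl.index) | set(case.index))
    cols = [f"{m}_scaled" for m in MEASURES]
    c0 = ctrl.reindex(genes)[cols].fillna(0.0)
    c1 = case.reindex(genes)[cols].fillna(0.0)
    comp0 = c0.mean(axis=1)
    comp1 = c1.mean(axis=1)
    delta = c1.to_numpy() - c0.to_numpy()
    out = pd.DataFrame(
        delta, index=genes, columns=[f"delta_{m}" for m in MEASURES]
    )
    out["composite_control"] = comp0
    out["composite_case"] = comp1
    out["composite_delta"] = out[[f"delta_{m}" for m in MEASURES]].mean(axis=1)

    def classify(c_case: float, c_ctrl: float) -> str:
        if c_case >= hi and c_ctrl >= hi:
            return "shared_central"
        if c_case >= hi and c_ctrl <= lo:
            return "pathology_specific"
        if c_ctrl >= hi and c_case <= lo:
            return "control_specific"
        return "peripheral"

    out["class"] = [
        classify(a, b) for a, b in zip(out["composite_case"], out["composite_control"])
    ]
    return out.sort_values("composite_delta", ascending=False)
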