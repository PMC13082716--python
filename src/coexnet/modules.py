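"""Signed weighted co-expression modules: soft-threshold scan with
scale-free fit, topological overlap, tree-cut module detection, eigengene
merging, module membership / gene significance, hub selection and classical
MDS on TOM dissimilarity.

The signed adjacency is a_ij = ((1 + cor_ij) / 2) ** beta so anti-correlated
genes get near-zero adjacency instead of being conflated with co-expressed
ones. The topological overlap of two genes augments their direct adjacency
with the adjacency they share through common neighbours, which suppresses
spurious one-off correlations; 1 - TOM is the clustering dissimilarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "soft_threshold_scan",
    "tom_matrix",
    "detect_modules",
    "eigengene_merge",
    "mm_gs",
    "select_hubs",
    "mds_embed",
    "SoftThresholdScan",
    "ModuleSet",
]


def signed_adjacency(cor: np.ndarray, beta: int, signed: bool = True) -> np.ndarray:
    a = ((1.0 + cor) / 2.0) ** beta if signed else np.abs(cor) ** beta
    a = np.asarray(a, dtype=float)
    np.fill_diagonal(a, 0.0)  # self-adjacency excluded from connectivity
    return a


@dataclass
class SoftThresholdScan:
    table: pd.DataFrame      # beta, r2_signed, slope, mean_k
    beta: int                # chosen power
    status: str              # "ok" or "fallback-max-r2"


def _scale_free_fit(k: np.ndarray, n_bins: int) -> tuple[float, float]:
    """Signed R^2 and slope of log10(frequency) vs log10(mean k) over
    equal-width connectivity bins (non-empty bins only)."""
    if np.ptp(k) == 0:
        raise ValueError("degenerate connectivity (all equal); fit undefined")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() == 0:
            continue
        mean_k = k[sel].mean()
        freq = sel.mean()
        if mean_k > 0 and freq > 0:
            xs.append(np.log10(mean_k))
            ys.append(np.log10(freq))
    if len(xs) < 3:
        raise ValueError("too few occupied connectivity bins for a fit")
    res = stats.linregress(xs, ys)
    r2 = res.rvalue**2
    return float(r2 * -np.sign(res.slope)), float(res.slope)


def soft_threshold_scan(
    X: pd.DataFrame,
    betas: range | list[int] = range(1, 21),
    r2_target: float = 0.9,
    n_bins: int = 10,
    signed: bool = True,
    method: str = "pearson",
) -> SoftThresholdScan:
    """Pick the smallest power whose scale-free fit reaches ``r2_target``.

    Falls back to the argmax signed R^2 (status flagged) when no power
    reaches the target.
    """
    if X.shape[0] < 30:
        raise ValueError("need >= 30 genes for a meaningful degree fit")
    cor = correlation_matrix(X, method)
    rows = []
    for b in betas:
        a = signed_adjacency(cor, b, signed)
        k = a.sum(axis=1)
        r2, slope = _scale_free_fit(k, n_bins)
        rows.append((b, r2, slope, float(k.mean())))
    table = pd.DataFrame(rows, columns=["beta", "r2_signed", "slope", "mean_k"])
    hit = table[table["r2_signed"] >= r2_target]
    if len(hit):
        return SoftThresholdScan(table, int(hit["beta"].iloc[0]), "ok")
    best = int(table.loc[table["r2_signed"].idxmax(), "beta"])
    return SoftThresholdScan(table, best, "fallback-max-r2")


def correlation_matrix(X: pd.DataFrame, method: str = "pearson") -> np.ndarray:
    M = X.to_numpy()
    if method == "spearman":
        M = stats.rankdata(M, axis=1)
    C = np.corrcoef(M)
    return np.clip((C + C.T) / 2.0, -1.0, 1.0)


def tom_matrix(cor: np.ndarray, beta: int, signed: bool = True) -> np.ndarray:
    """Topological overlap matrix from a correlation matrix.

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    L_ij = sum_u a_iu a_uj; diagonal set to 1.
    """
    cor = np.asarray(cor, dtype=float)
    if not np.allclose(cor, cor.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    a = signed_adjacency(cor, beta, signed)
    k = a.sum(axis=1)
    L = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (L + a) / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def _split_cluster(
    members: np.ndarray,
    d: np.ndarray,
    min_module_size: int,
    median_gap: float,
    depth: int,
) -> list[np.ndarray]:
    """Recursive gap split (simplified dynamic cut, two levels deep).

    A cluster is split at its largest internal merge-height gap when that gap
    exceeds the global median gap and both halves stay above the minimum
    module size.
    """
    if depth <= 0 or len(members) < 2 * min_module_size:
        return [members]
    sub = d[np.ix_(members, members)]
    L = linkage(squareform(sub, checks=False), method="average")
    heights = L[:, 2]
    gaps = np.diff(heights)
    if len(gaps) == 0 or gaps.max() <= median_gap:
        return [members]
    g = int(np.argmax(gaps))
    cut_h = (heights[g] + heights[g + 1]) / 2.0
    labs = cut_tree(L, height=cut_h).ravel()
    parts = [members[labs == v] for v in np.unique(labs)]
    if len(parts) < 2 or any(len(p) < min_module_size for p in parts):
        return [members]
    out: list[np.ndarray] = []
    for p in parts:
        out.extend(_split_cluster(p, d, min_module_size, median_gap, depth - 1))
    return out


def detect_modules(
    d: np.ndarray, min_module_size: int = 50
) -> np.ndarray:
    """Average-linkage tree cut on a dissimilarity matrix.

    Cut at 0.99 of the maximum merge height, then apply a recursive
    largest-gap split (two levels). Clusters below ``min_module_size`` get
    label 0; surviving modules are labelled 1, 2, ... by descending size.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if n < 2 * min_module_size:
        warnings.warn("fewer than 2x min_module_size genes; labels may be all 0")
    L = linkage(squareform(d, checks=False), method="average")
    heights = L[:, 2]
    if heights.max() == 0:  # all genes at zero dissimilarity: one cluster
        return (np.ones(n, dtype=int) if n >= min_module_size
                else np.zeros(n, dtype=int))
    cut_h = 0.99 * heights.max()
    labs = cut_tree(L, height=cut_h).ravel()
    median_gap = float(np.median(np.diff(np.sort(heights)))) if len(heights) > 1 else 0.0
    clusters: list[np.ndarray] = []
    for v in np.unique(labs):
        members = np.where(labs == v)[0]
        clusters.extend(_split_cluster(members, d, min_module_size, median_gap, 2))
    clusters = [c for c in clusters if len(c) >= min_module_size]
    clusters.sort(key=lambda c: (-len(c), c.min()))
    out = np.zeros(n, dtype=int)
    for i, c in enumerate(clusters, start=1):
        out[c] = i
    return out


@dataclass
class ModuleSet:
    labels: pd.Series                      # gene -> module (0 = unassigned)
    eigengenes: pd.DataFrame               # samples x modules ("ME1", ...)
    mm: pd.DataFrame | None = None         # genes x modules kME table
    gs: pd.Series | None = None            # per-gene |cor with trait|
    module_trait: pd.DataFrame | None = None  # module, r, p
    hubs: pd.DataFrame | None = None

    @property
    def module_ids(self) -> list[int]:
        return [int(c[2:]) for c in self.eigengenes.columns]

    def members(self, module: int) -> list[str]:
        return list(self.labels.index[self.labels == module])


def _eigengene(Xm: np.ndarray) -> np.ndarray:
    """Unit-norm sample scores of the module's first principal component,
    sign-oriented so the mean member correlation is positive."""
    Z = Xm - Xm.mean(axis=1, keepdims=True)
    sd = Z.std(axis=1, ddof=1)
    sd[sd == 0] = 1.0
    Z = Z / sd[:, None]
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    me = Vt[0]
    cors = np.array([np.corrcoef(me, row)[0, 1] for row in Z])
    if np.nanmean(cors) < 0:
        me = -me
    return me / np.linalg.norm(me)


def eigengene_merge(
    X: pd.DataFrame, labels: np.ndarray | pd.Series, merge_cut: float = 0.1
) -> ModuleSet:
    """Compute module eigengenes and merge highly similar modules.

    While the closest eigengene pair satisfies 1 - cor < merge_cut the two
    modules are fused and eigengenes recomputed; labels are then renumbered
    by descending module size.
    """
    lab = pd.Series(np.asarray(labels, dtype=int), index=X.index)
    modules = sorted(m for m in lab.unique() if m > 0)
    if not modules:
        raise ValueError("no modules to merge (all labels 0)")
    groups = {m: list(lab.index[lab == m]) for m in modules}
    while len(groups) > 1:
        ids = sorted(groups)
        mes = {m: _eigengene(X.loc[groups[m]].to_numpy()) for m in ids}
        best_pair, best_cor = None, -np.inf
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                c = float(np.corrcoef(mes[a], mes[b])[0, 1])
                if c > best_cor:
                    best_cor, best_pair = c, (a, b)
        if best_pair is None or 1.0 - best_cor >= merge_cut:
            break
        a, b = best_pair
        groups[a] = groups[a] + groups[b]
        del groups[b]
    # renumber by descending size, smallest original id breaking ties
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    new_lab = pd.Series(0, index=X.index, dtype=int)
    me_cols = {}
    for new_id, (_, members) in enumerate(ordered, start=1):
        new_lab[members] = new_id
        me_cols[f"ME{new_id}"] = _eigengene(X.loc[members].to_numpy())
    eig = pd.DataFrame(me_cols, index=X.columns)
    return ModuleSet(labels=new_lab, eigengenes=eig)


def mm_gs(
    X: pd.DataFrame,
    modules: ModuleSet,
    trait: np.ndarray,
    signed_gs: bool = False,
) -> ModuleSet:
    """Module membership (kME), gene significance and module-trait table.

    MM_gm = Pearson cor(gene g, eigengene m); GS_g = |cor(gene, trait)|
    (signed via ``signed_gs``); module-trait r tested with a two-sided
    Student t on n - 2 df.
    """
    trait = np.asarray(trait, dtype=float)
    if len(trait) != X.shape[1]:
        raise ValueError("trait length must equal sample count")
    if np.ptp(trait) == 0:
        raise ValueError("constant trait")
    Xa = X.to_numpy()
    n = X.shape[1]

    def cor_with(v: np.ndarray) -> np.ndarray:
        vz = (v - v.mean()) / v.std()
        Z = Xa - Xa.mean(axis=1, keepdims=True)
        sd = Z.std(axis=1)
        sd[sd == 0] = np.inf
        return (Z @ vz) / (n * sd)

    mm = pd.DataFrame(
        {c: cor_with(modules.eigengenes[c].to_numpy()) for c in modules.eigengenes},
        index=X.index,
    )
    gs_raw = cor_with(trait)
    gs = pd.Series(gs_raw if signed_gs else np.abs(gs_raw), index=X.index, name="GS")

    rows = []
    for c in modules.eigengenes:
        r = float(np.corrcoef(modules.eigengenes[c], trait)[0, 1])
        t = r * np.sqrt((n - 2) / max(1e-300, 1.0 - r**2))
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
        rows.append((int(c[2:]), r, p))
    mt = pd.DataFrame(rows, columns=["module", "r", "p"])
    return ModuleSet(
        labels=modules.labels,
        eigengenes=modules.eigengenes,
        mm=mm,
        gs=gs,
        module_trait=mt,
    )


def select_hubs(
    modules: ModuleSet, mm_min: float = 0.80, gs_min: float = 0.20
) -> pd.DataFrame:
    """Intramodular hubs: MM(own module) > mm_min and GS > gs_min (strict)."""
    if modules.mm is None or modules.gs is None:
        raise ValueError("run mm_gs first")
    rows = []
    for g in modules.labels.index:
        m = int(modules.labels[g])
        if m == 0:
            continue
        mm_own = float(modules.mm.loc[g, f"ME{m}"])
        gs = float(modules.gs[g])
        if mm_own > mm_min and gs > gs_min:
            rows.append((g, m, mm_own, gs))
    return pd.DataFrame(rows, columns=["gene", "module", "MM", "GS"])


def mds_embed(d: np.ndarray, dims: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS of a dissimilarity matrix.

    Double-centers -D^2/2 and projects on the top eigenpairs; non-positive
    eigenvalues yield zero coordinates (warned).
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if dims > n - 1:
        raise ValueError("dims must be at most n - 1")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d**2) @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(vals)[::-1][:dims]
    vals, vecs = vals[order], vecs[:, order]
    if (vals <= 0).any():
        warnings.warn("non-positive MDS eigenvalues; zero-filled coordinates")
    coords = vecs * np.sqrt(np.clip(vals, 0.0, None))
    return coords
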