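"""Hypergeometric overrepresentation analysis against GMT gene-set
collections, with Benjamini-Hochberg adjustment, Storey q-values and
multi-cluster comparison.

The test is the upper tail P(X >= k) of the hypergeometric distribution:
drawing the query of size n from a universe of N genes of which K belong to
the set, what is the chance of seeing at least the observed overlap k. The
universe always comes from the collection (or is supplied explicitly);
it is never silently inferred from an expression matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "hypergeom_p",
    "adjust_pvalues",
    "ora_compare",
]


@dataclass
class GeneSetCollection:
    sets: dict[str, list[str]]
    descriptions: dict[str, str]
    universe: list[str]

    def __post_init__(self) -> None:
        uni = set(self.universe)
        self.sets = {k: sorted(set(v) & uni) for k, v in self.sets.items()}
        self.universe = sorted(uni)

    @property
    def n_universe(self) -> int:
        return len(self.universe)


def read_gmt(path: str | Path, universe: list[str] | None = None) -> GeneSetCollection:
    """Parse a GMT file (set name, description, tab-separated gene ids).

    The universe defaults to the union of all member genes.
    """
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line {ln}: need name, "
                                 "description and at least one gene")
            name, description, *genes = parts
            sets[name] = sorted(set(g for g in genes if g))
            desc[name] = description
    uni = universe if universe is not None else sorted(
        set().union(*sets.values()) if sets else set()
    )
    return GeneSetCollection(sets=sets, descriptions=desc, universe=uni)


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in coll.sets.items():
            fh.write(
                "\t".join([name, coll.descriptions.get(name, name)] + members)
                + "\n"
            )


def hypergeom_p(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric P(X >= k) for overlap k, query n, set K,
    universe N (log-space survival function for stability)."""
    if not (0 <= k <= min(n, K) and n <= N and K <= N):
        raise ValueError(f"invalid hypergeometric bounds k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def adjust_pvalues(p) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg adjusted p-values and Storey q-values.

    Storey's null proportion uses the single-lambda estimate
    pi0 = min(1, #{p > 0.5} / (0.5 m)); q = pi0 * p_adj.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    pi0 = min(1.0, float((p > 0.5).sum()) / (0.5 * p.size))
    q = pi0 * p_adj
    return p_adj, q


def ora_compare(
    clusters: dict,
    coll: GeneSetCollection,
    min_cluster: int = 10,
    p_adj_max: float = 0.05,
    q_max: float = 0.1,
    top_k: int = 10,
) -> pd.DataFrame:
    """Overrepresentation of every cluster against every set in the
    collection, mirroring a compare-clusters table.

    Clusters with fewer than ``min_cluster`` mapped genes are skipped; BH
    and q-values are computed within each cluster x collection family; rows
    must pass p_adj < p_adj_max and q < q_max; the ``top_k`` smallest-p rows
    are kept per cluster. Columns: Cluster, ID, Description, GeneRatio,
    BgRatio, pvalue, p.adjust, qvalue, geneID, unmapped.
    """
    if not coll.sets:
        raise ValueError("empty gene-set collection")
    uni = set(coll.universe)
    N = coll.n_universe
    frames = []
    for cname, genes in clusters.items():
        query = sorted(set(genes) & uni)
        unmapped = len(set(genes)) - len(query)
        n = len(query)
        if n < min_cluster:
            continue
        rows = []
        for sid, members in coll.sets.items():
            K = len(members)
            if K == 0:
                continue
            hit = sorted(set(query) & set(members))
            k = len(hit)
            rows.append(
                {
                    "Cluster": cname,
                    "ID": sid,
                    "Description": coll.descriptions.get(sid, sid),
                    "GeneRatio": f"{k}/{n}",
                    "BgRatio": f"{K}/{N}",
                    "pvalue": hypergeom_p(k, n, K, N),
                    "geneID": "/".join(hit),
                    "unmapped": unmapped,
                }
            )
        if not rows:
            continue
        df = pd.DataFrame(rows)
        p_adj, q = adjust_pvalues(df["pvalue"].to_numpy())
        df["p.adjust"] = p_adj
        df["qvalue"] = q
        df = df[(df["p.adjust"] < p_adj_max) & (df["qvalue"] < q_max)]
        df = df.sort_values("pvalue").head(top_k)
        frames.append(df)
    cols = [
        "Cluster", "ID", "Description", "GeneRatio", "BgRatio",
        "pvalue", "p.adjust", "qvalue", "geneID", "unmapped",
    ]
    if not frames:
        return pd.DataFrame(columns=cols)
    return pd.concat(frames, ignore_index=True)[cols]
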