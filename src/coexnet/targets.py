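"""Multi-axis therapeutic-target ranking.

Combines four independent evidence axes for each gene: differential network
centrality (disease vs control backbone), module membership in its own
co-expression module, correlation with the clinical trait, and a
user-supplied tractability annotation. Classes:

* Rank A — pathology-specific centrality, MM > mm_min, GS > gs_min and
  annotated tractable: ready for biochemical follow-up.
* Rank B — same network/module/trait evidence but unknown or intractable
  chemistry: genetic-perturbation track first.
* Rank C — everything else (moderate or discordant evidence).
"""

from __future__ import annotations


import pandas as pd

__all__ = ["rank_targets", "read_tractability"]

TRACTABILITY_LEVELS = ("tractable", "unknown", "intractable")


def read_tractability(path) -> dict[str, str]:
    df = pd.read_csv(path)
    cols = list(df.columns)
    out = dict(zip(df[cols[0]].astype(str), df[cols[1]].astype(str)))
    bad = set(out.values()) - set(TRACTABILITY_LEVELS)
    if bad:
        raise ValueError(f"unknown tractability levels: {sorted(bad)}")
    return out


def rank_targets(
    diff: pd.DataFrame,
    modules,
    tractability: dict[str, str] | None = None,
    mm_min: float = 0.80,
    gs_min: float = 0.20,
) -> pd.DataFrame:
    """Assign every gene in the differential-centrality table a rank.

    ``diff`` is the output of :func:`coexnet.mstnet.differential_centrality`
    and ``modules`` a :class:`coexnet.modules.ModuleSet` with MM/GS filled
    in. Genes without a tractability entry are treated as unknown. Output is
    sorted rank A, B, C and by descending composite delta within rank.
    """
    if modules.mm is None or modules.gs is None:
        raise ValueError("modules must carry MM and GS (run mm_gs)")
    tractability = tractability or {}
    rows = []
    for g in diff.index:
        cls = diff.loc[g, "class"]
        if g in modules.labels.index and modules.labels[g] > 0:
            m = int(modules.labels[g])
            mm_own = float(modules.mm.loc[g, f"ME{m}"])
        else:
            m, mm_own = 0, 0.0
        gs = float(modules.gs[g]) if g in modules.gs.index else 0.0
        tract = tractability.get(g, "unknown")
        if tract not in TRACTABILITY_LEVELS:
            raise ValueError(f"bad tractability {tract!r} for {g}")
        core = cls == "pathology_specific" and mm_own > mm_min and gs > gs_min
        if core and tract == "tractable":
            rank = "A"
        elif core:
            rank = "B"
        else:
            rank = "C"
        rows.append(
            {
                "gene": g,
                "class": cls,
                "module": m,
                "MM": mm_own,
                "GS": gs,
                "tractability": tract,
                "composite_delta": float(diff.loc[g, "composite_delta"]),
                "rank": rank,
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["rank", "composite_delta"], ascending=[True, False]
    ).reset_index(drop=True)
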