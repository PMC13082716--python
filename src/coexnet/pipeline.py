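"""End-to-end orchestration of the three analysis branches.

preprocess -> {graph branch on control and case separately, module branch,
PCA branch} -> enrichment -> target ranking, with a JSON manifest recording
the configuration, seed and per-stage row counts so a run is reproducible
from its output directory alone.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import enrich, modules, mstnet, pca, preprocess, targets

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    expr: str
    meta: str
    gmt: str | None = None
    tractability: str | None = None
    outdir: str = "coexnet_run"
    # stage parameters (defaults are the pipeline's documented settings)
    var_cutoff: float = 0.01
    log2: bool = False
    zscore: bool = True
    covariates: tuple[str, ...] = ()
    q_max: int = 10
    alpha_retain: float = 0.05
    correlation: str = "spearman"
    tail_fraction: float = 0.8
    weight_mode: str = "signed"
    community: str = "louvain"
    beta: int | None = 12
    min_module_size: int = 50
    merge_cut: float = 0.1
    mm_min: float = 0.80
    gs_min: float = 0.20
    n_permutations: int = 20
    range_retain: float = 0.1
    n_pcs: int = 5
    min_cluster: int = 10
    p_adj_max: float = 0.05
    q_value_max: float = 0.1
    top_k: int = 10
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the result bundle to ``config.outdir``.

    Returns the manifest dictionary; raises at the first failing stage with
    the stage name in the message (partial outputs are kept on disk).
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    if config.gmt is None:
        # fail before any computation rather than at the enrichment stage
        raise ValueError("pipeline config error: gmt path is required for "
                         "the enrichment stage")

    def run_stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # annotate failures with the stage name
            _write_manifest(out, manifest)
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    def _load():
        X = preprocess.read_expression_tsv(config.expr)
        meta = preprocess.read_metadata(config.meta)
        meta = meta[meta["sample_id"].isin(X.columns)].reset_index(drop=True)
        return X[list(meta["sample_id"])], meta

    X, meta = run_stage("load", _load)
    manifest["stages"]["load"] = {"genes": int(X.shape[0]),
                                  "samples": int(X.shape[1])}

    def _pre():
        Xf = preprocess.variance_filter(X, config.var_cutoff)
        if config.log2:
            Xf = preprocess.transform_expression(Xf, zscore=False)
        kept, status = preprocess.detect_outliers(Xf)
        Xk = Xf[kept]
        mk = meta[meta["sample_id"].isin(kept)].reset_index(drop=True)
        full, null = preprocess.build_designs(mk, list(config.covariates))
        sv = preprocess.estimate_svs(
            Xk, full, null, q_max=config.q_max,
            alpha_retain=config.alpha_retain, seed=config.seed,
        )
        design = full.drop(columns=["diagnosis"])
        if sv.retained.any():
            design = pd.concat([design, sv.retained_sv], axis=1)
        Xr = preprocess.residualize(Xk, design)
        if config.zscore:
            sd = Xr.std(axis=1, ddof=1).replace(0, 1.0)
            Xr = Xr.sub(Xr.mean(axis=1), axis=0).div(sd, axis=0)
        return Xr, mk, sv, status

    Xr, meta_k, sv, outlier_status = run_stage("preprocess", _pre)
    sv.sv.to_csv(out / "surrogate_variables.tsv", sep="\t")
    manifest["stages"]["preprocess"] = {
        "genes": int(Xr.shape[0]),
        "samples": int(Xr.shape[1]),
        "svs_estimated": int(sv.sv.shape[1]),
        "svs_retained": int(sv.retained.sum()),
        "outlier_status": outlier_status,
    }

    diag = preprocess.diagnosis_vector(meta_k, Xr.columns)

    def _graph():
        tables = {}
        parts = {}
        for name, mask in (("control", diag == 0), ("case", diag == 1)):
            Xg = Xr.loc[:, mask.astype(bool)]
            C = mstnet.correlation_network(Xg, config.correlation)
            G = mstnet.sparsify_network(C, config.tail_fraction)
            tree = mstnet.mst_prim(G, config.weight_mode)
            part = mstnet.detect_communities(
                tree, config.community, seed=config.seed
            )
            tab = mstnet.compute_centralities(tree, part)
            tab.to_csv(out / f"centrality_{name}.tsv", sep="\t")
            _write_edge_list(tree, out / f"tree_{name}.tsv")
            tables[name] = tab
            parts[name] = part
        diff = mstnet.differential_centrality(tables["control"], tables["case"])
        diff.to_csv(out / "differential_centrality.tsv", sep="\t")
        return tables, parts, diff

    cent_tables, partitions, diff = run_stage("graph_branch", _graph)
    manifest["stages"]["graph_branch"] = {
        "control_nodes": int(len(cent_tables["control"])),
        "case_nodes": int(len(cent_tables["case"])),
        "differential_rows": int(len(diff)),
    }

    def _modules():
        cor = modules.correlation_matrix(Xr, "pearson")
        if config.beta is None:
            scan = modules.soft_threshold_scan(Xr)
            beta = scan.beta
        else:
            beta = config.beta
        tom = modules.tom_matrix(cor, beta)
        labels = modules.detect_modules(1.0 - tom, config.min_module_size)
        if labels.max() == 0:
            warnings.warn("no module reached min_module_size; treating all "
                          "genes as a single module")
            labels = np.ones_like(labels)
        mods = modules.eigengene_merge(Xr, labels, config.merge_cut)
        mods = modules.mm_gs(Xr, mods, diag)
        hubs = modules.select_hubs(mods, config.mm_min, config.gs_min)
        assign = pd.DataFrame({
            "gene": Xr.index,
            "module": mods.labels.to_numpy(),
            "GS": mods.gs.to_numpy(),
        })
        assign.to_csv(out / "module_assignment.tsv", sep="\t", index=False)
        mods.eigengenes.to_csv(out / "eigengenes.tsv", sep="\t")
        mods.module_trait.to_csv(out / "module_trait.tsv", sep="\t", index=False)
        hubs.to_csv(out / "module_hubs.tsv", sep="\t", index=False)
        return mods, hubs, beta

    mods, hubs, beta_used = run_stage("module_branch", _modules)
    manifest["stages"]["module_branch"] = {
        "beta": int(beta_used),
        "modules": int(len(mods.module_ids)),
        "hubs": int(len(hubs)),
    }

    def _pca():
        dec = pca.pca_decompose(Xr)
        scree = pca.permutation_scree(Xr, B=config.n_permutations,
                                      seed=config.seed)
        lists = pca.top_loading_genes(dec, config.range_retain, config.n_pcs)
        assoc = pca.pc_trait_association(dec, meta_k,
                                         ["diagnosis", "age", "sex"])
        (out / "scree.json").write_text(json.dumps({
            "observed": scree.observed.tolist(),
            "permuted_mean": scree.permuted_mean.tolist(),
            "retained": scree.retained,
        }))
        assoc.to_csv(out / "pc_trait_r2.tsv", sep="\t", index=False)
        return dec, scree, lists, assoc

    dec, scree, pc_lists, pc_assoc = run_stage("pca_branch", _pca)
    manifest["stages"]["pca_branch"] = {
        "retained_pcs": int(scree.retained),
        "n_pc_gene_lists": int(len(pc_lists)),
    }

    def _enrich():
        coll = enrich.read_gmt(config.gmt)
        clusters: dict[str, list[str]] = {}
        for m in mods.module_ids:
            clusters[f"module_{m}"] = mods.members(m)
        for pc_name, d in pc_lists.items():
            clusters[f"{pc_name}_top"] = d["top"]
            clusters[f"{pc_name}_bottom"] = d["bottom"]
        for name, part in partitions.items():
            for cid in range(1, part.n_communities + 1):
                clusters[f"{name}_community_{cid}"] = part.members(cid)
        table = enrich.ora_compare(
            clusters, coll, min_cluster=config.min_cluster,
            p_adj_max=config.p_adj_max, q_max=config.q_value_max,
            top_k=config.top_k,
        )
        table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        return table

    enr = run_stage("enrichment", _enrich)
    manifest["stages"]["enrichment"] = {"rows": int(len(enr))}

    def _prio():
        tract = (targets.read_tractability(config.tractability)
                 if config.tractability else {})
        ranked = targets.rank_targets(diff, mods, tract,
                                      config.mm_min, config.gs_min)
        ranked.to_csv(out / "ranked_targets.tsv", sep="\t", index=False)
        return ranked

    ranked = run_stage("prioritize", _prio)
    manifest["stages"]["prioritize"] = {
        "rank_A": int((ranked["rank"] == "A").sum()),
        "rank_B": int((ranked["rank"] == "B").sum()),
        "rank_C": int((ranked["rank"] == "C").sum()),
    }

    _write_manifest(out, manifest)
    return manifest


def _write_edge_list(tree, path) -> None:
    rows = [
        {"source": u, "target": v, "weight": d["weight"]}
        for u, v, d in tree.graph.edges(data=True)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  default=str))
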