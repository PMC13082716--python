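"""Synthetic two-condition expression data with planted network structure.

Generates genes x samples expression matrices under a latent-factor model:
each planted module shares one Gaussian factor, gene profiles are
``loading * factor + noise`` with the loading chosen so that the expected
within-module correlation matches a target. On top of the block structure the
generator plants

* intramodular hub genes (elevated loading within their own module),
* disease-specific hubs that load negatively on two module factors in case
  samples only (so they become dense repressor-like connectors in the case
  network while being pure noise in controls),
* an additive batch artifact on a subset of genes for a subset of samples
  (mimicking a library-protocol confound such as heterogeneous rRNA-depletion
  kits), and
* one module whose factor is correlated with the binary diagnosis at a
  target level (the trait-linked module).

Every downstream analysis stage can therefore be scored against the returned
ground truth without any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_expression",
    "generate_genesets",
    "generate_graph_fixture",
]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic cohort.

    Defaults emulate a two-group postmortem brain cohort (261 controls /
    153 cases) with four correlated modules of 50 genes each inside a
    300-gene matrix, plus planted hubs, a trait-linked module and a batch
    artifact.
    """

    n_genes: int = 300
    n_control: int = 261
    n_case: int = 153
    module_sizes: tuple[int, ...] = (50, 50, 50, 50)
    within_module_cor: float = 0.8
    hub_genes_per_module: int = 2
    disease_hub_count: int = 1
    trait_effect: float = 0.6
    batch_fraction: float = 0.3
    batch_shift: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_control <= 0 or self.n_case <= 0:
            raise ValueError("n_genes, n_control and n_case must be positive")
        if any(m < 0 for m in self.module_sizes):
            raise ValueError("module sizes must be non-negative")
        if sum(self.module_sizes) + self.disease_hub_count > self.n_genes:
            raise ValueError("sum(module_sizes) + disease hubs exceeds n_genes")
        if not 0.0 < self.within_module_cor < 1.0:
            raise ValueError("within_module_cor must be strictly inside (0, 1)")
        if not 0.0 <= self.batch_fraction <= 1.0:
            raise ValueError("batch_fraction must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.hub_genes_per_module < 0 or self.disease_hub_count < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.n_control + self.n_case


@dataclass
class GroundTruth:
    """What was planted: the key against which recovery is scored."""

    module_labels: dict[str, int]          # gene -> module (0 = background)
    hub_genes: list[str]                   # intramodular hubs
    disease_hubs: list[str]                # case-only multi-module hubs
    trait_module: int                      # module whose factor tracks diagnosis
    batch: dict[str, int]                  # sample -> batch group (0/1)
    batch_genes: list[str]                 # genes receiving the batch shift
    enriched_sets: dict[int, str] = field(default_factory=dict)

    def module_members(self, module: int) -> list[str]:
        return [g for g, m in self.module_labels.items() if m == module]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def generate_expression(
    config: SynthConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw one synthetic cohort.

    Returns ``(expression, metadata, truth)`` where expression is a
    genes x samples DataFrame on a log-like Gaussian scale (exponentiate via
    ``2 ** X`` for TPM-like positives), metadata has one row per sample with
    diagnosis and nuisance covariates, and truth records the planted
    structure. Deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n_mod = len(config.module_sizes)
    n_s = config.n_samples

    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    samples = [f"S{i:04d}" for i in range(n_s)]
    diagnosis = np.array([0] * config.n_control + [1] * config.n_case)

    # Module factors: factor 1 tracks the standardized diagnosis at the
    # requested level; the rest are independent standard normals.
    d_std = (diagnosis - diagnosis.mean()) / diagnosis.std()
    factors = rng.standard_normal((n_mod, n_s))
    if n_mod > 0 and abs(config.trait_effect) > 0:
        te = config.trait_effect
        factors[0] = te * d_std + np.sqrt(1.0 - te**2) * factors[0]

    rho = config.within_module_cor
    rho_hub = (1.0 + rho) / 2.0  # hubs sit halfway between rho and 1
    lam = config.noise_sd * np.sqrt(rho / (1.0 - rho))
    lam_hub = config.noise_sd * np.sqrt(rho_hub / (1.0 - rho_hub))

    X = config.noise_sd * rng.standard_normal((config.n_genes, n_s))
    labels = {g: 0 for g in genes}
    hubs: list[str] = []
    idx = 0
    for m, size in enumerate(config.module_sizes, start=1):
        n_hub = min(config.hub_genes_per_module, size)
        for j in range(size):
            g = genes[idx]
            labels[g] = m
            loading = lam_hub if j < n_hub else lam
            if j < n_hub:
                hubs.append(g)
            X[idx] += loading * factors[m - 1]
            idx += 1

    # Disease-specific hubs: in case samples they load negatively on the
    # first two module factors (repressor-like connectors); in controls they
    # are pure noise with the same marginal spread.
    disease_hubs: list[str] = []
    if config.disease_hub_count > 0 and n_mod >= 2:
        case = diagnosis == 1
        for _ in range(config.disease_hub_count):
            g = genes[idx]
            disease_hubs.append(g)
            combo = -(factors[0] + factors[1]) / np.sqrt(2.0)
            X[idx, case] += lam * combo[case]
            # match the marginal variance in controls so the hub is not a
            # trivially low-variance gene there
            X[idx, ~case] += lam * rng.standard_normal((~case).sum())
            idx += 1

    # Batch artifact: a random batch_fraction of samples get +batch_shift
    # (in noise-SD units) on a random quarter of genes.
    n_batch = int(round(config.batch_fraction * n_s))
    batch_samples = rng.choice(n_s, size=n_batch, replace=False)
    batch_vec = np.zeros(n_s, dtype=int)
    batch_vec[batch_samples] = 1
    n_bg = max(1, config.n_genes // 4)
    batch_gene_idx = rng.choice(config.n_genes, size=n_bg, replace=False)
    if config.batch_shift != 0 and n_batch > 0:
        X[np.ix_(batch_gene_idx, batch_samples)] += (
            config.batch_shift * config.noise_sd
        )

    expr = pd.DataFrame(X, index=genes, columns=samples)
    expr.index.name = "gene_id"

    meta = pd.DataFrame(
        {
            "sample_id": samples,
            "diagnosis": np.where(diagnosis == 1, "case", "control"),
            "age": np.clip(rng.normal(45, 15, n_s), 18, 90).round(1),
            "sex": rng.choice(["M", "F"], n_s),
            "region": rng.choice(["DLPFC", "HIPP", "CBC"], n_s),
            "protocol": np.where(batch_vec == 1, "kitB", "kitA"),
            "RIN": np.clip(rng.normal(7.5, 1.0, n_s), 4, 10).round(2),
        }
    )

    truth = GroundTruth(
        module_labels=labels,
        hub_genes=hubs,
        disease_hubs=disease_hubs,
        trait_module=1 if n_mod else 0,
        batch={s: int(b) for s, b in zip(samples, batch_vec)},
        batch_genes=[genes[i] for i in sorted(batch_gene_idx)],
    )
    return expr, meta, truth


def generate_genesets(
    truth: GroundTruth,
    n_decoy: int,
    set_size_range: tuple[int, int] = (20, 60),
    seed: int = 0,
) -> dict[str, list[str]]:
    """One true gene set per planted module plus random decoy sets.

    True sets draw >= 80% of their members from the module and the rest from
    the background; decoys are uniform draws from the whole universe. Updates
    ``truth.enriched_sets`` with the true-set names.
    """
    rng = np.random.default_rng(seed)
    universe = sorted(truth.module_labels)
    modules = sorted({m for m in truth.module_labels.values() if m > 0})
    if not modules:
        raise ValueError("ground truth contains no planted modules")
    lo, hi = set_size_range
    if hi > len(universe):
        raise ValueError("set_size_range exceeds the gene universe")
    if lo < 1 or lo > hi:
        raise ValueError("invalid set_size_range")

    sets: dict[str, list[str]] = {}
    for m in modules:
        members = truth.module_members(m)
        size = min(int(rng.integers(lo, hi + 1)), len(universe))
        n_true = max(1, int(np.ceil(0.8 * size)))
        n_true = min(n_true, len(members))
        picked = list(rng.choice(members, size=n_true, replace=False))
        others = [g for g in universe if truth.module_labels[g] != m]
        # cap the filler so module members stay >= 80% of the set even when
        # the drawn size exceeds the module
        n_fill = min(size - n_true, n_true // 4, len(others))
        if n_fill > 0:
            picked += list(rng.choice(others, size=n_fill, replace=False))
        name = f"MODULE{m}_TRUE"
        sets[name] = sorted(set(picked))
        truth.enriched_sets[m] = name
    for j in range(n_decoy):
        size = int(rng.integers(lo, hi + 1))
        sets[f"DECOY{j:03d}"] = sorted(
            rng.choice(universe, size=size, replace=False)
        )
    return sets


def generate_graph_fixture(kind: str, n: int, seed: int = 0) -> nx.Graph:
    """Small weighted graphs for exercising centrality and topology code.

    kinds: ``preferential_attachment`` (Barabasi-Albert, m=2),
    ``toy_path`` (path graph, unit weights), ``two_cliques_bridge``
    (two n-cliques joined by one bridge edge).
    """
    if kind == "preferential_attachment":
        if n < 3:
            raise ValueError("preferential attachment needs n >= 3")
        g = nx.barabasi_albert_graph(n, 2, seed=seed)
        nx.set_edge_attributes(g, 1.0, "weight")
        return g
    if kind == "toy_path":
        if n < 3:
            raise ValueError("toy_path needs n >= 3")
        g = nx.path_graph(n)
        nx.set_edge_attributes(g, 1.0, "weight")
        return g
    if kind == "two_cliques_bridge":
        if n < 3:
            raise ValueError("two_cliques_bridge needs clique size >= 3")
        g = nx.complete_graph(n)
        h = nx.relabel_nodes(nx.complete_graph(n), {i: i + n for i in range(n)})
        g = nx.union(g, h)
        g.add_edge(n - 1, n)
        nx.set_edge_attributes(g, 1.0, "weight")
        return g
    raise ValueError(f"unknown fixture kind: {kind!r}")


def write_expression_tsv(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t")


def write_metadata_csv(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, index=False)


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, name] + list(members)) + "\n")
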