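"""PCA branch: decomposition, permutation-null component retention
(parallel analysis), range-retain loading extraction and PC-trait R^2.

The permutation null shuffles every gene's values independently across
samples, which destroys inter-gene correlation while preserving each gene's
marginal distribution; a component is retained while its observed variance
stays strictly above the mean permuted variance at the same rank
(consecutive-prefix rule).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "pca_decompose",
    "permutation_scree",
    "top_loading_genes",
    "pc_trait_association",
    "PCDecomposition",
    "PermutationScree",
]


@dataclass
class PCDecomposition:
    scores: pd.DataFrame        # samples x r
    loadings: pd.DataFrame      # genes x r, unit-norm columns
    variance_fraction: np.ndarray


def pca_decompose(
    X: pd.DataFrame, center: bool = True, zscore: bool = False
) -> PCDecomposition:
    """SVD of the (centered, optionally gene-standardized) matrix with
    samples as observations.

    Sign convention: each loading column's largest-|value| entry is
    positive, so decompositions are reproducible across runs.
    """
    if X.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    M = X.to_numpy(dtype=float).T  # samples x genes
    if center:
        M = M - M.mean(axis=0, keepdims=True)
    if zscore:
        sd = M.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise ValueError("zero-variance gene under zscore")
        M = M / sd
    if np.allclose(M, 0):
        raise ValueError("constant matrix has no principal components")
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    r = len(s)
    for j in range(r):  # deterministic signs
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    var = s**2
    frac = var / var.sum()
    cols = [f"PC{j + 1}" for j in range(r)]
    scores = pd.DataFrame(U * s, index=X.columns, columns=cols)
    loadings = pd.DataFrame(Vt.T, index=X.index, columns=cols)
    return PCDecomposition(scores=scores, loadings=loadings, variance_fraction=frac)


@dataclass
class PermutationScree:
    observed: np.ndarray
    permuted_mean: np.ndarray
    n_permutations: int
    seed: int
    retained: int


def permutation_scree(
    X: pd.DataFrame, B: int = 20, seed: int = 0
) -> PermutationScree:
    """Observed vs permutation-null PC variances and the retained count."""
    if B < 5:
        raise ValueError("need at least 5 permutations")
    rng = np.random.default_rng(seed)
    obs = pca_decompose(X).variance_fraction
    M = X.to_numpy(dtype=float)
    perm = np.zeros((B, len(obs)))
    for b in range(B):
        P = M.copy()
        for i in range(P.shape[0]):
            rng.shuffle(P[i])
        frac = pca_decompose(
            pd.DataFrame(P, index=X.index, columns=X.columns)
        ).variance_fraction
        perm[b, : len(frac)] = frac
    mean_perm = perm.mean(axis=0)
    r = 0
    for i in range(len(obs)):
        if obs[i] > mean_perm[i]:
            r += 1
        else:
            break
    return PermutationScree(
        observed=obs, permuted_mean=mean_perm, n_permutations=B, seed=seed,
        retained=r,
    )


def top_loading_genes(
    P: PCDecomposition, range_retain: float = 0.1, n_pcs: int = 5
) -> dict[str, dict[str, list[str]]]:
    """Genes within ``range_retain`` of either extreme of each PC's loadings.

    Per PC the loading range is max - min; the top list keeps genes with
    loading >= max - range_retain * range and the bottom list mirrors it
    (closed inequalities, so boundary genes are kept).
    """
    if n_pcs > P.loadings.shape[1]:
        raise ValueError("n_pcs exceeds the decomposition rank")
    out: dict[str, dict[str, list[str]]] = {}
    for j in range(n_pcs):
        col = P.loadings.iloc[:, j]
        rng = col.max() - col.min()
        if rng == 0:
            warnings.warn(f"PC{j + 1} loadings constant; empty lists")
            out[f"PC{j + 1}"] = {"top": [], "bottom": []}
            continue
        eps = 1e-9 * rng  # keep the closed inequality robust to rounding
        hi = col.max() - range_retain * rng - eps
        lo = col.min() + range_retain * rng + eps
        out[f"PC{j + 1}"] = {
            "top": sorted(col.index[col >= hi]),
            "bottom": sorted(col.index[col <= lo]),
        }
    return out


def pc_trait_association(
    P: PCDecomposition, meta: pd.DataFrame, traits: list[str] | None = None,
    n_pcs: int = 6,
) -> pd.DataFrame:
    """Squared Pearson correlation between PC scores and coded traits.

    diagnosis is coded control=0/case=1, sex 0/1, other categoricals
    one-vs-rest per level; constant traits are excluded with a warning.
    """
    n_pcs = min(n_pcs, P.scores.shape[1])
    meta = meta.set_index("sample_id").loc[list(P.scores.index)]
    traits = traits or [c for c in meta.columns]
    coded: dict[str, np.ndarray] = {}
    for t in traits:
        col = meta[t]
        if pd.api.types.is_numeric_dtype(col):
            coded[t] = col.to_numpy(dtype=float)
        elif t == "diagnosis":
            coded[t] = col.map({"control": 0.0, "case": 1.0}).to_numpy()
        elif col.nunique() == 2:
            levels = sorted(col.unique())
            coded[t] = (col == levels[1]).to_numpy(dtype=float)
        else:
            for level in sorted(col.unique()):
                coded[f"{t}={level}"] = (col == level).to_numpy(dtype=float)
    rows = []
    for name, v in coded.items():
        if np.ptp(v) == 0:
            warnings.warn(f"trait {name!r} is constant; excluded")
            continue
        for j in range(n_pcs):
            r = np.corrcoef(P.scores.iloc[:, j], v)[0, 1]
            rows.append((name, f"PC{j + 1}", float(r**2)))
    out = pd.DataFrame(rows, columns=["trait", "pc", "r2"])
    return out.sort_values(["trait", "r2"], ascending=[True, False]).reset_index(
        drop=True
    )
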