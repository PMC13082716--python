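"""Expression preprocessing: filtering, transforms, surrogate variables,
outlier masking and a PVCA-style variance decomposition.

The surrogate-variable step follows the residual-SVD construction: regress
every gene on the full design (covariates + diagnosis), take the top
right-singular vectors of the residual matrix as candidate SVs, keep as many
as pass a permutation parallel-analysis rule, and retain only those not
significantly associated with diagnosis so the biological contrast is never
absorbed into the correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

__all__ = [
    "read_expression_tsv",
    "read_metadata",
    "build_designs",
    "variance_filter",
    "transform_expression",
    "qq_points",
    "residualize",
    "estimate_svs",
    "detect_outliers",
    "pvca_like",
    "SurrogateVariables",
    "diagnosis_vector",
]


def read_expression_tsv(path) -> pd.DataFrame:
    """Load a genes x samples expression table (gene ids in column 0)."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if df.index.duplicated().any():
        raise ValueError("duplicate gene ids in expression table")
    if df.columns.duplicated().any():
        raise ValueError("duplicate sample ids in expression table")
    if df.isna().any().any():
        raise ValueError("expression table contains missing values")
    return df.astype(float)


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep=None, engine="python")
    if "sample_id" not in meta.columns or "diagnosis" not in meta.columns:
        raise ValueError("metadata needs sample_id and diagnosis columns")
    return meta


def diagnosis_vector(meta: pd.DataFrame, samples=None) -> np.ndarray:
    """Diagnosis coded control=0 / case=1, aligned to ``samples`` order."""
    m = meta.set_index("sample_id")["diagnosis"]
    if samples is not None:
        m = m.loc[list(samples)]
    coded = m.map({"control": 0, "case": 1})
    if coded.isna().any():
        raise ValueError("diagnosis must be 'control' or 'case'")
    return coded.to_numpy(dtype=float)


def build_designs(
    meta: pd.DataFrame, covariates: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full (covariates + diagnosis) and null (covariates only) designs.

    Categorical covariates are dummy-coded (first level dropped); an
    intercept column is always present.
    """
    covariates = covariates or []
    null = pd.DataFrame({"intercept": np.ones(len(meta))}, index=meta["sample_id"])
    for c in covariates:
        col = meta[c]
        if pd.api.types.is_numeric_dtype(col):
            null[c] = col.to_numpy(dtype=float)
        else:
            dummies = pd.get_dummies(col, prefix=c, drop_first=True, dtype=float)
            dummies.index = null.index
            null = pd.concat([null, dummies], axis=1)
    full = null.copy()
    full["diagnosis"] = diagnosis_vector(meta)
    return full, null


def variance_filter(X: pd.DataFrame, cutoff: float = 0.01) -> pd.DataFrame:
    """Keep genes whose sample variance strictly exceeds ``cutoff``."""
    v = X.var(axis=1, ddof=1)
    kept = X.loc[v > cutoff]
    if kept.empty:
        raise ValueError("variance filter removed every gene")
    return kept


def transform_expression(
    X: pd.DataFrame, log2_offset: float = 1.0, zscore: bool = False
) -> pd.DataFrame:
    """log2(x + offset), optionally followed by per-gene z-scoring."""
    if (X.to_numpy() < 0).any():
        raise ValueError("negative values: input must be raw non-negative")
    Y = np.log2(X + log2_offset)
    if zscore:
        Y = Y.sub(Y.mean(axis=1), axis=0).div(Y.std(axis=1, ddof=1), axis=0)
    return Y


def qq_points(values) -> tuple[np.ndarray, np.ndarray]:
    """Normal Q-Q pairs: theoretical quantiles at (i - 0.5)/n vs sorted data."""
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 3:
        raise ValueError("need at least 3 values for a Q-Q plot")
    probs = (np.arange(1, n + 1) - 0.5) / n
    return stats.norm.ppf(probs), np.sort(v)


def _check_full_rank(design: pd.DataFrame) -> None:
    D = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        # name the columns involved in the collinearity for the error message
        bad = []
        for j in range(D.shape[1]):
            sub = np.delete(D, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(design.columns[j])
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")


def residualize(X: pd.DataFrame, design: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Per-gene OLS residuals against the design (intercept always included)."""
    D = np.asarray(design, dtype=float)
    if D.ndim == 1:
        D = D[:, None]
    if D.shape[0] != X.shape[1]:
        raise ValueError("design rows must equal the number of samples")
    if isinstance(design, pd.DataFrame):
        cols = list(design.columns)
    else:
        cols = [f"x{j}" for j in range(D.shape[1])]
    has_intercept = any(
        np.ptp(D[:, j]) == 0 and D[0, j] != 0 for j in range(D.shape[1])
    )
    if not has_intercept:
        D = np.column_stack([np.ones(D.shape[0]), D])
        cols = ["intercept"] + cols
    _check_full_rank(pd.DataFrame(D, columns=cols))
    # project out the design via QR, vectorized over genes
    Q, _ = np.linalg.qr(D)
    R = X.to_numpy() - (X.to_numpy() @ Q) @ Q.T
    return pd.DataFrame(R, index=X.index, columns=X.columns)


@dataclass
class SurrogateVariables:
    """Residual-SVD surrogate variables with the diagnosis-retention rule."""

    sv: pd.DataFrame               # samples x q, unit-norm orthogonal columns
    diagnosis_p: np.ndarray        # per-SV two-group association p-value
    retained: np.ndarray           # True where p >= alpha_retain

    @property
    def retained_sv(self) -> pd.DataFrame:
        return self.sv.loc[:, self.retained]


def _perm_rank(var_obs: np.ndarray, R: np.ndarray, B: int, rng) -> int:
    """Parallel-analysis rank: longest prefix where the observed component
    variance beats the mean permuted variance at the same rank."""
    n_g, n_s = R.shape
    perm_var = np.zeros((B, len(var_obs)))
    Rp = R.copy()
    for b in range(B):
        for i in range(n_g):
            rng.shuffle(Rp[i])
        s = np.linalg.svd(Rp - Rp.mean(axis=1, keepdims=True), compute_uv=False)
        v = s**2
        perm_var[b, : len(var_obs)] = v[: len(var_obs)]
    mean_perm = perm_var.mean(axis=0)
    r = 0
    for i in range(len(var_obs)):
        if var_obs[i] > mean_perm[i]:
            r += 1
        else:
            break
    return r


def estimate_svs(
    X: pd.DataFrame,
    full_design: pd.DataFrame,
    null_design: pd.DataFrame | None = None,
    q_max: int = 10,
    alpha_retain: float = 0.05,
    B: int = 20,
    seed: int = 0,
) -> SurrogateVariables:
    """Estimate surrogate variables from null-model residuals.

    The model pair is (full = covariates + diagnosis, null = covariates
    only). SVs are the top right-singular vectors of the residuals against
    the null design, so latent structure correlated with diagnosis remains
    visible; the count is chosen by permutation parallel analysis (capped at
    ``q_max``); each SV is then tested for association with diagnosis and
    flagged not-retained when p < alpha_retain — only retained SVs are safe
    to regress out without absorbing the biological contrast.
    """
    if q_max <= 0:
        raise ValueError("q_max must be positive")
    if null_design is None:
        null_design = full_design.drop(columns=["diagnosis"])
    rank_full = np.linalg.matrix_rank(full_design.to_numpy(dtype=float))
    if q_max >= X.shape[1] - rank_full:
        q_max = max(1, X.shape[1] - rank_full - 1)
    rng = np.random.default_rng(seed)
    R = residualize(X, null_design).to_numpy()
    Rc = R - R.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(Rc, full_matrices=False)
    var_obs = (s**2)[:q_max]
    q = _perm_rank(var_obs, R, B, rng)  # may be 0: no SV beats the null
    sv = Vt[:q].T  # samples x q, unit-norm orthogonal rows of Vt
    diag = full_design["diagnosis"].to_numpy(dtype=float)
    pvals = np.empty(q)
    for j in range(q):
        res = stats.linregress(diag, sv[:, j])
        pvals[j] = res.pvalue
    retained = pvals >= alpha_retain
    sv_df = pd.DataFrame(
        sv, index=X.columns, columns=[f"SV{j + 1}" for j in range(q)]
    )
    return SurrogateVariables(sv=sv_df, diagnosis_p=pvals, retained=retained)


def detect_outliers(
    X: pd.DataFrame,
    min_cluster_frac: float = 0.1,
    gap_frac_min: float = 0.3,
) -> tuple[list[str], str]:
    """Flag outlier samples by average-linkage hierarchical clustering.

    The dendrogram is cut at the largest gap between consecutive merge
    heights within the top quartile of merges; clusters holding fewer than
    ``min_cluster_frac`` of the samples are flagged. No cut is made (nobody
    flagged) unless that gap spans at least ``gap_frac_min`` of the full
    merge-height range — a homogeneous cohort shows max gaps around a tenth
    of the range, a genuinely shifted sample pushes the gap to most of it.
    Returns (kept sample ids, status) where status is "ok" or
    "all-retained" (safety valve when the cut would discard more than half
    the cohort).
    """
    n = X.shape[1]
    if n < 4:
        raise ValueError("need at least 4 samples for outlier detection")
    Z = X.sub(X.mean(axis=1), axis=0)
    sd = X.std(axis=1, ddof=1).replace(0, 1.0)
    Z = Z.div(sd, axis=0)
    L = linkage(pdist(Z.T.to_numpy()), method="average")
    heights = L[:, 2]
    q0 = max(0, int(np.floor(0.75 * len(heights))) - 1)
    top = heights[q0:]
    if len(top) < 2:
        return list(X.columns), "ok"
    gaps = np.diff(top)
    g = int(np.argmax(gaps))
    height_range = heights.max() - heights.min()
    if height_range == 0 or gaps[g] < gap_frac_min * height_range:
        return list(X.columns), "ok"
    cut = (top[g] + top[g + 1]) / 2.0
    labels = fcluster(L, t=cut, criterion="distance")
    kept_mask = np.zeros(n, dtype=bool)
    for lab in np.unique(labels):
        members = labels == lab
        if members.sum() >= min_cluster_frac * n:
            kept_mask |= members
    if kept_mask.sum() < 0.5 * n:
        return list(X.columns), "all-retained"
    return list(X.columns[kept_mask]), "ok"


def pvca_like(
    X: pd.DataFrame,
    meta: pd.DataFrame,
    covariates: list[str],
    n_pcs: int = 10,
) -> dict[str, float]:
    """Eigenvalue-weighted per-PC R-squared variance decomposition.

    For each of the top ``n_pcs`` sample-space principal components, the
    score vector is regressed on each covariate separately; the covariate's
    fraction is the eigenvalue-weighted sum of those R-squared values, the
    residual collects what no covariate explains, and everything is
    normalized to sum to one.
    """
    if n_pcs > X.shape[1] - 1:
        raise ValueError("n_pcs must be at most samples - 1")
    meta = meta.set_index("sample_id").loc[list(X.columns)].reset_index()
    Xc = X.to_numpy() - X.to_numpy().mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    lam = (s**2)[:n_pcs]
    w = lam / lam.sum()
    scores = Vt[:n_pcs].T  # samples x n_pcs

    usable: list[str] = []
    designs: dict[str, np.ndarray] = {}
    for c in covariates:
        col = meta[c]
        if col.nunique() < 2:
            warnings.warn(f"covariate {c!r} is constant; excluded")
            continue
        if pd.api.types.is_numeric_dtype(col):
            D = col.to_numpy(dtype=float)[:, None]
        else:
            D = pd.get_dummies(col, drop_first=True, dtype=float).to_numpy()
        designs[c] = np.column_stack([np.ones(len(col)), D])
        usable.append(c)

    r2 = np.zeros((n_pcs, len(usable)))
    for i in range(n_pcs):
        y = scores[:, i]
        tot = ((y - y.mean()) ** 2).sum()
        for j, c in enumerate(usable):
            D = designs[c]
            beta, *_ = np.linalg.lstsq(D, y, rcond=None)
            resid = y - D @ beta
            r2[i, j] = max(0.0, 1.0 - (resid**2).sum() / tot)
        row_sum = r2[i].sum()
        if row_sum > 1.0:  # covariates overlap; clip proportionally
            r2[i] *= 1.0 / row_sum
    fractions = {c: float((w * r2[:, j]).sum()) for j, c in enumerate(usable)}
    fractions["residual"] = float((w * (1.0 - r2.sum(axis=1))).sum())
    total = sum(fractions.values())
    return {k: v / total for k, v in fractions.items()}
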