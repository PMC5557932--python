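"""Discovery association scan with permutation-based minP FWER control.

Per CpG, methylation β-values are logit-transformed to M-values
(``M = log2(beta / (1 - beta))``) and regressed on age with the 6-part blood
cell composition as covariates (one fraction dropped to break the
compositional collinearity).  Family-wise error is controlled empirically:
age is permuted across samples K times, each permuted scan's minimum p-value
is recorded, and the FWER of a CpG with observed p is the fraction of
permuted minima strictly below it::

    FWER_j = #{ i : min_p[i] < p_obs_j } / K

The permutation deliberately breaks within-subject correlation of repeated
measures, so the point estimates can be plain OLS while significance is
assessed against a null that shares the marginal age distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CELL_TYPES, SEX_CHROMOSOMES, CpgManifest, MethylationStudy

__all__ = [
    "BETA_CLAMP_EPS",
    "beta_to_m",
    "m_to_beta",
    "filter_autosomal",
    "fit_cpg_ols",
    "run_scan",
    "permutation_null",
    "estimate_fwer",
    "significant_set",
    "run_ewas",
    "PermutationNull",
]

logger = logging.getLogger(__name__)

#: β-values of exactly 0 or 1 are clamped this far inside (0, 1) before the logit.
BETA_CLAMP_EPS = 1e-6

#: Cell fraction excluded from the design (the largest component; the six
#: fractions sum to 1, so one must be dropped to keep the design full rank).
DROPPED_CELL = "Gran"

MIN_PERMUTATIONS = 20


def beta_to_m(beta, eps: float = BETA_CLAMP_EPS):
    """Logit (base 2) transform of methylation β-values.

    Values of exactly 0 or 1 are clamped to ``eps`` / ``1 - eps`` so the
    result stays finite; anything outside [0, 1] is an error.
    """
    arr = np.asarray(beta, dtype=float)
    if ((arr < 0) | (arr > 1) | ~np.isfinite(arr)).any():
        raise ValueError("beta values must lie in [0, 1]")
    clamped = np.clip(arr, eps, 1.0 - eps)
    m = np.log2(clamped / (1.0 - clamped))
    if np.isscalar(beta):
        return float(m)
    return m


def m_to_beta(m):
    """Inverse of :func:`beta_to_m` (exact away from the clamp zone)."""
    arr = np.asarray(m, dtype=float)
    beta = np.exp2(arr) / (np.exp2(arr) + 1.0)
    if np.isscalar(m):
        return float(beta)
    return beta


def filter_autosomal(
    manifest: CpgManifest, study: MethylationStudy
) -> tuple[CpgManifest, MethylationStudy]:
    """Drop CpGs on chromosomes X and Y from both manifest and matrix,
    preserving the original CpG order."""
    keep = [
        c
        for c in study.cpg_ids
        if manifest.table.loc[c, "chromosome"] not in SEX_CHROMOSOMES
    ]
    if not keep:
        logger.warning("filter_autosomal: no autosomal CpGs remain")
    return manifest.subset(keep), study.subset_cpgs(keep)


def _design_matrix(age: np.ndarray, cells: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    # constant cell columns carry no information and are absorbed by the intercept
    covar = [
        c for c in CELL_TYPES
        if c != DROPPED_CELL and cells[c].nunique() > 1
    ]
    X = np.column_stack([np.ones(len(age)), age, cells[covar].to_numpy()])
    return X, ["intercept", "age"] + covar


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    # Column-pivoted look at the QR diagonal to name the collinear columns.
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [names[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {r} < {X.shape[1]}); "
            f"collinear column(s): {bad or names}"
        )


def _scan_matrix(M: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS of every column of M on X; slope/se/p for the age column (index 1).

    Closed-form vectorised fit: one QR of X serves all CpGs.
    """
    n, d = X.shape
    if n - d < 2:
        raise ValueError(f"need at least {d + 2} samples for {d} design columns")
    Q, R = np.linalg.qr(X)
    coef = np.linalg.solve(R, Q.T @ M)
    resid = M - X @ coef
    df = n - d
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    Rinv = np.linalg.inv(R)
    xtx_inv_age = float((Rinv @ Rinv.T)[1, 1])
    se = np.sqrt(sigma2 * xtx_inv_age)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef[1] / se, np.inf * np.sign(coef[1]))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)  # keep p in (0, 1]
    return coef[1], se, p


def fit_cpg_ols(
    m: np.ndarray, age: np.ndarray, cells: pd.DataFrame
) -> tuple[float, float, float]:
    """Single-CpG OLS of M on intercept + age + 5 cell fractions.

    Returns (slope, se, two-sided p) for the age coefficient.  Implemented
    through statsmodels, independently of the vectorised scan path.
    """
    import statsmodels.api as sm

    X, names = _design_matrix(np.asarray(age, dtype=float), cells)
    _check_rank(X, names)
    res = sm.OLS(np.asarray(m, dtype=float), X).fit()
    return float(res.params[1]), float(res.bse[1]), float(res.pvalues[1])


def run_scan(study: MethylationStudy, manifest: CpgManifest | None = None) -> pd.DataFrame:
    """Per-CpG regression scan of the whole study.

    Returns a DataFrame indexed by cpg_id with columns ``slope``, ``se``,
    ``p_obs`` and ``direction`` (gain for positive slopes, loss otherwise).
    """
    age = study.sheet["age"].to_numpy(dtype=float)
    X, names = _design_matrix(age, study.cells)
    _check_rank(X, names)
    M = beta_to_m(study.beta.to_numpy())
    slope, se, p = _scan_matrix(M, X)
    return pd.DataFrame(
        {
            "slope": slope,
            "se": se,
            "p_obs": p,
            "direction": np.where(slope > 0, "gain", "loss"),
        },
        index=study.cpg_ids.rename("cpg_id"),
    )


@dataclass(frozen=True)
class PermutationNull:
    """Null distribution of the per-scan minimum p-value."""

    min_p: np.ndarray
    k: int
    seed: int

    def __post_init__(self) -> None:
        if len(self.min_p) != self.k:
            raise ValueError("min_p must have exactly k entries")
        if ((self.min_p <= 0) | (self.min_p > 1)).any():
            raise ValueError("min_p entries must lie in (0, 1]")


def permutation_null(
    study: MethylationStudy,
    manifest: CpgManifest | None = None,
    k: int = 300,
    seed: int = 0,
) -> PermutationNull:
    """K permuted scans: age is shuffled uniformly across samples (M-values
    and cell fractions untouched) and each scan's minimum p-value recorded."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k < MIN_PERMUTATIONS:
        logger.warning(
            "k=%d permutations gives FWER resolution 1/%d; at least %d recommended",
            k, k, MIN_PERMUTATIONS,
        )
    age = study.sheet["age"].to_numpy(dtype=float)
    M = beta_to_m(study.beta.to_numpy())
    cells = study.cells
    rng = np.random.default_rng(seed)
    min_p = np.empty(k)
    for i in range(k):
        perm_age = age[rng.permutation(len(age))]
        X, names = _design_matrix(perm_age, cells)
        _check_rank(X, names)
        _, _, p = _scan_matrix(M, X)
        min_p[i] = p.min()
    return PermutationNull(min_p=min_p, k=k, seed=seed)


def estimate_fwer(p_obs: np.ndarray, null: PermutationNull) -> np.ndarray:
    """Per-CpG FWER: fraction of permuted minimum p-values strictly below the
    observed p (strict inequality; values are multiples of 1/K)."""
    if null.k < 1:
        raise ValueError("empty permutation null")
    sorted_min = np.sort(null.min_p)
    counts = np.searchsorted(sorted_min, np.asarray(p_obs, dtype=float), side="left")
    return counts / null.k


def significant_set(
    ewas: pd.DataFrame, alpha_fwer: float = 0.05
) -> tuple[pd.Index, pd.Index]:
    """CpGs with FWER strictly below the threshold, split into
    (gain set, loss set)."""
    hit = ewas[ewas["fwer"] < alpha_fwer]
    gains = hit.index[hit["direction"] == "gain"]
    losses = hit.index[hit["direction"] == "loss"]
    return gains, losses


def run_ewas(
    study: MethylationStudy,
    manifest: CpgManifest,
    k: int = 300,
    seed: int = 0,
    autosomal_only: bool = True,
) -> tuple[pd.DataFrame, PermutationNull]:
    """Full discovery stage: sex-chromosome filter, scan, permutation null,
    per-CpG FWER.  Returns (results frame with ``fwer`` column, null)."""
    if autosomal_only:
        manifest, study = filter_autosomal(manifest, study)
    result = run_scan(study, manifest)
    null = permutation_null(study, manifest, k=k, seed=seed)
    result["fwer"] = estimate_fwer(result["p_obs"].to_numpy(), null)
    return result, null
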