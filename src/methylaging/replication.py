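"""Double replication of discovery CpGs in independent clustered cohorts.

Each discovery-significant CpG is refitted in a validation cohort with a
linear mixed model — fixed effects intercept + age + 5 cell fractions, one
random intercept per cluster (the twin pair in a cross-sectional twin cohort,
the individual in a longitudinal cohort) — estimated by REML with a Wald
two-sided test for the age effect.  A CpG *replicates* in a cohort when its
validation slope has the same sign as the discovery slope and the validation
p is strictly below alpha; it *double-replicates* when it replicates in both
cohorts.
"""

from __future__ import annotations

import logging
import warnings
from typing import NamedTuple

import numpy as np
import pandas as pd

from .ewas import _check_rank, _design_matrix, beta_to_m, fit_cpg_ols
from .io_formats import MethylationStudy

__all__ = [
    "LmmFit",
    "fit_cpg_lmm",
    "rate_percent",
    "cluster_labels",
    "replicate_cohort",
    "build_ledger",
    "double_replicate",
    "replication_rates",
]

logger = logging.getLogger(__name__)


class LmmFit(NamedTuple):
    slope: float
    p: float
    method: str  # "lmm" | "ols" | "cluster_ols"


def fit_cpg_lmm(m, age, cells, cluster) -> LmmFit:
    """Random-intercept mixed model for one CpG.

    Degenerates to plain OLS when every cluster holds a single sample (the
    random intercept is unidentifiable there).  On non-convergence, falls
    back to OLS on cluster means (one mean per cluster), flagged in
    ``method``.
    """
    import statsmodels.api as sm

    m = np.asarray(m, dtype=float)
    age = np.asarray(age, dtype=float)
    cluster = np.asarray(cluster)
    groups = pd.unique(cluster)
    if len(groups) < 2:
        raise ValueError("need at least 2 clusters")

    if len(groups) == len(cluster):  # all singletons: no within-cluster replication
        slope, _, p = fit_cpg_ols(m, age, cells)
        return LmmFit(slope, p, "ols")

    X, names = _design_matrix(age, cells)
    _check_rank(X, names)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(m, X, groups=cluster)
            res = model.fit(reml=True)
        if not np.isfinite(res.params[1]) or not np.isfinite(res.bse[1]):
            raise np.linalg.LinAlgError("non-finite mixed-model estimates")
        return LmmFit(float(res.params[1]), float(res.pvalues[1]), "lmm")
    except (np.linalg.LinAlgError, ValueError) as exc:
        logger.warning("mixed model failed (%s); cluster-mean OLS fallback", exc)
        agg = pd.DataFrame({"m": m, "age": age}).assign(cluster=cluster)
        cells_agg = cells.copy()
        cells_agg["cluster"] = cluster
        gm = agg.groupby("cluster").mean()
        gc = cells_agg.groupby("cluster").mean()
        slope, _, p = fit_cpg_ols(gm["m"].to_numpy(), gm["age"].to_numpy(), gc)
        return LmmFit(slope, p, "cluster_ols")


def cluster_labels(study: MethylationStudy, cluster_by: str) -> np.ndarray:
    """Grouping labels for the random intercept: ``pair`` (falling back to
    subject for unpaired samples) or ``subject``."""
    sheet = study.sheet
    if cluster_by == "subject":
        return sheet["subject_id"].to_numpy()
    if cluster_by == "pair":
        pair = sheet["pair_id"].astype(str)
        return np.where(pair != "", pair, sheet["subject_id"]).astype(str)
    raise ValueError(f"cluster_by must be 'pair' or 'subject', got {cluster_by!r}")


def replicate_cohort(
    discovery: pd.DataFrame,
    validation: MethylationStudy,
    cluster_by: str = "pair",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Refit every discovery-significant CpG in a validation cohort.

    ``discovery`` is the significant slice of the discovery scan (indexed by
    cpg_id, with ``direction``).  CpGs absent from the validation array are
    marked not testable and excluded from rate denominators.  Returns a frame
    with ``slope``, ``p``, ``method``, ``testable`` and ``replicated``
    (same direction and p strictly below alpha).
    """
    if discovery.empty:
        raise ValueError("discovery set is empty")
    cluster = cluster_labels(validation, cluster_by)
    age = validation.sheet["age"].to_numpy(dtype=float)
    cells = validation.cells
    rows = []
    present = set(validation.cpg_ids)
    for cpg, disc in discovery.iterrows():
        if cpg not in present:
            rows.append((cpg, np.nan, np.nan, "absent", False, False))
            continue
        m = beta_to_m(validation.beta[cpg].to_numpy())
        fit = fit_cpg_lmm(m, age, cells, cluster)
        same_direction = np.sign(fit.slope) == (1.0 if disc["direction"] == "gain" else -1.0)
        replicated = bool(same_direction and fit.p < alpha)
        rows.append((cpg, fit.slope, fit.p, fit.method, True, replicated))
    out = pd.DataFrame(
        rows, columns=["cpg_id", "slope", "p", "method", "testable", "replicated"]
    ).set_index("cpg_id")
    return out


def build_ledger(
    discovery: pd.DataFrame, cohort_a: pd.DataFrame, cohort_b: pd.DataFrame
) -> pd.DataFrame:
    """Merge discovery directions with both cohorts' replication outcomes.

    The subset chain (double-replicated ⊆ each replicated set ⊆ discovery
    set) is asserted on every call.
    """
    ledger = pd.DataFrame(index=discovery.index.rename("cpg_id"))
    ledger["discovery_direction"] = discovery["direction"]
    ledger["discovery_slope"] = discovery["slope"]
    for tag, rep in (("a", cohort_a), ("b", cohort_b)):
        aligned = rep.reindex(discovery.index)
        ledger[f"slope_{tag}"] = aligned["slope"]
        ledger[f"p_{tag}"] = aligned["p"]
        ledger[f"testable_{tag}"] = aligned["testable"].fillna(False).astype(bool)
        ledger[f"replicated_{tag}"] = aligned["replicated"].fillna(False).astype(bool)
    ledger["double_replicated"] = ledger["replicated_a"] & ledger["replicated_b"]
    assert ledger["double_replicated"].le(ledger["replicated_a"]).all()
    assert ledger["double_replicated"].le(ledger["replicated_b"]).all()
    return ledger


def double_replicate(ledger: pd.DataFrame) -> tuple[pd.Index, pd.Index]:
    """The double-replicated set, split by discovery direction into
    (gain set, loss set)."""
    hit = ledger[ledger["double_replicated"]]
    gains = hit.index[hit["discovery_direction"] == "gain"]
    losses = hit.index[hit["discovery_direction"] == "loss"]
    return gains, losses


def rate_percent(numerator: int, denominator: int) -> float:
    """Percentage, or NaN as the undefined marker when the denominator is 0."""
    if denominator == 0:
        return float("nan")
    return 100.0 * numerator / denominator


def replication_rates(ledger: pd.DataFrame) -> dict[str, float]:
    """Replication rate per cohort (replicated / testable discovery CpGs, in
    percent) and the overlap rate (double-replicated / the smaller cohort's
    replicated count, in percent)."""
    n_a = int(ledger["replicated_a"].sum())
    n_b = int(ledger["replicated_b"].sum())
    n_double = int(ledger["double_replicated"].sum())
    return {
        "rate_cohort_a": rate_percent(n_a, int(ledger["testable_a"].sum())),
        "rate_cohort_b": rate_percent(n_b, int(ledger["testable_b"].sum())),
        "overlap_rate": rate_percent(n_double, min(n_a, n_b)),
    }
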