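"""Contingency characterization of replicated CpGs by gene region and CGI relation.

Two families of chi-square tests, both Yates continuity-corrected with 1 df:

* *Direction bias* within a category: are gains and losses balanced among the
  replicated CpGs of a gene region (or CGI relation)?  Implemented as the
  corrected chi-square of the symmetric 2×2 table ``[[gain, loss], [loss,
  gain]]``, which has the closed form ``8 * (max(|gain - n/2| - 1/2, 0))^2 / n``.
* *Proportionality* against the whole-array background: is a category over- or
  under-represented among gains (or losses) relative to its share of all CpGs
  on the array?  A two-sample 2×2 test of (category count, rest) in the group
  versus the array.

Gene-region membership is multi-label — a CpG contributes one count to every
region label it carries — while the CGI relation partitions the set.  For the
region × CGI cross-tabulation the six CGI relations collapse to three groups:
CGI (Island), Shore/Shelf, and non-CGI.
"""

from __future__ import annotations

from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CGI_LABELS, GENE_REGION_LABELS, CpgManifest

__all__ = [
    "direction_bias_chisq",
    "proportionality_test",
    "tabulate_by_region",
    "tabulate_by_cgi",
    "crosstab_region_by_cgi",
    "gain_share_summary",
    "set_overlap",
    "CGI_GROUPS",
]

#: Collapse of the six CGI relations used by the region × CGI cross-tab.
CGI_GROUPS: dict[str, str] = {
    "Island": "CGI",
    "N_Shore": "Shore/Shelf",
    "S_Shore": "Shore/Shelf",
    "N_Shelf": "Shore/Shelf",
    "S_Shelf": "Shore/Shelf",
    "non-CGI": "non-CGI",
}
CGI_GROUP_ORDER = ("non-CGI", "Shore/Shelf", "CGI")


class Chi2Result(NamedTuple):
    chisq: float
    p: float


class ProportionalityResult(NamedTuple):
    chisq: float
    p: float
    reliable: bool  # False when some expected cell < 1


def direction_bias_chisq(k_gain: int, k_loss: int) -> Chi2Result:
    """Yates-corrected chi-square for gain/loss balance.

    Equals the corrected chi-square of ``[[gain, loss], [loss, gain]]``;
    closed form ``8 * (max(|gain - n/2| - 0.5, 0))^2 / n``.  Symmetric in
    (gain, loss); zero at perfect balance.
    """
    n = k_gain + k_loss
    if n < 1:
        raise ValueError("need at least one CpG")
    dev = max(abs(k_gain - n / 2.0) - 0.5, 0.0)
    chisq = 8.0 * dev * dev / n
    return Chi2Result(chisq, float(stats.chi2.sf(chisq, df=1)))


def proportionality_test(
    k_group: int, n_group: int, k_array: int, n_array: int
) -> ProportionalityResult:
    """Two-sample Yates chi-square of a category's share in a CpG group versus
    the whole-array background."""
    if n_group < 1 or n_array < 1:
        raise ValueError("group and array totals must be >= 1")
    table = np.array(
        [[k_group, n_group - k_group], [k_array, n_array - k_array]], dtype=float
    )
    if (table < 0).any():
        raise ValueError("category count exceeds its total")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return ProportionalityResult(0.0, 1.0, False)
    res = stats.chi2_contingency(table, correction=True)
    reliable = bool((res.expected_freq >= 1.0).all())
    return ProportionalityResult(float(res.statistic), float(res.pvalue), reliable)


def _direction_counts(
    categories: Mapping[str, Iterable[str]] | pd.Series,
    directions: pd.Series,
    labels: tuple[str, ...],
    multi_label: bool,
) -> pd.DataFrame:
    counts = pd.DataFrame(0, index=pd.Index(labels, name="category"), columns=["k_gain", "k_loss"])
    col = {"gain": "k_gain", "loss": "k_loss"}
    for cpg, direction in directions.items():
        cats = categories[cpg] if multi_label else [categories[cpg]]
        for cat in cats:
            counts.loc[cat, col[direction]] += 1
    counts["n"] = counts["k_gain"] + counts["k_loss"]
    chisq, pval = [], []
    for _, row in counts.iterrows():
        if row["n"] == 0:
            chisq.append(np.nan)
            pval.append(np.nan)
        else:
            c = direction_bias_chisq(int(row["k_gain"]), int(row["k_loss"]))
            chisq.append(c.chisq)
            pval.append(c.p)
    counts["chisq"] = chisq
    counts["p"] = pval
    return counts[["n", "k_gain", "k_loss", "chisq", "p"]]


def _proportionality_rows(
    counts: pd.DataFrame, array_counts: pd.Series, n_array: int
) -> pd.DataFrame:
    rows = []
    for direction, col in (("gain", "k_gain"), ("loss", "k_loss")):
        total = int(counts[col].sum())
        for cat in counts.index:
            k = int(counts.loc[cat, col])
            k_arr = int(array_counts[cat])
            if total == 0:
                rows.append((cat, direction, np.nan, k_arr / n_array, np.nan, np.nan, False))
                continue
            res = proportionality_test(k, total, k_arr, n_array)
            rows.append(
                (cat, direction, k / total, k_arr / n_array, res.chisq, res.p, res.reliable)
            )
    return pd.DataFrame(
        rows,
        columns=["category", "direction", "p_group", "p_array", "chisq", "p", "reliable"],
    )


def _validated_directions(directions: pd.Series, manifest: CpgManifest) -> pd.Series:
    missing = directions.index.difference(manifest.cpg_ids)
    if len(missing):
        raise KeyError(f"CpG(s) absent from manifest: {list(missing[:5])}")
    bad = ~directions.isin(["gain", "loss"])
    if bad.any():
        raise ValueError(f"directions must be 'gain' or 'loss'; got {directions[bad].iloc[0]!r}")
    return directions


def tabulate_by_region(
    directions: pd.Series, manifest: CpgManifest
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gain/loss counts and direction-bias tests per gene region, plus
    proportionality rows against the whole-array region composition.

    ``directions`` maps cpg_id -> 'gain' | 'loss' (the double-replicated set
    with discovery directions).  Multi-label: a CpG counts in every region it
    carries, so column sums can exceed the set size.
    """
    directions = _validated_directions(directions, manifest)
    counts = _direction_counts(
        manifest.table["gene_regions"], directions, GENE_REGION_LABELS, multi_label=True
    )
    prop = _proportionality_rows(counts, manifest.region_counts(), len(manifest))
    return counts, prop


def tabulate_by_cgi(
    directions: pd.Series, manifest: CpgManifest
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """As :func:`tabulate_by_region`, but over the single-label CGI relation —
    per-relation totals partition the input set."""
    directions = _validated_directions(directions, manifest)
    counts = _direction_counts(
        manifest.table["cgi_relation"], directions, CGI_LABELS, multi_label=False
    )
    prop = _proportionality_rows(counts, manifest.cgi_counts(), len(manifest))
    return counts, prop


def crosstab_region_by_cgi(directions: pd.Series, manifest: CpgManifest) -> pd.DataFrame:
    """Gain/loss counts per (gene region × collapsed CGI group) cell.

    Returns one row per (region, cgi_group) with ``k_gain``, ``k_loss``,
    ``gain_prop`` (gain / (gain + loss), NaN for empty cells) and the
    direction-bias p.  Marginalising a region's cells over the three CGI
    groups reproduces that region's row in :func:`tabulate_by_region`.
    """
    directions = _validated_directions(directions, manifest)
    regions = manifest.table["gene_regions"]
    cgi = manifest.table["cgi_relation"]
    index = pd.MultiIndex.from_product(
        [GENE_REGION_LABELS, CGI_GROUP_ORDER], names=["region", "cgi_group"]
    )
    counts = pd.DataFrame(0, index=index, columns=["k_gain", "k_loss"])
    col = {"gain": "k_gain", "loss": "k_loss"}
    for cpg, direction in directions.items():
        group = CGI_GROUPS[cgi[cpg]]
        for region in regions[cpg]:
            counts.loc[(region, group), col[direction]] += 1
    n = counts["k_gain"] + counts["k_loss"]
    out = counts.copy()
    out["n"] = n
    with np.errstate(invalid="ignore"):
        out["gain_prop"] = np.where(n > 0, counts["k_gain"] / n.replace(0, np.nan), np.nan)
    pvals = []
    for (g, l) in counts.itertuples(index=False):
        pvals.append(direction_bias_chisq(g, l).p if g + l > 0 else np.nan)
    out["p"] = pvals
    return out[["n", "k_gain", "k_loss", "gain_prop", "p"]]


def gain_share_summary(
    counts: pd.DataFrame, totals: tuple[int, int] | None = None
) -> pd.DataFrame:
    """Per category: its share of all gains and of all losses, in percent.

    ``share_gain(cat) = 100 * k_gain(cat) / total gains`` (NaN when there are
    no gains at all; likewise for losses).  ``totals`` supplies the
    (total gains, total losses) of the underlying CpG set; it must be given
    for multi-label category tables, whose column sums overcount CpGs
    carrying several labels.  When omitted, the column sums are used (valid
    for single-label partitions such as the CGI relation).
    """
    if totals is None:
        total_gain = int(counts["k_gain"].sum())
        total_loss = int(counts["k_loss"].sum())
    else:
        total_gain, total_loss = totals
    share_gain = (
        100.0 * counts["k_gain"] / total_gain if total_gain > 0 else np.full(len(counts), np.nan)
    )
    share_loss = (
        100.0 * counts["k_loss"] / total_loss if total_loss > 0 else np.full(len(counts), np.nan)
    )
    return pd.DataFrame(
        {"share_gain_pct": share_gain, "share_loss_pct": share_loss}, index=counts.index
    )


class OverlapResult(NamedTuple):
    n_list: int
    n_overlap: int
    pct: float


def set_overlap(reference_cpgs: Iterable[str], replicated_cpgs: Iterable[str]) -> OverlapResult:
    """Overlap of a reference CpG list (e.g. an epigenetic-clock panel) with a
    replicated set: count and percentage of the reference list covered."""
    ref = set(reference_cpgs)
    if not ref:
        raise ValueError("reference list is empty")
    k = len(ref & set(replicated_cpgs))
    return OverlapResult(len(ref), k, 100.0 * k / len(ref))
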