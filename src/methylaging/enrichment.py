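"""Hypergeometric over-representation analysis of nearest genes.

Significant CpGs are mapped to their distinct nearest genes and each gene set
is tested for over-representation against the gene universe of the array::

    p(X > k) = 1 - sum_{r=0}^{k} C(m, r) * C(N - m, n - r) / C(N, n)

where N is the number of genes annotated to CpGs on the array, m the number
of genes annotated to the significant CpGs, n the number of genes in the set
(after intersection with the universe) and k the overlap.  The default tail
is the strictly-greater one, ``P(X > k)``, exactly as written above; the more
common ``P(X >= k)`` convention is available via ``tail="ge"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .io_formats import CpgManifest, GeneSetCollection

__all__ = ["cpgs_to_genes", "hypergeom_upper", "run_enrichment", "EnrichmentResult"]

logger = logging.getLogger(__name__)


def cpgs_to_genes(cpgs, manifest: CpgManifest) -> frozenset[str]:
    """Distinct non-empty nearest-gene symbols of the given CpGs."""
    cpgs = pd.Index(cpgs)
    missing = cpgs.difference(manifest.cpg_ids)
    if len(missing):
        raise KeyError(f"CpG(s) absent from manifest: {list(missing[:5])}")
    genes = manifest.table["nearest_gene"].reindex(cpgs)
    return frozenset(g for g in genes if g)


def _check_counts(N: int, m: int, n: int, k: int) -> None:
    if not (0 <= m <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= m, n <= N; got N={N}, m={m}, n={n}")
    if not 0 <= k <= min(m, n):
        raise ValueError(f"need 0 <= k <= min(m, n); got k={k}, m={m}, n={n}")


def hypergeom_upper(N: int, m: int, n: int, k: int, tail: str = "gt") -> float:
    """Upper-tail hypergeometric probability of the overlap.

    ``tail="gt"`` gives P(X > k) (the default); ``tail="ge"`` gives P(X >= k).
    X counts the overlap when n genes are drawn without replacement from a
    universe of N containing m marked genes.
    """
    _check_counts(N, m, n, k)
    dist = stats.hypergeom(N, m, n)
    if tail == "gt":
        return float(dist.sf(k))
    if tail == "ge":
        return float(dist.sf(k - 1))
    raise ValueError(f"tail must be 'gt' or 'ge', got {tail!r}")


@dataclass(frozen=True)
class EnrichmentResult:
    """One gene set's over-representation counts and p-value."""

    set_name: str
    N: int
    m: int
    n: int
    k: int
    p_hyper: float

    def __post_init__(self) -> None:
        _check_counts(self.N, self.m, self.n, self.k)
        if not 0.0 <= self.p_hyper <= 1.0:
            raise ValueError("p_hyper outside [0, 1]")


def run_enrichment(
    gene_list,
    universe,
    collection: GeneSetCollection,
    tail: str = "gt",
    top: int | None = None,
) -> pd.DataFrame:
    """Test every set in the collection for over-representation of the gene list.

    Genes outside the universe are dropped from the list (with a logged
    count); each set is intersected with the universe before its size n is
    computed.  Rows are sorted by ascending p, ties broken by larger overlap
    k then set name, and optionally truncated to the top sets.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty gene universe")
    gene_list = set(gene_list)
    outside = gene_list - universe
    if outside:
        logger.warning("dropping %d gene(s) outside the universe", len(outside))
        gene_list -= outside
    N, m = len(universe), len(gene_list)
    rows = []
    for name in collection.names():
        members = collection.genes(name) & universe
        n = len(members)
        k = len(members & gene_list)
        p = hypergeom_upper(N, m, n, k, tail=tail)
        rows.append(EnrichmentResult(name, N, m, n, k, p))
    out = pd.DataFrame(
        [(r.set_name, r.N, r.m, r.n, r.k, r.p_hyper) for r in rows],
        columns=["set_name", "N", "m", "n", "k", "p_hyper"],
    )
    out = out.sort_values(
        by=["p_hyper", "k", "set_name"], ascending=[True, False, True], kind="mergesort"
    ).reset_index(drop=True)
    if top is not None:
        out = out.head(top)
    return out
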