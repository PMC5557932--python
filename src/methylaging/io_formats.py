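"""Readers, writers and validated containers for the pipeline's on-disk artifacts.

Four artifact kinds are handled, all plain text:

* CpG annotation manifest (TSV) — per-CpG genomic annotation in the style of the
  Illumina 450K manifest: chromosome, position, a multi-label gene-region
  assignment (semicolon-separated, mirroring the ``UCSC_RefGene_Group``
  convention) and a single-label relation to the nearest CpG island.
* Methylation study — a β-value matrix (TSV, samples × CpGs) together with a
  sample sheet (CSV) and a 6-part blood cell-composition table (CSV), all keyed
  by ``sample_id``.
* Gene-set collections in standard GMT.

Every type invariant is enforced at read/construction time so that downstream
stages never see malformed data.  Open sea is spelled ``non-CGI`` everywhere;
the Illumina dialect ``OpenSea`` is rejected rather than silently mapped so
that outputs stay bit-comparable across runs.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

#: Gene-region labels, in the display order used by all output tables.
GENE_REGION_LABELS: tuple[str, ...] = (
    "Intergenic", "TSS1500", "TSS200", "5'UTR", "1stExon", "Body", "3'UTR",
)

#: Relation-to-CpG-island labels (single membership).
CGI_LABELS: tuple[str, ...] = (
    "non-CGI", "N_Shelf", "N_Shore", "Island", "S_Shore", "S_Shelf",
)

#: The six blood cell types of the reference-based deconvolution.
CELL_TYPES: tuple[str, ...] = ("CD8T", "CD4T", "NK", "Bcell", "Mono", "Gran")

CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")
SEX_CHROMOSOMES: frozenset[str] = frozenset({"X", "Y"})

ZYGOSITY_LABELS: tuple[str, ...] = ("MZ", "DZ", "NA")
SEX_LABELS: tuple[str, ...] = ("F", "M", "NA")

_CELL_SUM_TOL = 1e-6

MANIFEST_COLUMNS = ("CpG_ID", "CHR", "POS", "GENE_REGIONS", "CGI_RELATION", "NEAREST_GENE")


class FormatError(ValueError):
    """A file or in-memory artifact violates one of the format invariants."""


@dataclass(frozen=True)
class CpgManifest:
    """Per-CpG genomic annotation.

    ``table`` is indexed by ``cpg_id`` with columns ``chromosome`` (str),
    ``position`` (int, 1-based point coordinate), ``gene_regions``
    (frozenset of labels from :data:`GENE_REGION_LABELS`), ``cgi_relation``
    (one label from :data:`CGI_LABELS`) and ``nearest_gene`` (str, may be
    empty for intergenic probes).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            dup = t.index[t.index.duplicated()][0]
            raise FormatError(f"duplicate cpg_id {dup!r}")
        for cpg, regions in t["gene_regions"].items():
            if not regions:
                raise FormatError(f"empty gene_regions for {cpg!r}")
            bad = set(regions) - set(GENE_REGION_LABELS)
            if bad:
                raise FormatError(f"unknown gene-region label(s) {sorted(bad)} for {cpg!r}")
        bad_cgi = ~t["cgi_relation"].isin(CGI_LABELS)
        if bad_cgi.any():
            cpg = t.index[bad_cgi][0]
            raise FormatError(
                f"unknown CGI label {t.loc[cpg, 'cgi_relation']!r} for {cpg!r} "
                f"(open sea must be spelled 'non-CGI')"
            )
        bad_chr = ~t["chromosome"].isin(CHROMOSOMES)
        if bad_chr.any():
            cpg = t.index[bad_chr][0]
            raise FormatError(f"unknown chromosome {t.loc[cpg, 'chromosome']!r} for {cpg!r}")
        if (t["position"] < 1).any():
            raise FormatError("positions must be >= 1 (1-based coordinates)")

    @property
    def cpg_ids(self) -> pd.Index:
        return self.table.index

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, cpg_ids) -> "CpgManifest":
        """Restrict to the given CpGs, preserving their order in ``cpg_ids``."""
        missing = pd.Index(cpg_ids).difference(self.table.index)
        if len(missing):
            raise KeyError(f"CpG(s) absent from manifest: {list(missing[:5])}")
        return CpgManifest(self.table.loc[list(cpg_ids)])

    def region_counts(self) -> pd.Series:
        """Number of CpGs carrying each gene-region label (multi-label: a CpG
        counts once in every label it carries)."""
        counts = {lab: 0 for lab in GENE_REGION_LABELS}
        for regions in self.table["gene_regions"]:
            for lab in regions:
                counts[lab] += 1
        return pd.Series(counts, name="n_cpgs")

    def cgi_counts(self) -> pd.Series:
        """Number of CpGs per relation-to-CGI label (single-label partition)."""
        return (
            self.table["cgi_relation"].value_counts().reindex(CGI_LABELS, fill_value=0)
        ).rename("n_cpgs")


def read_manifest(path: str | Path) -> CpgManifest:
    """Read a manifest TSV (columns ``CpG_ID CHR POS GENE_REGIONS CGI_RELATION
    NEAREST_GENE``; gene regions semicolon-separated)."""
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(MANIFEST_COLUMNS) - set(raw.columns)
    if missing:
        raise FormatError(f"manifest {path}: missing column(s) {sorted(missing)}")
    regions = [
        frozenset(lab for lab in cell.split(";") if lab)
        for cell in raw["GENE_REGIONS"]
    ]
    table = pd.DataFrame(
        {
            "chromosome": raw["CHR"].values,
            "position": pd.to_numeric(raw["POS"]).astype(int).values,
            "gene_regions": regions,
            "cgi_relation": raw["CGI_RELATION"].values,
            "nearest_gene": raw["NEAREST_GENE"].values,
        },
        index=pd.Index(raw["CpG_ID"], name="cpg_id"),
    )
    return CpgManifest(table)


def write_manifest(manifest: CpgManifest, path: str | Path) -> None:
    t = manifest.table
    out = pd.DataFrame(
        {
            "CpG_ID": t.index,
            "CHR": t["chromosome"].values,
            "POS": t["position"].values,
            "GENE_REGIONS": [
                ";".join(sorted(r, key=GENE_REGION_LABELS.index))
                for r in t["gene_regions"]
            ],
            "CGI_RELATION": t["cgi_relation"].values,
            "NEAREST_GENE": t["nearest_gene"].values,
        }
    )
    out.to_csv(path, sep="\t", index=False)


SHEET_COLUMNS = ("subject_id", "pair_id", "zygosity", "age", "sex", "cohort", "wave")


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample sheet (index ``sample_id``) and normalise dtypes."""
    if sheet.index.has_duplicates:
        dup = sheet.index[sheet.index.duplicated()][0]
        raise FormatError(f"duplicate sample_id {dup!r}")
    missing = set(SHEET_COLUMNS) - set(sheet.columns)
    if missing:
        raise FormatError(f"sample sheet missing column(s) {sorted(missing)}")
    sheet = sheet.copy()
    sheet["age"] = pd.to_numeric(sheet["age"])
    sheet["wave"] = pd.to_numeric(sheet["wave"]).astype(int)
    if (sheet["age"] <= 0).any():
        bad = sheet.index[sheet["age"] <= 0][0]
        raise FormatError(f"non-positive age for sample {bad!r}")
    if (sheet["wave"] < 1).any():
        raise FormatError("wave must be >= 1")
    if not sheet["zygosity"].isin(ZYGOSITY_LABELS).all():
        raise FormatError(f"zygosity must be one of {ZYGOSITY_LABELS}")
    if not sheet["sex"].isin(SEX_LABELS).all():
        raise FormatError(f"sex must be one of {SEX_LABELS}")
    sw = sheet[["subject_id", "wave"]]
    if sw.duplicated().any():
        pair = tuple(sw[sw.duplicated()].iloc[0])
        raise FormatError(f"duplicate (subject_id, wave) {pair}")
    return sheet


@dataclass(frozen=True)
class MethylationStudy:
    """One cohort: β matrix (samples × CpGs), sample sheet and cell fractions.

    All three tables are indexed by ``sample_id`` in identical order.  β-values
    lie in [0, 1]; each cell-composition row is a non-negative 6-vector over
    :data:`CELL_TYPES` summing to 1.
    """

    beta: pd.DataFrame
    sheet: pd.DataFrame
    cells: pd.DataFrame

    def __post_init__(self) -> None:
        object.__setattr__(self, "sheet", validate_sample_sheet(self.sheet))
        if not (self.beta.index.equals(self.sheet.index) and self.beta.index.equals(self.cells.index)):
            raise FormatError("beta, sheet and cells must share an identical sample_id index")
        vals = self.beta.to_numpy()
        bad = (vals < 0) | (vals > 1) | ~np.isfinite(vals)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"beta out of [0,1] at sample {self.beta.index[i]!r}, "
                f"CpG {self.beta.columns[j]!r}: {vals[i, j]}"
            )
        missing = set(CELL_TYPES) - set(self.cells.columns)
        if missing:
            raise FormatError(f"cell table missing column(s) {sorted(missing)}")
        cells = self.cells[list(CELL_TYPES)].astype(float)
        object.__setattr__(self, "cells", cells)
        if (cells.to_numpy() < 0).any():
            raise FormatError("cell fractions must be non-negative")
        sums = cells.sum(axis=1)
        off = (sums - 1.0).abs() > _CELL_SUM_TOL
        if off.any():
            bad_id = sums.index[off][0]
            raise FormatError(
                f"cell fractions for sample {bad_id!r} sum to {sums[bad_id]:.6f}, not 1"
            )

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def cpg_ids(self) -> pd.Index:
        return self.beta.columns

    @property
    def n_samples(self) -> int:
        return len(self.beta)

    def subset_cpgs(self, cpg_ids) -> "MethylationStudy":
        return MethylationStudy(self.beta[list(cpg_ids)], self.sheet, self.cells)


def read_study(
    beta_path: str | Path, sheet_path: str | Path, cells_path: str | Path
) -> MethylationStudy:
    """Assemble a :class:`MethylationStudy` from its three files, aligning the
    sheet and cell tables to the β matrix's sample order."""
    beta = pd.read_csv(beta_path, sep="\t", index_col=0)
    beta.index = beta.index.astype(str)
    beta.index.name = "sample_id"
    sheet = pd.read_csv(sheet_path, index_col=0, dtype={"wave": int}, keep_default_na=False)
    sheet.index = sheet.index.astype(str)
    cells = pd.read_csv(cells_path, index_col=0)
    cells.index = cells.index.astype(str)
    for name, table in (("sample sheet", sheet), ("cell table", cells)):
        absent = beta.index.difference(table.index)
        if len(absent):
            raise FormatError(
                f"sample(s) present in beta matrix but missing from {name}: "
                f"{list(absent[:5])}"
            )
    return MethylationStudy(beta, sheet.loc[beta.index], cells.loc[beta.index])


def write_study(
    study: MethylationStudy,
    beta_path: str | Path,
    sheet_path: str | Path,
    cells_path: str | Path,
) -> None:
    study.beta.to_csv(beta_path, sep="\t", index_label="sample_id")
    study.sheet.to_csv(sheet_path, index_label="sample_id")
    study.cells.to_csv(cells_path, index_label="sample_id")


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets: ``sets`` maps set name -> (description, frozenset of symbols)."""

    sets: Mapping[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for name, (_, genes) in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def genes(self, name: str) -> frozenset[str]:
        return self.sets[name][1]


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a standard GMT file (name TAB description TAB gene TAB gene ...)."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >= 3 tab-separated fields")
            name, desc, *genes = fields
            if name in sets:
                raise FormatError(f"{path}: line {lineno}: duplicate gene set name {name!r}")
            symbols = frozenset(g for g in genes if g)
            if not symbols:
                raise FormatError(f"{path}: line {lineno}: gene set {name!r} has no genes")
            sets[name] = (desc, symbols)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, (desc, genes) in collection.sets.items():
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")
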