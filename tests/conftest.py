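import numpy as np
import pandas as pd
import pytest

from methylaging.io_formats import CELL_TYPES, CpgManifest, MethylationStudy


def make_manifest(rows):
    """rows: list of (cpg_id, chrom, pos, regions, cgi, gene)."""
    table = pd.DataFrame(
        {
            "chromosome": [r[1] for r in rows],
            "position": [r[2] for r in rows],
            "gene_regions": [frozenset(r[3]) for r in rows],
            "cgi_relation": [r[4] for r in rows],
            "nearest_gene": [r[5] for r in rows],
        },
        index=pd.Index([r[0] for r in rows], name="cpg_id"),
    )
    return CpgManifest(table)


@pytest.fixture
def manifest10():
    """10 CpGs, 2 on X and 1 on Y, mixed annotation."""
    return make_manifest(
        [
            ("cg001", "1", 1000, {"TSS200", "1stExon"}, "Island", "GENE1"),
            ("cg002", "2", 2000, {"Body"}, "non-CGI", "GENE1"),
            ("cg003", "3", 3000, {"Intergenic"}, "N_Shore", ""),
            ("cg004", "4", 4000, {"TSS1500"}, "S_Shore", "GENE2"),
            ("cg005", "5", 5000, {"5'UTR", "Body"}, "N_Shelf", "GENE3"),
            ("cg006", "6", 6000, {"3'UTR"}, "S_Shelf", "GENE4"),
            ("cg007", "7", 7000, {"Body"}, "Island", "GENE5"),
            ("cg008", "X", 8000, {"TSS200"}, "Island", "GENE6"),
            ("cg009", "X", 9000, {"Body"}, "non-CGI", "GENE7"),
            ("cg010", "Y", 10000, {"Intergenic"}, "non-CGI", ""),
        ]
    )


def make_study(beta, ages, subjects=None, pairs=None, waves=None, cohort="test"):
    """Assemble a valid study around a (samples x CpGs) beta DataFrame."""
    n = len(beta)
    rng = np.random.default_rng(0)
    cells = rng.dirichlet((4, 8, 2.5, 2.5, 3.5, 30), size=n)
    sheet = pd.DataFrame(
        {
            "subject_id": subjects if subjects is not None else [f"S{i}" for i in range(n)],
            "pair_id": pairs if pairs is not None else [""] * n,
            "zygosity": ["NA"] * n,
            "age": ages,
            "sex": ["F"] * n,
            "cohort": [cohort] * n,
            "wave": waves if waves is not None else [1] * n,
        },
        index=beta.index,
    )
    cells_df = pd.DataFrame(cells, index=beta.index, columns=list(CELL_TYPES))
    return MethylationStudy(beta, sheet, cells_df)


@pytest.fixture
def make_study_fn():
    return make_study
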