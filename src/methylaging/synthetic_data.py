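"""Synthetic 450K-like cohorts with planted age effects.

The generator emulates the statistical structure the downstream analysis
assumes, so that every stage — discovery scan, permutation FWER, mixed-model
replication, contingency characterization, pathway over-representation — can
be exercised end-to-end without access to any real array data.

Generative model (per CpG *j*, sample *i* of subject *s*)::

    M_ij = mu_j(cgi) + b_j * age_i + sum_c gamma_jc * cellfrac_ic + u_js + eps_ij
    beta_ij = 2**M_ij / (2**M_ij + 1)          # inverse of the M transform

with subject random intercepts ``u ~ N(0, subject_sd^2)``, residual noise
``eps ~ N(0, noise_sd^2)``, per-CpG cell-type effects
``gamma ~ N(0, cell_effect_sd^2)`` and cell fractions drawn from a Dirichlet
whose mean mimics whole blood (granulocyte-dominated).  A fraction of CpGs
carries a true age slope ``b_j`` (in M-units per year); the rest are null.
The direction mix defaults to demethylation-dominant (61 % negative slopes
among affected CpGs), matching the direction imbalance the analysis is
designed to detect.

Randomness is organised as counter-based substreams of a single global seed:
every CpG owns its own stream, so enlarging ``n_cpgs`` never perturbs the
values generated for earlier CpGs, and the planted truth is shared across
cohorts simulated from the same seed (which is what makes replication of the
same planted CpGs possible).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    CELL_TYPES,
    CGI_LABELS,
    CHROMOSOMES,
    GENE_REGION_LABELS,
    CpgManifest,
    GeneSetCollection,
    MethylationStudy,
)

__all__ = [
    "SimulationConfig",
    "CohortDesign",
    "TruthTable",
    "simulate_manifest",
    "simulate_cohort",
    "simulate_gene_sets",
    "presets",
]

# Whole-array inclusion probabilities for the six genic labels; CpGs drawing
# no genic label fall back to Intergenic alone, so the Intergenic entry is a
# fallback marker and is never sampled directly.
DEFAULT_REGION_PROBS: dict[str, float] = {
    "Intergenic": 0.0,
    "TSS1500": 0.17,
    "TSS200": 0.13,
    "5'UTR": 0.14,
    "1stExon": 0.08,
    "Body": 0.36,
    "3'UTR": 0.04,
}

# Whole-array relation-to-CGI composition (categorical, sums to 1).
DEFAULT_CGI_PROBS: dict[str, float] = {
    "non-CGI": 0.36,
    "N_Shelf": 0.05,
    "N_Shore": 0.13,
    "Island": 0.31,
    "S_Shore": 0.10,
    "S_Shelf": 0.05,
}

# Baseline M-value by CGI relation: islands hypomethylated, open sea
# hypermethylated, shores/shelves intermediate.
DEFAULT_BASELINE_M: dict[str, float] = {
    "Island": -2.0,
    "N_Shore": -0.5,
    "S_Shore": -0.5,
    "N_Shelf": 1.5,
    "S_Shelf": 1.5,
    "non-CGI": 2.0,
}

# Dirichlet concentration over (CD8T, CD4T, NK, Bcell, Mono, Gran): mean
# composition ~ (0.08, 0.16, 0.05, 0.05, 0.07, 0.59), granulocyte-dominated
# as in whole blood.
DEFAULT_CELL_CONCENTRATION: tuple[float, ...] = (4.0, 8.0, 2.5, 2.5, 3.5, 30.0)

# Substream tags (see module docstring).
_S_TRUTH = 0
_S_EFFECTS = 1
_S_MANIFEST = 2
_S_SUBJECTS = 3
_S_NOISE = 4
_S_GENESETS = 5


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic substream of the global seed, addressed by integer key."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _cohort_tag(cohort: str) -> int:
    return zlib.crc32(cohort.encode("utf-8"))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the generative model; see module docstring for the model.

    Slopes are in M-units per year; ``slope_mean``/``slope_sd`` parameterise
    the magnitude of planted slopes (the sign is assigned separately by
    ``frac_demethylated_among_affected``).
    """

    n_cpgs: int = 2000
    region_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REGION_PROBS)
    )
    cgi_probs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CGI_PROBS))
    frac_affected: float = 0.10
    frac_demethylated_among_affected: float = 0.61
    slope_mean: float = 0.01
    slope_sd: float = 0.005
    baseline_m_by_cgi: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_M)
    )
    subject_sd: float = 0.15
    noise_sd: float = 0.15
    cell_concentration: tuple[float, ...] = DEFAULT_CELL_CONCENTRATION
    cell_effect_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cpgs <= 0:
            raise ValueError("n_cpgs must be positive")
        for name, probs in (("region_probs", self.region_probs), ("cgi_probs", self.cgi_probs)):
            for lab, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{name}[{lab!r}] = {p} outside [0, 1]")
        unknown = set(self.region_probs) - set(GENE_REGION_LABELS)
        if unknown:
            raise ValueError(f"unknown gene-region label(s) in region_probs: {sorted(unknown)}")
        unknown = set(self.cgi_probs) - set(CGI_LABELS)
        if unknown:
            raise ValueError(f"unknown CGI label(s) in cgi_probs: {sorted(unknown)}")
        if abs(sum(self.cgi_probs.values()) - 1.0) > 1e-9:
            raise ValueError("cgi_probs must sum to 1")
        for name in ("frac_affected", "frac_demethylated_among_affected"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")
        for name in ("slope_sd", "subject_sd", "noise_sd", "cell_effect_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if len(self.cell_concentration) != len(CELL_TYPES):
            raise ValueError(f"cell_concentration must have {len(CELL_TYPES)} entries")
        if any(a <= 0 for a in self.cell_concentration):
            raise ValueError("cell_concentration entries must be positive")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class TruthTable:
    """Planted ground truth: per-CpG true slope (M-units/year) and direction.

    ``direction`` is ``gain`` for positive slopes, ``loss`` for negative and
    ``null`` exactly when the slope is zero.
    """

    table: pd.DataFrame  # index cpg_id; columns true_slope, direction

    def __post_init__(self) -> None:
        slopes = self.table["true_slope"]
        expected = np.where(slopes > 0, "gain", np.where(slopes < 0, "loss", "null"))
        if not (self.table["direction"].to_numpy() == expected).all():
            raise ValueError("direction inconsistent with sign(true_slope)")

    @property
    def affected(self) -> pd.Index:
        return self.table.index[self.table["direction"] != "null"]


def _true_slope(config: SimulationConfig, j: int) -> float:
    rng = _rng(config.seed, _S_TRUTH, j)
    if rng.random() >= config.frac_affected:
        return 0.0
    sign = -1.0 if rng.random() < config.frac_demethylated_among_affected else 1.0
    magnitude = abs(rng.normal(config.slope_mean, config.slope_sd))
    if magnitude == 0.0:  # degenerate draw; keep the CpG affected
        magnitude = config.slope_mean or np.finfo(float).tiny
    return sign * magnitude


def make_truth(config: SimulationConfig) -> TruthTable:
    """The planted truth is a function of the config alone (shared by every
    cohort simulated from the same seed)."""
    slopes = np.array([_true_slope(config, j) for j in range(config.n_cpgs)])
    direction = np.where(slopes > 0, "gain", np.where(slopes < 0, "loss", "null"))
    table = pd.DataFrame(
        {"true_slope": slopes, "direction": direction},
        index=pd.Index([_cpg_id(j) for j in range(config.n_cpgs)], name="cpg_id"),
    )
    return TruthTable(table)


def _cpg_id(j: int) -> str:
    return f"cg{j:07d}"


def simulate_manifest(config: SimulationConfig) -> CpgManifest:
    """Draw a synthetic annotation manifest.

    Genic region labels are included independently per label with their
    ``region_probs``; CpGs drawing no genic label are assigned Intergenic
    alone.  The CGI relation is categorical with ``cgi_probs``.  Chromosomes
    rotate round-robin over 1..22, X, Y and genes come from a shared synthetic
    symbol pool so several CpGs can map to the same gene.
    """
    genic = [lab for lab in GENE_REGION_LABELS if lab != "Intergenic"]
    genic_p = np.array([config.region_probs.get(lab, 0.0) for lab in genic])
    cgi_labels = list(config.cgi_probs)
    cgi_p = np.array([config.cgi_probs[lab] for lab in cgi_labels])
    n_genes = max(50, config.n_cpgs // 20)

    rows = []
    for j in range(config.n_cpgs):
        rng = _rng(config.seed, _S_MANIFEST, j)
        include = rng.random(len(genic)) < genic_p
        regions = frozenset(lab for lab, inc in zip(genic, include) if inc)
        if not regions:
            regions = frozenset({"Intergenic"})
        cgi = cgi_labels[rng.choice(len(cgi_labels), p=cgi_p / cgi_p.sum())]
        position = 1 + j // len(CHROMOSOMES) * 500 + int(rng.integers(0, 500))
        gene = "" if regions == {"Intergenic"} else f"GENE{int(rng.integers(0, n_genes)):05d}"
        rows.append(
            {
                "chromosome": CHROMOSOMES[j % len(CHROMOSOMES)],
                "position": position,
                "gene_regions": regions,
                "cgi_relation": cgi,
                "nearest_gene": gene,
            }
        )
    table = pd.DataFrame(rows, index=pd.Index([_cpg_id(j) for j in range(config.n_cpgs)], name="cpg_id"))
    return CpgManifest(table)


@dataclass(frozen=True)
class CohortDesign:
    """Sampling design of one cohort.

    ``age_ranges`` lists (low, high) intervals; subjects (or twin pairs — the
    members of a pair share one age) are split evenly across the intervals
    with baseline ages drawn uniformly inside each.  ``waves`` repeated
    measures are taken ``wave_gap`` years apart, reusing the subject's random
    intercept.  ``twin_structure`` is ``none``, ``MZ_pairs`` or
    ``mixed_MZ_DZ``.
    """

    name: str
    n_subjects: int
    age_ranges: Sequence[tuple[float, float]]
    waves: int = 1
    wave_gap: float = 10.0
    twin_structure: str = "none"

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if self.waves < 1:
            raise ValueError("waves must be >= 1")
        if self.twin_structure not in {"none", "MZ_pairs", "mixed_MZ_DZ"}:
            raise ValueError(f"unknown twin_structure {self.twin_structure!r}")
        if self.twin_structure != "none" and self.n_subjects % 2:
            raise ValueError("twin designs need an even number of subjects")
        for low, high in self.age_ranges:
            if low <= 0 or high < low:
                raise ValueError(f"invalid age range ({low}, {high})")


def _simulate_sheet(design: CohortDesign, config: SimulationConfig) -> pd.DataFrame:
    rng = _rng(config.seed, _cohort_tag(design.name), _S_SUBJECTS)
    n = design.n_subjects
    twin = design.twin_structure != "none"
    n_units = n // 2 if twin else n  # a unit = a twin pair or a singleton

    ranges = list(design.age_ranges)
    unit_range = [ranges[u % len(ranges)] for u in range(n_units)]
    unit_age = np.array([rng.uniform(low, high) for low, high in unit_range])

    records = []
    for s in range(n):
        unit = s // 2 if twin else s
        if twin:
            pair_id = f"{design.name}_P{unit:04d}"
            if design.twin_structure == "MZ_pairs":
                zyg = "MZ"
            else:  # alternate pairs MZ/DZ
                zyg = "MZ" if unit % 2 == 0 else "DZ"
        else:
            pair_id, zyg = "", "NA"
        subject_id = f"{design.name}_S{s:04d}"
        sex = "F" if rng.random() < 0.5 else "M"
        for wave in range(1, design.waves + 1):
            records.append(
                {
                    "sample_id": f"{subject_id}_w{wave}",
                    "subject_id": subject_id,
                    "pair_id": pair_id,
                    "zygosity": zyg,
                    "age": unit_age[unit] + (wave - 1) * design.wave_gap,
                    "sex": sex,
                    "cohort": design.name,
                    "wave": wave,
                }
            )
    sheet = pd.DataFrame.from_records(records).set_index("sample_id")
    return sheet


def m_from_beta_inverse(m: np.ndarray) -> np.ndarray:
    """Inverse-M map onto (0, 1): beta = 2**M / (2**M + 1)."""
    return np.exp2(m) / (np.exp2(m) + 1.0)


def simulate_cohort(
    manifest: CpgManifest, design: CohortDesign, config: SimulationConfig
) -> tuple[MethylationStudy, TruthTable]:
    """Simulate one cohort under the generative model.

    The returned :class:`TruthTable` depends only on ``config`` — two cohorts
    simulated from the same config share the same planted CpGs, slopes and
    directions.
    """
    if len(manifest) != config.n_cpgs:
        raise ValueError("manifest size does not match config.n_cpgs")
    sheet = _simulate_sheet(design, config)
    tag = _cohort_tag(design.name)
    n_samples = len(sheet)

    rng_subj = _rng(config.seed, tag, _S_SUBJECTS, 1)
    cells = rng_subj.dirichlet(np.asarray(config.cell_concentration), size=n_samples)
    subjects = sheet["subject_id"].to_numpy()
    uniq_subjects = pd.unique(subjects)
    subject_idx = pd.Series(np.arange(len(uniq_subjects)), index=uniq_subjects)[subjects].to_numpy()
    age = sheet["age"].to_numpy(dtype=float)

    truth = make_truth(config)
    baseline = np.array(
        [config.baseline_m_by_cgi.get(c, 0.0) for c in manifest.table["cgi_relation"]]
    )
    slopes = truth.table["true_slope"].to_numpy()

    # u is indexed by (CpG, subject): random intercepts are independent
    # across CpGs, shared only across a subject's repeated measures.
    M = np.empty((n_samples, config.n_cpgs))
    for j in range(config.n_cpgs):
        gamma = _rng(config.seed, _S_EFFECTS, j).normal(0.0, config.cell_effect_sd, len(CELL_TYPES))
        rng_noise = _rng(config.seed, tag, _S_NOISE, j)
        u = rng_noise.normal(0.0, config.subject_sd, len(uniq_subjects))[subject_idx]
        eps = rng_noise.normal(0.0, config.noise_sd, n_samples)
        M[:, j] = baseline[j] + slopes[j] * age + cells @ gamma + u + eps

    beta = pd.DataFrame(m_from_beta_inverse(M), index=sheet.index, columns=manifest.cpg_ids)
    cells_df = pd.DataFrame(cells, index=sheet.index, columns=list(CELL_TYPES))
    return MethylationStudy(beta, sheet, cells_df), truth


def simulate_gene_sets(
    manifest: CpgManifest,
    truth: TruthTable | None = None,
    n_sets: int = 40,
    set_size: tuple[int, int] = (10, 60),
    seed: int = 0,
) -> GeneSetCollection:
    """Synthetic GMT-style collection drawn from the manifest's gene pool.

    Random sets give a null background; when a truth table is supplied, two
    extra sets concentrate on the genes nearest to planted gain/loss CpGs so
    that over-representation is detectable by construction.
    """
    rng = _rng(seed, _S_GENESETS)
    pool = sorted({g for g in manifest.table["nearest_gene"] if g})
    if not pool:
        raise ValueError("manifest has no annotated genes")
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    lo, hi = set_size
    hi = min(hi, len(pool))
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        members = rng.choice(pool, size=min(size, len(pool)), replace=False)
        sets[f"RANDOM_SET_{i:03d}"] = ("random background set", frozenset(members))
    if truth is not None:
        genes_of = manifest.table["nearest_gene"]
        for direction in ("gain", "loss"):
            cpgs = truth.table.index[truth.table["direction"] == direction]
            genes = frozenset(g for g in genes_of.reindex(cpgs).dropna() if g)
            if genes:
                sets[f"PLANTED_{direction.upper()}_SET"] = (
                    f"genes nearest to planted {direction} CpGs",
                    genes,
                )
    return GeneSetCollection(sets)


def presets() -> dict[str, CohortDesign]:
    """Desk-scale analogues of the three study designs.

    ``discovery_like``: an elderly cohort with repeated measures (baseline
    ages 70–90, a second wave after a six-year follow-up, matching the
    follow-up length of the birth-cohort studies this design emulates).  ``cross_sectional_like``: MZ
    twin pairs in two age clusters, 30–37 and 57–74, one visit each.
    ``longitudinal_like``: mixed MZ/DZ elderly twins aged 73–82 at baseline
    with a second wave after a ten-year follow-up.
    """
    return {
        "discovery_like": CohortDesign(
            name="discovery_like",
            n_subjects=200,
            age_ranges=[(70.0, 90.0)],
            waves=2,
            wave_gap=6.0,
            twin_structure="none",
        ),
        "cross_sectional_like": CohortDesign(
            name="cross_sectional_like",
            n_subjects=150,
            age_ranges=[(30.0, 37.0), (57.0, 74.0)],
            waves=1,
            twin_structure="MZ_pairs",
        ),
        "longitudinal_like": CohortDesign(
            name="longitudinal_like",
            n_subjects=90,
            age_ranges=[(73.0, 82.0)],
            waves=2,
            wave_gap=10.0,
            twin_structure="mixed_MZ_DZ",
        ),
    }
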