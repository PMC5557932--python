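"""End-to-end orchestration: simulate → ewas → replicate → characterize → enrich.

A single global seed is expanded into named per-stage substreams so any stage
can be re-run in isolation from the artifacts of the previous one without
disturbing the others.  Every stage writes plain TSV/CSV/JSON artifacts into
the run directory, and the final ``run_report.json`` records seeds, row
counts at every stage and input hashes; each reported count is re-derived
from the written artifact before the report is emitted.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import characterization, enrichment, ewas, replication, synthetic_data
from .io_formats import (
    CpgManifest,
    GeneSetCollection,
    MethylationStudy,
    read_gmt,
    read_manifest,
    read_study,
    write_gmt,
    write_manifest,
    write_study,
)

__all__ = ["PipelineConfig", "run_all", "stage_seed"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and sizes of one pipeline run.

    ``alpha_fwer`` gates discovery (FWER strictly below), ``alpha_replication``
    gates each validation cohort (p strictly below, same direction), ``k`` is
    the number of permuted scans, ``tail`` the hypergeometric tail convention
    and ``top_sets`` the number of enrichment rows reported per direction.
    """

    seed: int = 0
    k: int = 300
    alpha_fwer: float = 0.05
    alpha_replication: float = 0.05
    tail: str = "gt"
    top_sets: int = 50
    sim: synthetic_data.SimulationConfig = dataclasses.field(
        default_factory=synthetic_data.SimulationConfig
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_fwer < 1.0:
            raise ValueError("alpha_fwer must lie in (0, 1)")
        if not 0.0 < self.alpha_replication < 1.0:
            raise ValueError("alpha_replication must lie in (0, 1)")
        if self.k < ewas.MIN_PERMUTATIONS:
            raise ValueError(f"k must be >= {ewas.MIN_PERMUTATIONS}")

    @classmethod
    def from_mapping(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sim_fields = {f.name for f in dataclasses.fields(synthetic_data.SimulationConfig)}
        sim_kwargs = {k: data.pop(k) for k in list(data) if k in sim_fields}
        seed = data.get("seed", 0)
        sim_kwargs.setdefault("seed", stage_seed(seed, "simulate"))
        for tuple_field in ("cell_concentration",):
            if tuple_field in sim_kwargs:
                sim_kwargs[tuple_field] = tuple(sim_kwargs[tuple_field])
        return cls(sim=synthetic_data.SimulationConfig(**sim_kwargs), **data)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (< 2**31) of the global seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def simulate_stage(config: PipelineConfig, outdir: Path) -> dict:
    """Write manifest, the three cohorts, the planted truth and a synthetic
    gene-set collection."""
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = synthetic_data.simulate_manifest(config.sim)
    write_manifest(manifest, outdir / "manifest.tsv")
    designs = synthetic_data.presets()
    truth = None
    for name, design in designs.items():
        study, truth = synthetic_data.simulate_cohort(manifest, design, config.sim)
        write_study(
            study,
            outdir / f"{name}_beta.tsv",
            outdir / f"{name}_sheet.csv",
            outdir / f"{name}_cells.csv",
        )
    truth.table.to_csv(outdir / "truth_table.csv")
    gene_sets = synthetic_data.simulate_gene_sets(
        manifest, truth, seed=stage_seed(config.seed, "gene_sets")
    )
    write_gmt(gene_sets, outdir / "gene_sets.gmt")
    return {"n_cpgs": len(manifest), "cohorts": list(designs)}


def ewas_stage(
    config: PipelineConfig, study: MethylationStudy, manifest: CpgManifest, outdir: Path
) -> pd.DataFrame:
    result, null = ewas.run_ewas(
        study, manifest, k=config.k, seed=stage_seed(config.seed, "permutation")
    )
    result.to_csv(outdir / "ewas_results.tsv", sep="\t")
    pd.DataFrame({"min_p": null.min_p}).to_csv(outdir / "null_minp.tsv", sep="\t", index=False)
    return result


def replicate_stage(
    config: PipelineConfig,
    discovery_sig: pd.DataFrame,
    cross_sectional: MethylationStudy,
    longitudinal: MethylationStudy,
    outdir: Path,
) -> pd.DataFrame:
    rep_a = replication.replicate_cohort(
        discovery_sig, cross_sectional, cluster_by="pair", alpha=config.alpha_replication
    )
    rep_b = replication.replicate_cohort(
        discovery_sig, longitudinal, cluster_by="subject", alpha=config.alpha_replication
    )
    ledger = replication.build_ledger(discovery_sig, rep_a, rep_b)
    ledger.to_csv(outdir / "replication_ledger.tsv", sep="\t")
    return ledger


def characterize_stage(
    directions: pd.Series, manifest: CpgManifest, outdir: Path
) -> dict[str, pd.DataFrame]:
    region_counts, region_prop = characterization.tabulate_by_region(directions, manifest)
    cgi_counts, cgi_prop = characterization.tabulate_by_cgi(directions, manifest)
    crosstab = characterization.crosstab_region_by_cgi(directions, manifest)
    totals = (int((directions == "gain").sum()), int((directions == "loss").sum()))
    shares = pd.concat(
        [
            characterization.gain_share_summary(region_counts, totals).assign(axis="region"),
            characterization.gain_share_summary(cgi_counts, totals).assign(axis="cgi"),
        ]
    )
    prop = pd.concat(
        [region_prop.assign(axis="region"), cgi_prop.assign(axis="cgi")], ignore_index=True
    )
    region_counts.to_csv(outdir / "region_counts.tsv", sep="\t")
    cgi_counts.to_csv(outdir / "cgi_counts.tsv", sep="\t")
    crosstab.to_csv(outdir / "region_by_cgi.tsv", sep="\t")
    prop.to_csv(outdir / "proportionality.tsv", sep="\t", index=False)
    shares.to_csv(outdir / "direction_shares.tsv", sep="\t")
    return {
        "region_counts": region_counts,
        "cgi_counts": cgi_counts,
        "crosstab": crosstab,
        "proportionality": prop,
        "shares": shares,
    }


def enrich_stage(
    config: PipelineConfig,
    gains: pd.Index,
    losses: pd.Index,
    manifest: CpgManifest,
    collection: GeneSetCollection,
    outdir: Path,
) -> dict[str, pd.DataFrame]:
    universe = frozenset(g for g in manifest.table["nearest_gene"] if g)
    out = {}
    for direction, cpgs in (("gain", gains), ("loss", losses)):
        genes = enrichment.cpgs_to_genes(cpgs, manifest)
        if genes:
            table = enrichment.run_enrichment(
                genes, universe, collection, tail=config.tail, top=config.top_sets
            )
        else:
            table = pd.DataFrame(columns=["set_name", "N", "m", "n", "k", "p_hyper"])
        table.to_csv(outdir / f"enrichment_{direction}.tsv", sep="\t", index=False)
        out[direction] = table
    return out


def run_all(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage in order and write ``run_report.json``.

    Returns the report dict.  The subset chain (double-replicated ⊆ each
    cohort's replicated set ⊆ discovery-significant set) is asserted, and all
    reported counts are re-derived from the on-disk TSVs before reporting.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    sim_info = simulate_stage(config, outdir)
    manifest = read_manifest(outdir / "manifest.tsv")

    def load(name: str) -> MethylationStudy:
        return read_study(
            outdir / f"{name}_beta.tsv", outdir / f"{name}_sheet.csv", outdir / f"{name}_cells.csv"
        )

    discovery = load("discovery_like")
    cross_sectional = load("cross_sectional_like")
    longitudinal = load("longitudinal_like")

    result = ewas_stage(config, discovery, manifest, outdir)
    gains, losses = ewas.significant_set(result, config.alpha_fwer)
    sig = result.loc[gains.union(losses, sort=False)]
    sig = sig.loc[[c for c in result.index if c in set(sig.index)]]  # scan order

    report: dict = {
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in ("simulate", "permutation", "gene_sets")},
        "config": {
            "k": config.k,
            "alpha_fwer": config.alpha_fwer,
            "alpha_replication": config.alpha_replication,
            "tail": config.tail,
            "top_sets": config.top_sets,
            "n_cpgs": config.sim.n_cpgs,
        },
        "counts": {
            "cpgs_simulated": sim_info["n_cpgs"],
            "cpgs_autosomal": int(len(result)),
            "discovery_significant": int(len(sig)),
            "discovery_gain": int(len(gains)),
            "discovery_loss": int(len(losses)),
        },
    }

    if sig.empty:
        logger.warning("no discovery-significant CpGs; downstream stages skipped")
        report["counts"].update(
            {"replicated_cross_sectional": 0, "replicated_longitudinal": 0, "double_replicated": 0}
        )
    else:
        ledger = replicate_stage(config, sig, cross_sectional, longitudinal, outdir)
        dr_gain, dr_loss = replication.double_replicate(ledger)
        rates = replication.replication_rates(ledger)
        report["counts"].update(
            {
                "replicated_cross_sectional": int(ledger["replicated_a"].sum()),
                "replicated_longitudinal": int(ledger["replicated_b"].sum()),
                "double_replicated": int(ledger["double_replicated"].sum()),
                "double_replicated_gain": int(len(dr_gain)),
                "double_replicated_loss": int(len(dr_loss)),
            }
        )
        report["replication_rates_pct"] = {
            k: (None if np.isnan(v) else round(v, 4)) for k, v in rates.items()
        }
        directions = ledger.loc[ledger["double_replicated"], "discovery_direction"]
        if not directions.empty:
            characterize_stage(directions, manifest, outdir)
            collection = read_gmt(outdir / "gene_sets.gmt")
            enrich_stage(config, dr_gain, dr_loss, manifest, collection, outdir)
            report["counts"]["genes_gain"] = len(enrichment.cpgs_to_genes(dr_gain, manifest))
            report["counts"]["genes_loss"] = len(enrichment.cpgs_to_genes(dr_loss, manifest))

        # Cross-check every count against the written artifacts.
        ledger_disk = pd.read_csv(outdir / "replication_ledger.tsv", sep="\t", index_col=0)
        assert int(ledger_disk["double_replicated"].sum()) == report["counts"]["double_replicated"]
        assert len(ledger_disk) == report["counts"]["discovery_significant"]
        rep_a_set = set(ledger_disk.index[ledger_disk["replicated_a"]])
        rep_b_set = set(ledger_disk.index[ledger_disk["replicated_b"]])
        dr_set = set(ledger_disk.index[ledger_disk["double_replicated"]])
        assert dr_set <= rep_a_set and dr_set <= rep_b_set
        assert rep_a_set <= set(ledger_disk.index)

    ewas_disk = pd.read_csv(outdir / "ewas_results.tsv", sep="\t", index_col=0)
    assert int((ewas_disk["fwer"] < config.alpha_fwer).sum()) == report["counts"]["discovery_significant"]

    report["input_hashes"] = {
        p.name: _sha256(p) for p in sorted(outdir.glob("*.tsv")) if p.stat().st_size < 10_000_000
    }
    (outdir / "run_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
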