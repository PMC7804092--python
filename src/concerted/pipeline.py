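"""End-to-end orchestration: simulate -> dereplicate -> rank-abundance fits
-> similarity/homogenisation -> temporal network with KS tests.

Every run writes plain-text artefacts plus a ``manifest.json`` recording
the configuration, the seed, package and library versions and a SHA-256
digest of every output file, so that reruns with the same seed can be
verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

from . import __version__, haplotypes, networks, radmodels, similarity
from .simulate import (SimConfig, evolve_population, sample_environment,
                       sample_strain_reads, write_date_map, write_reads_fasta,
                       write_reference_fasta, write_truth_table)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Settings of one pipeline run.

    ``sim`` carries the generative model; the remaining fields mirror the
    analysis settings (length/quality filters, top-50 truncation, minimum
    haplotype abundance for networks, 99% clustering identity, 1000 KS
    permutations at alpha 0.05).
    """

    sim: SimConfig = field(default_factory=SimConfig)
    n_strains: int = 3
    min_len: int = haplotypes.DEFAULT_MIN_LEN
    min_q: float = haplotypes.DEFAULT_MIN_QUAL
    top: int = 50
    min_abund: int = 2
    cluster_id: float = 99.0
    n_perm: int = 1000
    alpha: float = 0.05
    limit: int | str = "auto"
    species_label: str = "simulated species"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    sim = d.pop("sim")
    if sim.get("seasonal_profile") is not None:
        sim["seasonal_profile"] = list(sim["seasonal_profile"])
    sim["copy_number_bounds"] = list(sim["copy_number_bounds"])
    d["sim"] = sim
    return d


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Run the full analysis and return the manifest dictionary.

    Artefacts (all tab-separated or FASTA/NEXUS text) are written under
    ``outdir``: simulated reads and truth tables, per-strain haplotype
    tables, rank-abundance fit reports, similarity and homogenisation
    reports, and the environmental network with its KS table.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim = cfg.sim

    logger.info("stage simulate: %d lineages, %d generations",
                sim.n_lineages, sim.n_generations)
    genomes = evolve_population(sim)
    strains = [g.lineage_id for g in genomes[:cfg.n_strains]]
    strain_reads = sample_strain_reads(genomes, sim, strains)
    env_reads = sample_environment(genomes, sim)
    write_reads_fasta(strain_reads, out / "strain_reads.fasta")
    write_reads_fasta(env_reads, out / "env_reads.fasta")
    write_date_map(env_reads, out / "env_dates.tsv")
    write_truth_table(genomes, out / "truth_haplotypes.tsv")
    write_reference_fasta(genomes, out / "references.fasta")

    logger.info("stage derep/filter")
    strain_reads = haplotypes.filter_reads(strain_reads, cfg.min_len, cfg.min_q)
    env_reads = haplotypes.filter_reads(env_reads, cfg.min_len, cfg.min_q)
    strain_table = haplotypes.dereplicate(strain_reads, cfg.species_label)
    env_table = haplotypes.dereplicate(env_reads, cfg.species_label)
    haplotypes.write_count_table(strain_table, out / "strain_haplotypes.tsv")
    haplotypes.write_count_table(env_table, out / "env_haplotypes.tsv")
    haplotypes.write_haplotype_fasta(haplotypes.top_k(env_table, cfg.top),
                                     out / "env_top_haplotypes.fasta")

    summary_rows = []
    logger.info("stage radfit")
    for label, table in (("strain", strain_table), ("environment", env_table)):
        truncated = haplotypes.top_k(table, cfg.top)
        haplotypes.write_rank_abundance(truncated,
                                        out / f"{label}_rank_abundance.tsv")
        fits = radmodels.select_model(truncated.abundances())
        radmodels.write_fit_report(fits, out / f"{label}_rad_fits.tsv")
        radmodels.write_fitted_values(fits, out / f"{label}_rad_fitted.tsv")
        dom = haplotypes.dominance(table)
        summary_rows.append({
            "dataset": label,
            "reads": table.N,
            "haplotypes": table.S,
            "dominant_id": dom.dominant_id,
            "log10_dominance_ratio": round(dom.log10_ratio, 4),
            "is_dominant": dom.is_dominant,
            "best_rad_model": fits[0].model,
        })

    logger.info("stage similarity")
    ref_table = haplotypes.dereplicate(
        haplotypes.read_reads(out / "references.fasta"))
    env_top = haplotypes.top_k(env_table, cfg.top)
    matches = similarity.best_match(env_top, strain_table)
    similarity.write_match_report(matches, out / "env_vs_strain_matches.tsv")
    classes = similarity.classify_similarity(matches)
    similarity.write_class_table(classes, out / "similarity_classes.tsv")
    dom_match = similarity.best_match(
        strain_table.subset([strain_table.counts.index[0]]), ref_table)[0]
    homog = similarity.cluster_to_dominant(strain_reads, cfg.cluster_id)
    with open(out / "homogenisation.tsv", "w") as fh:
        fh.write("n_reads\tn_in_dominant_cluster\tn_clusters\t"
                 "threshold_pct\tefficiency_pct\tdominant_vs_reference_pct\n")
        fh.write(f"{homog.n_reads}\t{homog.n_in_dominant_cluster}\t"
                 f"{homog.n_clusters}\t{homog.threshold_pct}\t"
                 f"{homog.efficiency:.4f}\t{dom_match.pct_identity:.4f}\n")

    logger.info("stage network")
    net_table = haplotypes.min_abundance(env_table, cfg.min_abund)
    network = networks.build_network(net_table, cfg.limit)
    networks.write_nexus(network, net_table, out / "env_network.nex")
    networks.write_edge_list(network, out / "env_network_edges.tsv")
    networks.write_gml(network, out / "env_network.gml")

    logger.info("stage ks")
    labels = networks.classify_nodes(network, net_table, n_perm=cfg.n_perm,
                                     seed=sim.seed, alpha=cfg.alpha)
    networks.write_ks_report(labels["results"], out / "ks_report.tsv")
    summary_rows.append({
        "dataset": "network",
        "reads": net_table.N,
        "haplotypes": net_table.S,
        "dominant_id": network.dominant_id,
        "log10_dominance_ratio": "",
        "is_dominant": "",
        "best_rad_model": "",
        "congruent_nodes": len(labels["congruent"]),
        "divergent_nodes": len(labels["divergent"]),
    })
    pd.DataFrame(summary_rows).to_csv(out / "summary.tsv", sep="\t",
                                      index=False)

    manifest = {
        "package": "concerted",
        "version": __version__,
        "seed": sim.seed,
        "config": _config_dict(cfg),
        "versions": {"numpy": np.__version__, "scipy": scipy.__version__,
                     "pandas": pd.__version__},
        "outputs": {p.name: _sha256(p)
                    for p in sorted(out.iterdir())
                    if p.name != "manifest.json"},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline complete: %s", out)
    return manifest
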