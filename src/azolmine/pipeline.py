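"""End-to-end orchestration: genomes -> mining -> cross-genome seed
deduplication -> precursor prediction -> family classification -> similarity
network -> run report and artifacts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from . import __version__
from .config import PipelineConfig
from .mining import CandidateCluster, mine_genome
from .motifs import FamilyCall, classify_family, compute_profile, write_family_tsv
from .network import BGCNetwork, ClusterProfile, build_network, write_edge_tsv, write_graphml
from .precursors import PrecursorCandidate, find_cluster_precursors, write_precursor_fasta
from .redundancy import greedy_cluster
from .seq_records import AnnotationTable, GenomeRecord, write_genbank

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1


@dataclass
class ClusterResult:
    genome_id: str
    cluster: CandidateCluster
    precursors: list[PrecursorCandidate] = field(default_factory=list)
    family: Optional[FamilyCall] = None
    deduplicated: bool = False  # True when dropped as a redundant seed copy


@dataclass
class RunReport:
    schema_version: int
    version: str
    seed: Optional[int]
    config: dict
    genome_counts: dict
    cluster_records: list[dict]
    network_summary: dict

    def to_json(self) -> str:
        return json.dumps({
            "schema_version": self.schema_version,
            "version": self.version,
            "seed": self.seed,
            "config": self.config,
            "genome_counts": self.genome_counts,
            "clusters": self.cluster_records,
            "network": self.network_summary,
        }, indent=1, sort_keys=True)


def _dedup_seed_proteins(results: list[ClusterResult],
                         genomes: dict[str, GenomeRecord],
                         cfg: PipelineConfig) -> None:
    """Mark clusters whose every seed protein is a redundant (>=90/90) copy
    of another cluster's representative seed."""
    proteins: dict[str, str] = {}
    owner: dict[str, list[ClusterResult]] = {}
    for res in results:
        genome = genomes[res.genome_id]
        for gene_id in res.cluster.seed_gene_ids:
            key = f"{res.genome_id}::{gene_id}"
            proteins[key] = genome.feature_by_id(gene_id).protein
            owner.setdefault(key, []).append(res)
    if not proteins:
        return
    clusters = greedy_cluster(proteins, cfg.dedup_identity, cfg.dedup_coverage)
    representatives = {c.representative_id for c in clusters}
    for res in results:
        keys = [f"{res.genome_id}::{g}" for g in res.cluster.seed_gene_ids]
        res.deduplicated = bool(keys) and not any(k in representatives for k in keys)


def run_pipeline(genomes: Iterable[tuple[GenomeRecord, AnnotationTable]],
                 cfg: Optional[PipelineConfig] = None,
                 out_dir: Optional[Path] = None,
                 seed: Optional[int] = None) -> tuple[RunReport, list[ClusterResult], BGCNetwork]:
    """Run every stage over pre-loaded (genome, annotation) pairs.

    Every genome must come with an annotation table (an empty table is
    explicit, a missing one is an error) — silent skips would bias counts.
    """
    cfg = cfg or PipelineConfig()
    results: list[ClusterResult] = []
    genome_index: dict[str, GenomeRecord] = {}
    annot_index: dict[str, AnnotationTable] = {}
    for genome, annot in genomes:
        if annot is None:
            raise ValueError(f"missing annotation table for genome {genome.contig_id}")
        genome_index[genome.contig_id] = genome
        annot_index[genome.contig_id] = annot
        for cluster in mine_genome(genome, annot, cfg.mining):
            log.info("cluster %s: status=%s partner=%s", cluster.cluster_id,
                     cluster.status, cluster.partner_class)
            results.append(ClusterResult(genome.contig_id, cluster))

    _dedup_seed_proteins(results, genome_index, cfg)

    profiles: list[ClusterProfile] = []
    for res in results:
        if res.cluster.status != "passed" or res.deduplicated:
            continue
        genome = genome_index[res.genome_id]
        annot = annot_index[res.genome_id]
        res.precursors = find_cluster_precursors(
            genome, res.cluster, flank_bp=cfg.precursor_flank_bp,
            min_aa=cfg.precursor_min_aa, max_aa=cfg.precursor_max_aa)
        top = res.precursors[0] if res.precursors else None
        profile = compute_profile(top.peptide, cfg.motifs) if top else compute_profile("A")
        res.family = classify_family(profile, res.cluster, cfg.motifs)
        domain_set = frozenset(
            acc for gene_id in res.cluster.member_gene_ids
            for acc in annot.accessions(gene_id))
        profiles.append(ClusterProfile(
            cluster_id=f"{res.genome_id}|{res.cluster.cluster_id}",
            domain_accessions=domain_set,
            precursor=top.peptide if top else None,
            partner_class=res.cluster.partner_class,
            family_label=res.family.label))

    network = build_network(profiles, cutoff=cfg.network_cutoff,
                            w_dom=cfg.network_w_dom, w_prec=cfg.network_w_prec)
    report = _build_report(cfg, results, network, seed)
    if out_dir is not None:
        _write_artifacts(out_dir, cfg, results, network, report, genome_index, annot_index)
    return report, results, network


def _build_report(cfg: PipelineConfig, results: list[ClusterResult],
                  network: BGCNetwork, seed: Optional[int]) -> RunReport:
    statuses = ["passed", "rejected_invalid_seed", "rejected_lanB", "rejected_no_partner"]
    genome_counts: dict[str, dict] = {}
    for res in results:
        counts = genome_counts.setdefault(res.genome_id, {
            "clusters_called": 0, "deduplicated": 0,
            **{s: 0 for s in statuses}})
        counts["clusters_called"] += 1
        counts[res.cluster.status] += 1
        if res.deduplicated:
            counts["deduplicated"] += 1
    cluster_records = []
    for res in results:
        top = res.precursors[0] if res.precursors else None
        cluster_records.append({
            "genome": res.genome_id,
            "cluster_id": res.cluster.cluster_id,
            "start": res.cluster.start, "end": res.cluster.end,
            "strand": res.cluster.strand,
            "n_genes": len(res.cluster.member_gene_ids),
            "status": res.cluster.status,
            "rejection_reasons": res.cluster.rejection_reasons,
            "partner_class": res.cluster.partner_class,
            "flags": res.cluster.flags,
            "deduplicated": res.deduplicated,
            "family": res.family.label if res.family else None,
            "precursor_score": top.score if top else None,
            "precursor_peptide": top.peptide if top else None,
        })
    return RunReport(
        schema_version=SCHEMA_VERSION, version=__version__, seed=seed,
        config=cfg.snapshot(),
        genome_counts=genome_counts,
        cluster_records=cluster_records,
        network_summary={
            "nodes": network.graph.number_of_nodes(),
            "edges": network.graph.number_of_edges(),
            "components": len(network.components),
        })


def _write_artifacts(out_dir: Path, cfg: PipelineConfig, results, network,
                     report: RunReport, genome_index, annot_index) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "report.json").write_text(report.to_json() + "\n")
    write_graphml(network, out_dir / "network.graphml")
    write_edge_tsv(network, out_dir / "edges.tsv")
    calls = [res.family for res in results if res.family is not None]
    write_family_tsv(calls, out_dir / "families.tsv")
    by_cluster = {f"{r.genome_id}|{r.cluster.cluster_id}": r.precursors
                  for r in results if r.precursors}
    write_precursor_fasta(by_cluster, out_dir / "precursors.fasta", top_n=3)
    gbk_dir = out_dir / "genomes"
    gbk_dir.mkdir(exist_ok=True)
    labels = {r.cluster.cluster_id: (r.family.label if r.family else r.cluster.status)
              for r in results}
    by_genome: dict[str, list] = {}
    for res in results:
        by_genome.setdefault(res.genome_id, []).append(res.cluster)
    for genome_id, genome in genome_index.items():
        write_genbank(genome, by_genome.get(genome_id, []),
                      gbk_dir / f"{genome_id}.gbk",
                      annot=annot_index[genome_id],
                      biosynthetic_accessions=cfg.mining.biosynthetic_accessions,
                      cluster_labels=labels)
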