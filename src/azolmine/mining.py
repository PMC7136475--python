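"""YcaO-seeded BGC mining: seed detection, neighborhood cutting, cluster
calling and inclusion/exclusion filtering.

The workflow mirrors the standard azol(in)e-RiPP mining recipe: find genes
carrying a YcaO cyclodehydratase domain, cut a +/-12.5 kbp neighborhood
around each validated seed, call the cluster as the maximal run of
same-strand genes separated by at most 100 bp, then keep only neighborhoods
that also encode an E1-like or ThiF-like partner protein and discard any
neighborhood carrying a lantipeptide-dehydratase (LanB) gene, which is
diagnostic of thiopeptide-like chemistry handled by other tools.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Optional

from .seq_records import AnnotationTable, GeneFeature, GenomeRecord

# C-terminal Pro-x-Pro motif of azoline-forming YcaOs; searched within the
# last PXP_WINDOW residues of a YcaO-hit protein.
PXP_WINDOW = 10
_PXP = re.compile(r"P.P")

REJECTION_PRIORITY = ("rejected_invalid_seed", "rejected_lanB", "rejected_no_partner")


def _default_ycao() -> set[str]:
    return {"TIGR03549", "TIGR03604", "PF02624"}


def _default_e1() -> set[str]:
    return {"PF00881", "TIGR03603", "TIGR04424"}


def _default_thif() -> set[str]:
    return {"PF00899", "TIGR02354", "TIGR02356", "TIGR03693", "TIGR03736", "TIGR03882"}


def _default_lanb() -> set[str]:
    return {"PF14028", "PF04738", "TIGR03897", "PF05147"}


@dataclass
class MiningConfig:
    """Accession lists and thresholds driving the mining stage.

    Defaults reproduce the published accession lists: YcaO seeds
    TIGR03549/TIGR03604/PF02624, E1-like PF00881/TIGR03603/TIGR04424,
    ThiF-like PF00899/TIGR02354/TIGR02356/TIGR03693/TIGR03736/TIGR03882,
    LanB PF14028/PF04738/TIGR03897/PF05147, PRP PF00805, a 12.5 kbp window
    and a 100 bp same-strand gap.  ``permissive_seed_accessions`` lets a
    sensitive pre-annotation nominate putative YcaO genes that are then
    rejected (status ``rejected_invalid_seed``) unless they also carry a
    *bona fide* YcaO accession.
    """

    ycao_accessions: set[str] = field(default_factory=_default_ycao)
    e1_accessions: set[str] = field(default_factory=_default_e1)
    thif_accessions: set[str] = field(default_factory=_default_thif)
    lanb_accessions: set[str] = field(default_factory=_default_lanb)
    prp_accessions: set[str] = field(default_factory=lambda: {"PF00805"})
    protease_accessions: set[str] = field(default_factory=lambda: {"PF00082", "PF13365"})
    dehydrogenase_accessions: set[str] = field(default_factory=lambda: {"PF00881"})
    transporter_accessions: set[str] = field(default_factory=lambda: {"PF00005", "PF13437"})
    permissive_seed_accessions: set[str] = field(default_factory=lambda: {"YCAO_PUTATIVE"})
    biosynthetic_accessions: Optional[set[str]] = None  # None -> union of the above
    window_bp: int = 12_500
    max_gap_bp: int = 100
    seed_evalue_max: float = 1e-5

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window_bp must be > 0")
        if self.max_gap_bp < 0:
            raise ValueError("max_gap_bp must be >= 0")
        if self.biosynthetic_accessions is None:
            self.biosynthetic_accessions = (
                set(self.ycao_accessions) | self.e1_accessions | self.thif_accessions
                | self.lanb_accessions | self.prp_accessions
            )


@dataclass(frozen=True)
class SeedHit:
    contig_id: str
    gene_id: str
    best_ycao_accession: str
    validated: bool


@dataclass
class Neighborhood:
    contig_id: str
    window_start: int
    window_end: int
    seed_gene_id: str
    member_gene_ids: list[str]
    genome: Optional[GenomeRecord] = field(default=None, repr=False, compare=False)


@dataclass
class CandidateCluster:
    """A called BGC: the same-strand gene run containing the seed plus the
    evidence flags computed over the full neighborhood."""

    cluster_id: str
    contig_id: str
    start: int
    end: int
    member_gene_ids: list[str]
    strand: int
    seed_gene_id: str
    seed_gene_ids: list[str] = field(default_factory=list)
    partner_class: str = "none"  # E1 | ThiF | both | none
    flags: dict = field(default_factory=dict)
    status: str = "called"
    rejection_reasons: list[str] = field(default_factory=list)
    validated_seed: bool = True

    def __post_init__(self) -> None:
        if not self.seed_gene_ids:
            self.seed_gene_ids = [self.seed_gene_id]


def find_seeds(genome: GenomeRecord, annot: AnnotationTable, cfg: MiningConfig) -> list[SeedHit]:
    """One SeedHit per gene with a qualifying YcaO hit (validated) or, for
    genes lacking one, a hit from the permissive pre-annotation set."""
    seeds: list[SeedHit] = []
    for feature in genome.features:
        hits = [h for h in annot.hits(feature.gene_id) if h.e_value <= cfg.seed_evalue_max]
        ycao_hits = [h for h in hits if h.accession in cfg.ycao_accessions]
        if ycao_hits:
            best = max(ycao_hits, key=lambda h: h.bit_score)
            seeds.append(SeedHit(genome.contig_id, feature.gene_id, best.accession, True))
            continue
        permissive = [h for h in hits if h.accession in cfg.permissive_seed_accessions]
        if permissive:
            best = max(permissive, key=lambda h: h.bit_score)
            seeds.append(SeedHit(genome.contig_id, feature.gene_id, best.accession, False))
    return seeds


def extract_neighborhood(genome: GenomeRecord, seed: SeedHit, cfg: MiningConfig) -> Neighborhood:
    """Window of ``window_bp`` to each side of the seed gene, clipped to the
    contig; members are all genes overlapping the window by >= 1 bp."""
    gene = genome.feature_by_id(seed.gene_id)
    start = max(0, gene.start - cfg.window_bp)
    end = min(genome.length_bp, gene.end + cfg.window_bp)
    members = [f.gene_id for f in genome.features_overlapping(start, end)]
    return Neighborhood(genome.contig_id, start, end, seed.gene_id, members, genome)


def _strand_run(genes: list[GeneFeature], seed_idx: int, max_gap_bp: int) -> list[GeneFeature]:
    strand = genes[seed_idx].strand
    lo = hi = seed_idx
    while hi + 1 < len(genes):
        nxt = genes[hi + 1]
        if nxt.strand != strand or nxt.start - genes[hi].end > max_gap_bp:
            break
        hi += 1
    while lo > 0:
        prv = genes[lo - 1]
        if prv.strand != strand or genes[lo].start - prv.end > max_gap_bp:
            break
        lo -= 1
    return genes[lo:hi + 1]


def call_cluster(neigh: Neighborhood, genome: GenomeRecord, cfg: MiningConfig,
                 validated: bool = True) -> CandidateCluster:
    """Call the cluster as the maximal run of genes on the seed's strand with
    intergenic gaps <= ``max_gap_bp`` (a 100 bp gap is included; 101 splits).
    An opposite-strand gene terminates extension in that direction."""
    genes = sorted((genome.feature_by_id(g) for g in neigh.member_gene_ids),
                   key=lambda f: (f.start, f.end, f.gene_id))
    seed_idx = next(i for i, f in enumerate(genes) if f.gene_id == neigh.seed_gene_id)
    run = _strand_run(genes, seed_idx, cfg.max_gap_bp)
    start = run[0].start
    end = max(f.end for f in run)
    return CandidateCluster(
        cluster_id=f"{neigh.contig_id}:{start}-{end}",
        contig_id=neigh.contig_id,
        start=start,
        end=end,
        member_gene_ids=[f.gene_id for f in run],
        strand=run[0].strand,
        seed_gene_id=neigh.seed_gene_id,
        validated_seed=validated,
    )


def _has_pxp_cterm(protein: str) -> bool:
    return bool(_PXP.search(protein[-PXP_WINDOW:]))


def apply_filters(cluster: CandidateCluster, neigh: Neighborhood,
                  annot: AnnotationTable, cfg: MiningConfig) -> CandidateCluster:
    """Set partner class, evidence flags and final status.

    Partner and LanB evidence is collected over the full neighborhood (the
    inclusion/exclusion rules act on genomic regions); the YcaO-specific
    flags are computed over the cluster's own members.  Rejection reasons are
    recorded in priority order invalid seed > lanB > no partner, and the
    status is the highest-priority applicable reason.
    """
    neigh_accessions: set[str] = set()
    for gene_id in neigh.member_gene_ids:
        neigh_accessions |= annot.accessions(gene_id)
    has_e1 = bool(neigh_accessions & cfg.e1_accessions)
    has_thif = bool(neigh_accessions & cfg.thif_accessions)
    partner = {(True, True): "both", (True, False): "E1",
               (False, True): "ThiF", (False, False): "none"}[(has_e1, has_thif)]

    n_ycao = 0
    has_pxp = False
    for gene_id in cluster.member_gene_ids:
        if annot.accessions(gene_id) & cfg.ycao_accessions:
            n_ycao += 1
            if neigh.genome is not None:
                protein = neigh.genome.feature_by_id(gene_id).protein
                if _has_pxp_cterm(protein):
                    has_pxp = True

    flags = {
        "has_lanB": bool(neigh_accessions & cfg.lanb_accessions),
        "has_prp": bool(neigh_accessions & cfg.prp_accessions),
        "n_ycao_genes": n_ycao,
        "has_pxp_ycao": has_pxp,
        "has_extra_protease": bool(neigh_accessions & cfg.protease_accessions),
        "has_dehydrogenase": bool(neigh_accessions & cfg.dehydrogenase_accessions),
        "has_transporter": bool(neigh_accessions & cfg.transporter_accessions),
    }
    reasons = []
    if not cluster.validated_seed:
        reasons.append("rejected_invalid_seed")
    if flags["has_lanB"]:
        reasons.append("rejected_lanB")
    if partner == "none":
        reasons.append("rejected_no_partner")
    status = reasons[0] if reasons else "passed"
    out = replace(cluster)
    out.partner_class = partner
    out.flags = flags
    out.status = status
    out.rejection_reasons = reasons
    return out


def mine_genome(genome: GenomeRecord, annot: AnnotationTable,
                cfg: Optional[MiningConfig] = None) -> list[CandidateCluster]:
    """Full per-contig mining: seeds -> neighborhoods -> clusters -> filters.

    Clusters from distinct seeds that land in the same same-strand run are
    merged into one cluster (all seeds retained); the merge inherits seed
    validation if any contributing seed is validated.
    """
    cfg = cfg or MiningConfig()
    seeds = find_seeds(genome, annot, cfg)
    raw: list[tuple[CandidateCluster, SeedHit]] = []
    for seed in seeds:
        neigh = extract_neighborhood(genome, seed, cfg)
        cluster = call_cluster(neigh, genome, cfg, validated=seed.validated)
        raw.append((cluster, seed))
    raw.sort(key=lambda t: (t[0].start, t[0].end, t[0].seed_gene_id))

    merged: list[tuple[CandidateCluster, list[SeedHit]]] = []
    for cluster, seed in raw:
        if merged:
            prev, prev_seeds = merged[-1]
            if prev.strand == cluster.strand and cluster.start < prev.end and prev.start < cluster.end:
                member_ids = sorted(set(prev.member_gene_ids) | set(cluster.member_gene_ids),
                                    key=lambda g: genome.feature_by_id(g).start)
                prev.member_gene_ids = member_ids
                prev.start = min(prev.start, cluster.start)
                prev.end = max(prev.end, cluster.end)
                prev.cluster_id = f"{genome.contig_id}:{prev.start}-{prev.end}"
                prev.seed_gene_ids = sorted(set(prev.seed_gene_ids) | {cluster.seed_gene_id})
                prev.validated_seed = prev.validated_seed or cluster.validated_seed
                prev_seeds.append(seed)
                continue
        merged.append((cluster, [seed]))

    out: list[CandidateCluster] = []
    for cluster, cluster_seeds in merged:
        # neighborhood of the merged cluster = union of member windows
        primary = next(s for s in cluster_seeds
                       if s.gene_id == cluster.seed_gene_id)
        window_start = min(extract_neighborhood(genome, s, cfg).window_start for s in cluster_seeds)
        window_end = max(extract_neighborhood(genome, s, cfg).window_end for s in cluster_seeds)
        members = [f.gene_id for f in genome.features_overlapping(window_start, window_end)]
        neigh = Neighborhood(genome.contig_id, window_start, window_end,
                             primary.gene_id, members, genome)
        out.append(apply_filters(cluster, neigh, annot, cfg))
    out.sort(key=lambda c: (c.start, c.end))
    return out
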