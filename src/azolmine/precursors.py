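"""Precursor-peptide candidate discovery and ranking.

Short ORFs inside (and just around) a called cluster are enumerated in all
six frames and ranked by the count of cyclizable residues (Ser, Thr, Cys)
in the C-terminal half of the translated peptide — the residues a YcaO
cyclodehydratase can convert into azoline heterocycles.  The best candidate
per cluster (highest score, then nearest to the seed gene, then leftmost)
is taken as the predicted precursor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from Bio.Seq import Seq

from .mining import CandidateCluster
from .seq_records import GenomeRecord

START_CODONS = {"ATG", "GTG", "TTG"}
STOP_CODONS = {"TAA", "TAG", "TGA"}
CYCLIZABLE = set("STC")

#: ORFs overlapping an annotated CDS at least this long (aa), on the same
#: strand and frame, are fragments of enzymes, not precursors.
SUPPRESS_CDS_MIN_AA = 60


@dataclass
class PrecursorCandidate:
    cluster_id: str
    start: int
    end: int  # genomic, 0-based half-open, stop codon included
    strand: int
    frame: int
    peptide: str
    length_aa: int
    source: str  # annotated_cds | novel_orf
    score: Optional[int] = None
    cterm_half_len: Optional[int] = None
    distance_to_seed_bp: int = 0
    rank: int = 0


def cterm_cyclizable_score(peptide: str) -> tuple[int, int]:
    """Count of Ser/Thr/Cys in the C-terminal half (last ceil(n/2) residues).

    Returns ``(score, half_len)``.
    """
    if not peptide:
        raise ValueError("empty peptide")
    half = math.ceil(len(peptide) / 2)
    score = sum(1 for aa in peptide[-half:] if aa in CYCLIZABLE)
    return score, half


def _translate(dna: str) -> str:
    pep = str(Seq(dna).translate(table=11))
    return "M" + pep[1:] if pep else pep


def _scan_frame(seq: str, frame: int, min_aa: int, max_aa: int):
    """Yield (start, end) offsets of ORFs in one forward frame of ``seq``.

    An ORF runs from the first start codon after a stop (the frame start is
    treated as preceded by a stop) through the next stop codon, which must
    lie within the scanned sequence; the emitted interval includes the stop.
    """
    orf_start = None
    open_for_start = True
    for pos in range(frame, len(seq) - 2, 3):
        codon = seq[pos:pos + 3]
        if codon in STOP_CODONS:
            if orf_start is not None:
                length_aa = (pos - orf_start) // 3
                if min_aa <= length_aa <= max_aa:
                    yield orf_start, pos + 3
            orf_start = None
            open_for_start = True
        elif open_for_start and codon in START_CODONS:
            orf_start = pos
            open_for_start = False


def find_orfs(genome: GenomeRecord, region: tuple[int, int], min_aa: int = 5,
              max_aa: int = 170, cluster_id: str = "") -> list[PrecursorCandidate]:
    """All candidate precursor ORFs in ``region`` (both strands, 3 frames
    each) plus annotated short CDS overlapping the region.

    Candidates with identical genomic intervals are collapsed, preferring
    the annotated copy; novel ORFs that overlap a long annotated CDS in the
    same strand and frame are suppressed as enzyme fragments.
    """
    rs, re_ = region
    if not (0 <= rs < re_ <= genome.length_bp):
        raise ValueError(f"region [{rs}, {re_}) outside contig {genome.contig_id}")
    seq = genome.sequence[rs:re_].upper()
    cands: dict[tuple[int, int, int], PrecursorCandidate] = {}

    def _add(cand: PrecursorCandidate) -> None:
        key = (cand.start, cand.end, cand.strand)
        if key in cands and cands[key].source == "annotated_cds":
            return
        if key in cands and cand.source != "annotated_cds":
            return
        cands[key] = cand

    for frame in range(3):
        for s, e in _scan_frame(seq, frame, min_aa, max_aa):
            pep = _translate(seq[s:e - 3])
            _add(PrecursorCandidate(cluster_id, rs + s, rs + e, +1, frame,
                                    pep, len(pep), "novel_orf"))
    rc = str(Seq(seq).reverse_complement())
    for frame in range(3):
        for s, e in _scan_frame(rc, frame, min_aa, max_aa):
            pep = _translate(rc[s:e - 3])
            # rc offset i maps to genomic coordinate re_ - 1 - i
            _add(PrecursorCandidate(cluster_id, re_ - e, re_ - s, -1, frame,
                                    pep, len(pep), "novel_orf"))

    long_cds = [f for f in genome.features if len(f.protein) >= SUPPRESS_CDS_MIN_AA]
    for f in genome.features_overlapping(rs, re_):
        if min_aa <= len(f.protein) <= max_aa:
            cand = PrecursorCandidate(cluster_id, f.start, f.end, f.strand,
                                      f.start % 3 if f.strand == 1 else f.end % 3,
                                      f.protein, len(f.protein), "annotated_cds")
            cands[(f.start, f.end, f.strand)] = cand

    def _same_frame(cand: PrecursorCandidate, f) -> bool:
        if cand.strand != f.strand:
            return False
        if cand.strand == 1:
            return (cand.start - f.start) % 3 == 0
        return (f.end - cand.end) % 3 == 0

    kept = [
        c for c in cands.values()
        if c.source == "annotated_cds"
        or not any(f.overlaps(c.start, c.end) and _same_frame(c, f) for f in long_cds)
    ]
    kept.sort(key=lambda c: (c.start, c.end, c.strand))
    return kept


def _interval_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, max(a_start, b_start) - min(a_end, b_end))


def rank_precursors(cands: list[PrecursorCandidate],
                    seed_interval: tuple[int, int]) -> list[PrecursorCandidate]:
    """Score (if unscored) and rank candidates of one cluster.

    Sort key: cyclizable score descending, distance to the seed gene
    ascending (0 when overlapping), then leftmost start.  Ranks are 1..n.
    """
    ss, se = seed_interval
    for c in cands:
        if c.score is None:
            c.score, c.cterm_half_len = cterm_cyclizable_score(c.peptide)
        c.distance_to_seed_bp = _interval_gap(c.start, c.end, ss, se)
    ranked = sorted(cands, key=lambda c: (-c.score, c.distance_to_seed_bp, c.start))
    for i, c in enumerate(ranked, 1):
        c.rank = i
    return ranked


def find_cluster_precursors(genome: GenomeRecord, cluster: CandidateCluster,
                            flank_bp: int = 1000, min_aa: int = 5,
                            max_aa: int = 170) -> list[PrecursorCandidate]:
    """Ranked precursor candidates for one called cluster.

    The search region is the cluster boundary extended by ``flank_bp`` on
    each side (precursor genes can sit just outside the strand run).
    """
    region = (max(0, cluster.start - flank_bp),
              min(genome.length_bp, cluster.end + flank_bp))
    cands = find_orfs(genome, region, min_aa=min_aa, max_aa=max_aa,
                      cluster_id=cluster.cluster_id)
    seed = genome.feature_by_id(cluster.seed_gene_id)
    return rank_precursors(cands, (seed.start, seed.end))


def write_precursor_fasta(cands_by_cluster: dict[str, list[PrecursorCandidate]],
                          path, top_n: Optional[int] = None) -> None:
    """FASTA export of ranked precursors; headers carry cluster, rank, score."""
    with open(path, "w") as fh:
        for cluster_id in sorted(cands_by_cluster):
            for c in cands_by_cluster[cluster_id]:
                if top_n is not None and c.rank > top_n:
                    continue
                fh.write(f">{cluster_id}|rank={c.rank}|score={c.score}"
                         f"|{c.start}-{c.end}({'+' if c.strand == 1 else '-'})\n"
                         f"{c.peptide}\n")
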