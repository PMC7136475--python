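"""Genome and annotation data model plus all external-format I/O.

Internal coordinates are 0-based half-open on the forward strand throughout
the package; GenBank's 1-based inclusive convention is converted at the I/O
boundary.  Domain-accession version suffixes (``PF02624.19`` -> ``PF02624``)
are stripped on ingest so configuration lists can use bare accessions.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

_VERSION_SUFFIX = re.compile(r"\.\d+$")


class ParseError(ValueError):
    """Raised when an external file cannot be interpreted."""


def normalize_accession(accession: str) -> str:
    """Strip a trailing version suffix (``PF02624.19`` -> ``PF02624``)."""
    return _VERSION_SUFFIX.sub("", accession)


@dataclass(frozen=True)
class GeneFeature:
    """A protein-coding feature on the forward-strand coordinate system.

    ``start``/``end`` are 0-based half-open; ``strand`` is +1 or -1.
    """

    gene_id: str
    start: int
    end: int
    strand: int
    protein: str
    product_label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval for {self.gene_id}: [{self.start}, {self.end})")
        if self.strand not in (+1, -1):
            raise ValueError(f"bad strand for {self.gene_id}: {self.strand}")

    @property
    def span(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass
class GenomeRecord:
    """A contig with strand-aware CDS features and protein translations."""

    contig_id: str
    length_bp: int
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features.sort(key=lambda f: (f.start, f.end, f.gene_id))
        for f in self.features:
            if f.end > self.length_bp:
                raise ValueError(
                    f"feature {f.gene_id} [{f.start}, {f.end}) outside contig "
                    f"{self.contig_id} of length {self.length_bp}"
                )

    def feature_by_id(self, gene_id: str) -> GeneFeature:
        for f in self.features:
            if f.gene_id == gene_id:
                return f
        raise KeyError(gene_id)

    def features_overlapping(self, start: int, end: int) -> list[GeneFeature]:
        return [f for f in self.features if f.overlaps(start, end)]

    def proteins(self) -> Iterator[tuple[str, str]]:
        for f in self.features:
            yield f.gene_id, f.protein


@dataclass(frozen=True)
class DomainHit:
    """A protein-domain annotation (one hmmsearch domain row, or one TSV row).

    ``ali_from``/``ali_to`` are 1-based inclusive protein coordinates;
    ``None`` means the alignment extent is unknown (treated as full length).
    """

    protein_id: str
    accession: str
    bit_score: float
    e_value: float = 0.0
    ali_from: Optional[int] = None
    ali_to: Optional[int] = None

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")
        if self.ali_from is not None and self.ali_to is not None and self.ali_from > self.ali_to:
            raise ValueError("ali_from must be <= ali_to")


class AnnotationTable:
    """Mapping protein_id -> list of DomainHit; unknown proteins yield []."""

    def __init__(self, hits: Iterable[DomainHit] = ()) -> None:
        self._hits: dict[str, list[DomainHit]] = {}
        for h in hits:
            self.add(h)

    def add(self, hit: DomainHit) -> None:
        self._hits.setdefault(hit.protein_id, []).append(hit)

    def hits(self, protein_id: str) -> list[DomainHit]:
        return list(self._hits.get(protein_id, ()))

    def accessions(self, protein_id: str) -> set[str]:
        return {h.accession for h in self._hits.get(protein_id, ())}

    def proteins(self) -> list[str]:
        return sorted(self._hits)

    def merge(self, other: "AnnotationTable") -> None:
        for hits in other._hits.values():
            for h in hits:
                self.add(h)

    def __len__(self) -> int:
        return sum(len(v) for v in self._hits.values())

    def __eq__(self, other: object) -> bool:
        return isinstance(other, AnnotationTable) and self._hits == other._hits


# ---------------------------------------------------------------------------
# GenBank I/O


def _conceptual_translation(dna: str) -> str:
    trimmed = dna[: len(dna) - len(dna) % 3]
    pep = str(Seq(trimmed).translate(table=11))
    pep = pep.rstrip("*")
    if "*" in pep:  # internal stop: annotation slop, keep up to it
        pep = pep.split("*", 1)[0]
    if pep:
        # bacterial start codons (ATG/GTG/TTG) all initiate with Met
        pep = "M" + pep[1:]
    return pep


def read_genbank(path) -> list[GenomeRecord]:
    """Read a (possibly multi-record) GenBank flat file into GenomeRecords.

    Coordinates are converted to 0-based half-open; ``complement(...)``
    features get strand -1.  Translations come from the ``/translation``
    qualifier when present, otherwise the CDS is conceptually translated
    with the bacterial code (table 11, first codon read as Met).
    """
    records: list[GenomeRecord] = []
    try:
        seq_records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # biopython raises assorted ValueError subclasses
        raise ParseError(f"{path}: malformed GenBank record: {exc}") from exc
    for rec in seq_records:
        try:
            seq = str(rec.seq).upper()
        except Exception:  # undefined sequence (e.g. CONTIG only)
            seq = ""
        features: list[GeneFeature] = []
        n = 0
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            n += 1
            start = int(feat.location.start)
            end = int(feat.location.end)
            strand = -1 if feat.location.strand == -1 else +1
            gene_id = (
                feat.qualifiers.get("locus_tag", [None])[0]
                or feat.qualifiers.get("protein_id", [None])[0]
                or f"{rec.id}_cds{n}"
            )
            product = feat.qualifiers.get("product", [""])[0]
            translation = feat.qualifiers.get("translation", [None])[0]
            if translation is None:
                cds_dna = seq[start:end]
                if not cds_dna or set(cds_dna) <= {"N"}:
                    log.warning(
                        "skipping CDS %s on %s: no sequence and no /translation",
                        gene_id, rec.id,
                    )
                    continue
                if strand == -1:
                    cds_dna = str(Seq(cds_dna).reverse_complement())
                translation = _conceptual_translation(cds_dna)
                if not translation:
                    log.warning("skipping CDS %s on %s: untranslatable", gene_id, rec.id)
                    continue
            try:
                features.append(
                    GeneFeature(gene_id=gene_id, start=start, end=end,
                                strand=strand, protein=translation, product_label=product)
                )
            except ValueError as exc:
                raise ParseError(f"{path}: locus {gene_id}: {exc}") from exc
        length = len(seq) if seq else (max((f.end for f in features), default=0))
        records.append(GenomeRecord(rec.id, length, seq, features))
    return records


def write_genbank(record: GenomeRecord, cluster_annotations, path, *,
                  annot: Optional[AnnotationTable] = None,
                  biosynthetic_accessions: Optional[set[str]] = None,
                  cluster_labels: Optional[dict[str, str]] = None) -> None:
    """Write a GenomeRecord, adding one ``cluster`` feature per called BGC.

    Each cluster feature spans the cluster boundary and carries our own
    qualifier names: ``cluster_id`` and ``product_class`` (family label from
    ``cluster_labels`` when given, else the cluster's partner class).  Genes
    whose domain hits intersect ``biosynthetic_accessions`` carry a
    ``biosynthetic`` marker qualifier.
    """
    seq = record.sequence or "N" * record.length_bp
    rec = SeqRecord(Seq(seq), id=record.contig_id, name=record.contig_id[:16],
                    description="", annotations={"molecule_type": "DNA"})
    cluster_labels = cluster_labels or {}
    for cluster in cluster_annotations:
        if not (0 <= cluster.start < cluster.end <= record.length_bp):
            raise ValueError(
                f"cluster {cluster.cluster_id} [{cluster.start}, {cluster.end}) "
                f"outside contig {record.contig_id}"
            )
        label = cluster_labels.get(cluster.cluster_id, getattr(cluster, "partner_class", ""))
        rec.features.append(SeqFeature(
            FeatureLocation(cluster.start, cluster.end, strand=cluster.strand),
            type="cluster",
            qualifiers={"cluster_id": [cluster.cluster_id], "product_class": [label]},
        ))
    for f in record.features:
        qualifiers = {"locus_tag": [f.gene_id], "translation": [f.protein]}
        if f.product_label:
            qualifiers["product"] = [f.product_label]
        if annot is not None and biosynthetic_accessions:
            if annot.accessions(f.gene_id) & biosynthetic_accessions:
                qualifiers["biosynthetic"] = ["true"]
        rec.features.append(SeqFeature(
            FeatureLocation(f.start, f.end, strand=f.strand),
            type="CDS", qualifiers=qualifiers,
        ))
    SeqIO.write([rec], str(path), "genbank")


def write_protein_fasta(records: Iterable[GenomeRecord], path) -> None:
    """Export every CDS translation (for external hmmsearch runs)."""
    with open(path, "w") as fh:
        for record in records:
            for gene_id, protein in record.proteins():
                fh.write(f">{gene_id}\n{protein}\n")


# ---------------------------------------------------------------------------
# Annotation tables

#: column counts of hmmsearch --domtblout: 22 mandatory + free-text description
_DOMTBL_MIN_COLS = 22


def read_domtblout(path) -> AnnotationTable:
    """Read hmmsearch per-domain tabular output (``--domtblout``).

    The query accession column supplies ``DomainHit.accession`` (falling back
    to the query name when it is '-'); the independent-domain e-value column
    supplies ``e_value``.
    """
    table = AnnotationTable()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split(None, _DOMTBL_MIN_COLS)
            if len(cols) < _DOMTBL_MIN_COLS:
                raise ParseError(f"{path}:{lineno}: expected >= {_DOMTBL_MIN_COLS} columns, "
                                 f"got {len(cols)}")
            accession = cols[4] if cols[4] != "-" else cols[3]
            try:
                table.add(DomainHit(
                    protein_id=cols[0],
                    accession=normalize_accession(accession),
                    bit_score=float(cols[13]),
                    e_value=float(cols[12]),
                    ali_from=int(cols[17]),
                    ali_to=int(cols[18]),
                ))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return table


def read_annotation_tsv(path) -> AnnotationTable:
    """Read a plain protein->accession table: protein_id, accession,
    bit_score [, e_value, ali_from, ali_to].

    Missing optional columns default to e-value 0 and a full-length
    alignment.  Duplicate rows are retained as duplicate hits.
    """
    table = AnnotationTable()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 columns, got {len(cols)}")
            try:
                table.add(DomainHit(
                    protein_id=cols[0],
                    accession=normalize_accession(cols[1]),
                    bit_score=float(cols[2]),
                    e_value=float(cols[3]) if len(cols) > 3 else 0.0,
                    ali_from=int(cols[4]) if len(cols) > 4 else None,
                    ali_to=int(cols[5]) if len(cols) > 5 else None,
                ))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return table


def write_annotation_tsv(table: AnnotationTable, path) -> None:
    with open(path, "w") as fh:
        for protein_id in table.proteins():
            for h in table.hits(protein_id):
                ali_from = h.ali_from if h.ali_from is not None else ""
                ali_to = h.ali_to if h.ali_to is not None else ""
                fh.write(f"{h.protein_id}\t{h.accession}\t{h.bit_score:g}"
                         f"\t{h.e_value:g}\t{ali_from}\t{ali_to}\n")


def write_domtblout(table: AnnotationTable, path, protein_lengths: dict[str, int]) -> None:
    """Emit an AnnotationTable in hmmsearch --domtblout layout (for I/O tests
    and for interchangeability with a real hmmsearch run)."""
    header = ("#                                                               --- full sequence ---"
              " -------------- this domain -------------   hmm coord   ali coord   env coord\n"
              "# target name        accession   tlen query name           accession   qlen"
              "   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to"
              "  from    to  from    to  acc description of target\n")
    with open(path, "w") as fh:
        fh.write(header)
        for protein_id in table.proteins():
            tlen = protein_lengths.get(protein_id, 0)
            for h in table.hits(protein_id):
                ali_from = h.ali_from if h.ali_from is not None else 1
                ali_to = h.ali_to if h.ali_to is not None else tlen
                fh.write(
                    f"{protein_id} - {tlen} {h.accession}_hmm {h.accession} 120 "
                    f"{h.e_value:.2g} {h.bit_score:.1f} 0.0 1 1 {h.e_value:.2g} "
                    f"{h.e_value:.2g} {h.bit_score:.1f} 0.0 1 120 {ali_from} {ali_to} "
                    f"{ali_from} {ali_to} 0.99 -\n"
                )
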