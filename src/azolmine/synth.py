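"""Synthetic annotated genomes with planted BGCs, decoys and ground truth.

Every pipeline stage is testable against genomes generated here: templates
encode the canonical azol(in)e-RiPP cluster architectures (klebsazolicin /
phazolicin / microcin-C style operons, lactazolicin, heterocycloanthracin,
McB-like with and without PRP, fused and split flavazolicin cassettes) plus
three decoy architectures that the filter stage must reject (thiopeptide
LanB carriers, invalid putative-YcaO seeds, partnerless YcaO genes).

Domain annotation is mocked with sentinels: each accession maps to a fixed
WW-containing peptide 12-mer embedded in the proteins that should carry the
domain.  All random residue pools exclude Trp, so a sentinel can never arise
by chance; a collision check asserts this at generation time.  The mock
annotator and a real hmmsearch run are interchangeable backends behind the
AnnotationTable contract (a domtblout-layout writer is provided).

Precursor generators plant exact repeat structure and are engineered so
that only true duplicated cores read as cassettes: repeat spacers follow
slot/letter schedules that mismatch at every repeat-compatible alignment
offset, cyclizable density is concentrated in short dense cores whose
self-overlap can never span the cassette detector's minimum length, and
each non-cassette leader carries a deliberate sub-threshold direct-repeat
decoy that dominates (and thereby suppresses) any spurious gap-assisted
self-alignment.  Precursor CDSs use antisense-safe codons for Ser/Thr/Cys
so the reverse-strand shadow of a dense core cannot itself score as a
precursor ORF.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field, asdict
from typing import Optional

from Bio.Data import CodonTable

from .seq_records import AnnotationTable, DomainHit, GeneFeature, GenomeRecord

# ---------------------------------------------------------------------------
# Sentinels

SENTINELS: dict[str, str] = {
    "TIGR03549": "WWAGYHQDLNRV",
    "TIGR03604": "WWADYHQELNRV",
    "PF02624": "WWAEYHQGLNRV",
    "YCAO_PUTATIVE": "WWAHYQDGLNRV",
    "PF00881": "WWDAYHQGLNRV",
    "TIGR03603": "WWDEYHQGLNRV",
    "TIGR04424": "WWDGYHQALNRV",
    "PF00899": "WWEAYHQGLNRV",
    "TIGR02354": "WWEDYHQGLNRV",
    "TIGR02356": "WWEGYHQALNRV",
    "TIGR03693": "WWEHYQAGLNRV",
    "TIGR03736": "WWFAYHQGLNRV",
    "TIGR03882": "WWFDYHQGLNRV",
    "PF14028": "WWGAYHQDLNRV",
    "PF04738": "WWGDYHQALNRV",
    "TIGR03897": "WWGEYHQALNRV",
    "PF05147": "WWGHYQADLNRV",
    "PF00805": "WWHAYQDGLNRV",
    "PF00005": "WWHDYQAGLNRV",
    "PF13437": "WWHEYQAGLNRV",
    "PF00082": "WWIAYHQGLNRV",
    "PF13365": "WWIDYHQGLNRV",
}

#: enzyme/background residue alphabet — no Trp, so sentinels cannot collide
ENZYME_POOL = "ACDEFGHIKLMNQRSTVY"
BACKGROUND_POOL = "ACDEFGHIKLMNPQRSTVY"
#: leader-peptide alphabet: no cyclizable residues, no Arg/Lys, no Trp/Pro
LEADER_POOL = "ADEFGHILMNQV"
NEUTRAL_POOL = "ADEFGHILMNQV"  # mutation replacements: never adds C/S/T/R/K/G

_TABLE = CodonTable.unambiguous_dna_by_id[11]
_CODONS: dict[str, list[str]] = {}
for codon, aa in sorted(_TABLE.forward_table.items()):
    _CODONS.setdefault(aa, []).append(codon)
_STOPS = sorted(_TABLE.stop_codons)


# ---------------------------------------------------------------------------
# Template specifications

@dataclass(frozen=True)
class TemplateGene:
    role: str
    accessions: tuple[str, ...] = ()
    length_aa: int = 300
    pxp: Optional[bool] = None  # True: C-terminal PxP; False: none; None: n/a
    precursor: bool = False


@dataclass
class TemplateSpec:
    """One cluster architecture: ordered gene roles, gap bounds, and the
    precursor generator the template uses."""

    name: str
    genes: list[TemplateGene]
    gap_bp: tuple[int, int] = (20, 80)
    expected_status: str = "passed"
    expected_family: str = "unclassified"
    precursor_kind: str = ""  # key into the precursor generators; "" = none


def _enz(role: str, accs: tuple[str, ...], length: int, pxp: Optional[bool] = None) -> TemplateGene:
    return TemplateGene(role, accs, length, pxp)


def _prec(role: str = "precursor") -> TemplateGene:
    return TemplateGene(role, (), 0, None, True)


TEMPLATES: dict[str, TemplateSpec] = {
    # klebsazolicin-style operon: precursor, E1, dehydrogenase, YcaO, exporter
    "klp_like": TemplateSpec("klp_like", [
        _prec(), _enz("C_e1", ("TIGR04424",), 420), _enz("B_dehydrogenase", ("PF00881",), 300),
        _enz("D_ycao", ("PF02624",), 450, pxp=True), _enz("E_transport", ("PF00005",), 360),
    ], expected_family="mcb_like_no_prp", precursor_kind="lap_core"),
    # phazolicin-style operon: exporter first
    "phz_like": TemplateSpec("phz_like", [
        _enz("E_transport", ("PF00005",), 360), _prec(), _enz("C_e1", ("TIGR04424",), 420),
        _enz("B_dehydrogenase", ("PF00881",), 300), _enz("D_ycao", ("PF02624",), 450, pxp=True),
    ], expected_family="mcb_like_no_prp", precursor_kind="lap_core"),
    # microcin-C-style six-gene operon; mccB (ThiF/E1-superfamily adenylating
    # enzyme) is the kind of protein a sensitive YcaO pre-search flags, so it
    # carries the permissive putative-YcaO mark and the cluster is called but
    # rejected as an invalid seed.
    "mcc_like": TemplateSpec("mcc_like", [
        _prec("mccA"), _enz("mccB_adenylase", ("PF00899", "YCAO_PUTATIVE"), 350),
        _enz("mccC_transport", ("PF13437",), 400), _enz("mccD_mtase", (), 260),
        _enz("mccE_acetyltransferase", (), 400), _enz("mccF_peptidase", (), 330),
    ], expected_status="rejected_invalid_seed", precursor_kind="mcc"),
    # lactazolicin architecture: E, C, B, D2, X1, D1, X2 (+ precursor);
    # D1 is the second YcaO lacking the C-terminal PxP motif.
    "lactazolicin": TemplateSpec("lactazolicin", [
        _prec(), _enz("E_transport", ("PF13437",), 370), _enz("C_e1", ("TIGR04424",), 430),
        _enz("B_dehydrogenase", (), 300), _enz("D2_ycao", ("PF02624",), 450, pxp=True),
        _enz("X1_unknown", (), 200), _enz("D1_ycao", ("TIGR03604",), 440, pxp=False),
        _enz("X2_rre", (), 380),
    ], expected_family="lactazolicin_like", precursor_kind="lactazolicin"),
    # heterocycloanthracin-like: ThiF partner, [Cxx]-repeat precursor
    "hca": TemplateSpec("hca", [
        _prec(), _enz("F_thif", ("TIGR03882",), 400),
        _enz("D_ycao", ("TIGR03549",), 450, pxp=True), _enz("T_transport", ("PF00005",), 360),
    ], expected_family="hca_like", precursor_kind="hca"),
    # microcin-B17-like with the PRP (gyrase-protecting) gene, order EBCDA[G]
    "mcb_with_prp": TemplateSpec("mcb_with_prp", [
        _enz("E_transport", ("PF00005",), 360), _enz("B_e1", ("TIGR04424",), 430),
        _enz("C_dehydrogenase", ("PF00881",), 300), _enz("D_ycao", ("PF02624",), 450, pxp=True),
        _prec("mcbA"), _enz("G_prp", ("PF00805",), 190),
    ], expected_family="mcb_like_with_prp", precursor_kind="mcb"),
    "mcb_no_prp": TemplateSpec("mcb_no_prp", [
        _enz("E_transport", ("PF13437",), 380), _enz("B_e1", ("TIGR03603",), 430),
        _enz("C_dehydrogenase", ("PF00881",), 300), _enz("D_ycao", ("PF02624",), 450, pxp=True),
        _prec("mcbA"),
    ], expected_family="mcb_like_no_prp", precursor_kind="mcb"),
    # flavazolicin: fused cassette precursor + extra protease
    "flavazolicin_fused": TemplateSpec("flavazolicin_fused", [
        _prec(), _enz("D_ycao", ("TIGR03604",), 450, pxp=True), _enz("C_e1", ("TIGR03603",), 430),
        _enz("B_dehydrogenase", (), 290), _enz("T_transport", ("PF00005",), 360),
        _enz("P_protease", ("PF00082",), 340),
    ], expected_family="flavazolicin_like", precursor_kind="flavazolicin_fused"),
    # flavazolicin split arrangement: separate single leader-core ORFs, no protease
    "flavazolicin_split": TemplateSpec("flavazolicin_split", [
        _prec("precursor_1"), _prec("precursor_2"),
        _enz("D_ycao", ("TIGR03604",), 450, pxp=True), _enz("C_e1", ("TIGR03603",), 430),
        _enz("B_dehydrogenase", (), 290), _enz("T_transport", ("PF00005",), 360),
    ], expected_family="unclassified", precursor_kind="single_core"),
    # decoys
    "thiopeptide_decoy": TemplateSpec("thiopeptide_decoy", [
        _enz("D_ycao", ("PF02624",), 450, pxp=True), _enz("F_thif", ("PF00899",), 400),
        _enz("lanB_dehydratase", ("PF14028",), 500),
    ], expected_status="rejected_lanB"),
    "invalid_ycao_decoy": TemplateSpec("invalid_ycao_decoy", [
        _enz("Y_putative", ("YCAO_PUTATIVE",), 420), _enz("C_e1", ("TIGR03603",), 430),
        _enz("T_transport", ("PF00005",), 360),
    ], expected_status="rejected_invalid_seed"),
    "partnerless_decoy": TemplateSpec("partnerless_decoy", [
        _enz("D_ycao", ("PF02624",), 450, pxp=True), _enz("T_transport", ("PF00005",), 360),
        _enz("U_unknown", (), 280),
    ], expected_status="rejected_no_partner"),
}

BENCHMARK_FAMILIES = ["lactazolicin", "hca", "mcb_with_prp", "mcb_no_prp", "flavazolicin_fused"]


def template_spec(name: str) -> TemplateSpec:
    if name not in TEMPLATES:
        raise ValueError(f"unknown template {name!r}; known: {sorted(TEMPLATES)}")
    spec = TEMPLATES[name]
    return TemplateSpec(spec.name, list(spec.genes), spec.gap_bp,
                        spec.expected_status, spec.expected_family, spec.precursor_kind)


# ---------------------------------------------------------------------------
# Precursor generators

def _multiset(rng: random.Random, length: int, weights: dict[str, float],
              rest_pool: str) -> list[str]:
    """A residue multiset realizing the weighted composition exactly
    (rounded), so enrichment fractions do not fluctuate between draws."""
    out: list[str] = []
    for aa, w in sorted(weights.items()):
        out.extend(aa * round(w * length))
    while len(out) < length:
        out.append(rng.choice(rest_pool))
    del out[length:]
    return out


def _constrained_stream(rng: random.Random, pool: list[str],
                        ban_back: range) -> list[str]:
    """Arrange a residue multiset so that no residue equals the residue
    ``j`` positions back for any ``j`` in ``ban_back``.  This removes the
    periodic self-matches that would otherwise let a repeat-rich segment
    read as a duplicated cassette.  When every remaining residue is banned
    (rare), one is placed anyway."""
    remaining = list(pool)
    rng.shuffle(remaining)
    out: list[str] = []
    for _ in range(len(pool)):
        banned = {out[-j] for j in ban_back if j <= len(out)}
        idx = next((i for i, aa in enumerate(remaining) if aa not in banned), 0)
        out.append(remaining.pop(idx))
    return out


def _leader(rng: random.Random, lo: int, hi: int) -> str:
    return "M" + "".join(rng.choice(LEADER_POOL) for _ in range(rng.randint(lo, hi) - 1))


#: alphabets of the sub-threshold self-alignment decoy planted in the
#: leaders of non-cassette precursors: a 10-mer direct repeat at offset 15
#: (best self-alignment score 20 over 10 < 15 columns) whose mid segment
#: uses letters reserved for it alone, so the alignment cannot extend in
#: either direction.  The decoy outscores any spurious gap-assisted
#: self-alignment elsewhere in the peptide, which keeps the cassette call
#: deterministically negative for non-cassette templates.
_TWIN_ALPHABET = "AFGHMN"
_TWIN_MID = "QVIL"  # reserved: appears nowhere else in planted precursors
_PAD_POOL = "DEPY"  # 4 letters: pad self-alignments drift negative
#: filler alphabet for dense cores, repeat spacers and linkers; disjoint
#: from the decoy mid letters
_SAFE_FILL = "ADEGHN"


def _decoy_leader(rng: random.Random, length: int) -> str:
    """Leader of exactly ``length`` residues ending in the repeat decoy."""
    if length < 34:
        raise ValueError("decoy leader needs >= 34 residues")
    copy = "".join(rng.choice(_TWIN_ALPHABET) for _ in range(10))
    block = (copy + "".join(rng.choice(_TWIN_MID) for _ in range(5)) + copy
             + "".join(rng.choice("AH") for _ in range(5)))
    pad = "".join(rng.choice(_PAD_POOL) for _ in range(length - 1 - len(block)))
    return "M" + pad + block


#: letter schedule for the single cyclizable spacer of each repeat: any two
#: repeats whose spacers can align under a detector-range offset get
#: different letters (r and r+6 differ by 2 mod 4 -> S vs T)
_SPACER_LETTERS = "STTS"


def _dense_core(rng: random.Random, length: int, letter: str, n_c: int = 0) -> str:
    """A short cyclizable-dense core: ~5/6 of positions hold ``letter``
    (plus optional sparse Cys), the rest random filler.  Kept at <= 28
    residues by callers so an off-diagonal self-alignment can never span 15
    columns, whatever its identity."""
    phase = rng.randrange(6)
    out = [rng.choice(_SAFE_FILL) if i % 6 == phase else letter
           for i in range(length)]
    if n_c:
        # Cys 9 apart: never on a stride-3 or stride-4 chain
        for p in range(2, length, 9):
            if out[p] == letter and n_c > 0:
                out[p] = "C"
                n_c -= 1
    return "".join(out)


def _lact_span(rng: random.Random, k: int) -> str:
    """k exact [Cxxx] repeats.  Each spacer triplet holds one cyclizable
    residue at slot r mod 3 with letter _SPACER_LETTERS[r mod 4] and two
    Arg/Lys-enriched fillers from an anti-match stream, so self-alignments
    at any offset the cassette detector can see keep identity <= 1/4."""
    n_fill = 2 * (k - 1)
    pool = _multiset(rng, n_fill, {"R": 0.2, "K": 0.2}, _SAFE_FILL)
    fillers = _constrained_stream(rng, pool, range(8, 15))
    fi = 0
    span: list[str] = []
    for r in range(k):
        span.append("C")
        if r == k - 1:
            break
        triplet = [None, None, None]
        triplet[r % 3] = _SPACER_LETTERS[r % 4]
        for s in range(3):
            if triplet[s] is None:
                triplet[s] = fillers[fi]
                fi += 1
        span.extend(triplet)
    return "".join(span)


def _hca_span(rng: random.Random, k: int) -> str:
    """k exact [Cxx] repeats; each spacer pair holds one Gly (slot 1 - r%2)
    and one cyclizable residue (slot r%2, letter by the same schedule).
    Callers keep k <= 10 so the span (<= 28 aa) cannot self-align over 15
    columns."""
    span: list[str] = []
    for r in range(k):
        span.append("C")
        if r == k - 1:
            break
        pair = ["G", "G"]
        pair[r % 2] = _SPACER_LETTERS[r % 4]
        span.extend(pair)
    return "".join(span)


def _leader_mutable(leader: str) -> list[int]:
    return list(range(1, len(leader)))


def _pad_mutable(leader: str) -> list[int]:
    """Mutable positions of a decoy leader: the pad only, so within-family
    mutations can never degrade the planted self-alignment decoy."""
    return list(range(1, max(1, len(leader) - 30)))


def _gen_lactazolicin(rng: random.Random) -> tuple[str, dict]:
    """83-106 aa precursor: long leader, then 8-12 exact [Cxxx] repeats
    (the N-terminal part of the core) with Arg/Lys-enriched spacers, then a
    short Thr-dense C-terminal core."""
    k = rng.randint(8, 12)
    span = _lact_span(rng, k)
    core_b = _dense_core(rng, 16, "T")
    total = rng.randint(max(83, len(span) + 16 + 35), 106)
    leader = _decoy_leader(rng, total - len(span) - 16)
    peptide = leader + span + core_b
    span_iv = (len(leader), len(leader) + len(span))
    return peptide, {
        "kind": "lactazolicin", "planted_period4": k, "period4_span": span_iv,
        "cassette": False, "mutable_positions": _pad_mutable(leader),
    }


def _gen_hca(rng: random.Random) -> tuple[str, dict]:
    """Heterocycloanthracin-like precursor: [Cxx] repeats with Gly-bearing
    spacers, then a linker and a Thr-dense C-terminal core.  The repeat
    count is capped at 10 so the span stays below cassette-alignable size."""
    k = rng.randint(7, 10)
    span = _hca_span(rng, k)
    linker = "".join(rng.choice(_SAFE_FILL) for _ in range(6))
    core_b = _dense_core(rng, 16, "T")
    total = rng.randint(max(78, len(span) + 22 + 35), 100)
    leader = _decoy_leader(rng, total - len(span) - 22)
    peptide = leader + span + linker + core_b
    span_iv = (len(leader), len(leader) + len(span))
    return peptide, {
        "kind": "hca", "planted_period3": k, "period3_span": span_iv,
        "cassette": False, "mutable_positions": _pad_mutable(leader),
    }


def _gen_mcb(rng: random.Random) -> tuple[str, dict]:
    """McbA-like precursor: long leader, then a Ser-dense core (with sparse
    Cys) and a Thr-dense core separated by a linker.  The two cores use
    disjoint cyclizable alphabets, so they never read as a duplication."""
    leader = _decoy_leader(rng, rng.randint(34, 40))
    core_s = _dense_core(rng, rng.randint(16, 18), "S", n_c=3)
    linker = "".join(rng.choice(_SAFE_FILL) for _ in range(rng.randint(8, 10)))
    core_t = _dense_core(rng, rng.randint(16, 18), "T")
    peptide = leader + core_s + linker + core_t
    return peptide, {"kind": "mcb", "cassette": False,
                     "mutable_positions": _pad_mutable(leader)}


def _gen_core(rng: random.Random, length: int) -> str:
    core = _multiset(rng, length, {"S": 0.38, "C": 0.20, "T": 0.14, "G": 0.06},
                     "ADENQHV")
    rng.shuffle(core)
    return "".join(core)


def _gen_flava_fused(rng: random.Random) -> tuple[str, dict]:
    """Cassette precursor: leader + core + internal leader + mutated
    duplicate core (two Ser/Cys-rich putative core sequences)."""
    leader = _leader(rng, 10, 14)
    core_len = rng.randint(36, 40)
    core1 = _gen_core(rng, core_len)
    internal_res = _multiset(rng, rng.randint(10, 14), {"S": 0.25, "T": 0.15}, LEADER_POOL)
    rng.shuffle(internal_res)
    internal = "".join(internal_res)
    core2 = list(core1)
    for i in range(len(core2)):
        if rng.random() < 0.10:
            core2[i] = rng.choice("ADENQHV")
    peptide = leader + core1 + internal + "".join(core2)
    mutable = _leader_mutable(leader)
    return peptide, {
        "kind": "flavazolicin_fused", "cassette": True,
        "core_offsets": [[len(leader), len(leader) + core_len],
                         [len(leader) + core_len + len(internal), len(peptide)]],
        "mutable_positions": mutable,
    }


def _gen_single_core(rng: random.Random) -> tuple[str, dict]:
    leader = _decoy_leader(rng, rng.randint(34, 38))
    core = _dense_core(rng, rng.randint(22, 26), "S", n_c=3)
    peptide = leader + core
    return peptide, {"kind": "single_core", "cassette": False,
                     "mutable_positions": _pad_mutable(leader)}


def _gen_lap_core(rng: random.Random) -> tuple[str, dict]:
    """Klebsazolicin/phazolicin-style precursor: every third core residue
    cyclizable."""
    leader = _decoy_leader(rng, rng.randint(34, 40))
    # 24-27 aa core, matching the short cores of this compound class; also
    # below the size at which a core could self-align over 15 columns
    core_len = 3 * rng.randint(8, 9)
    core = []
    for i in range(core_len):
        if i % 3 == 2:
            core.append(rng.choice("CSCT"))  # half Cys, rest Ser/Thr
        else:
            core.append(rng.choice(_SAFE_FILL))
    peptide = leader + "".join(core)
    return peptide, {"kind": "lap_core", "cassette": False,
                     "mutable_positions": _pad_mutable(leader)}


def _gen_mcc(rng: random.Random) -> tuple[str, dict]:
    # the seven-residue microcin C precursor peptide
    return "MRTGNAN", {"kind": "mcc", "cassette": False, "mutable_positions": []}


_GENERATORS = {
    "lactazolicin": _gen_lactazolicin,
    "hca": _gen_hca,
    "mcb": _gen_mcb,
    "flavazolicin_fused": _gen_flava_fused,
    "single_core": _gen_single_core,
    "lap_core": _gen_lap_core,
    "mcc": _gen_mcc,
}


def make_precursor(spec, rng_seed: int) -> tuple[str, dict]:
    """Generate the precursor peptide for a template (by TemplateSpec or
    name) plus its planted motif truths."""
    name = spec.precursor_kind if isinstance(spec, TemplateSpec) else spec
    if isinstance(spec, str) and spec in TEMPLATES:
        name = TEMPLATES[spec].precursor_kind
    if name not in _GENERATORS:
        raise ValueError(f"template has no precursor generator: {name!r}")
    return _GENERATORS[name](random.Random(rng_seed))


def mutate_precursor(peptide: str, truths: dict, rate: float,
                     rng: random.Random) -> str:
    """Apply point substitutions at the generator-declared mutable positions
    (never inside a planted repeat span, never introducing C/S/T/W), so the
    planted motif truths stay valid."""
    out = list(peptide)
    pool = truths.get("mutation_pool", NEUTRAL_POOL)
    for i in truths.get("mutable_positions", []):
        if rng.random() < rate:
            choices = [aa for aa in pool if aa != out[i]]
            out[i] = rng.choice(choices)
    return "".join(out)


# ---------------------------------------------------------------------------
# Genome assembly

@dataclass
class PlantedClusterTruth:
    template: str
    contig_id: str
    start: int
    end: int
    strand: int
    gene_roles: dict[str, str]
    precursor_interval: Optional[tuple[int, int]]
    precursor_peptide: Optional[str]
    precursor_truths: dict
    expected_status: str
    expected_family: str
    family_id: int = -1


@dataclass
class GroundTruth:
    clusters: list[PlantedClusterTruth] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({"clusters": [asdict(c) for c in self.clusters]},
                          indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        data = json.loads(text)
        clusters = []
        for c in data["clusters"]:
            c["precursor_interval"] = (tuple(c["precursor_interval"])
                                       if c["precursor_interval"] else None)
            clusters.append(PlantedClusterTruth(**c))
        return cls(clusters)


def _random_protein(rng: random.Random, length: int, pool: str) -> list[str]:
    return [rng.choice(pool) for _ in range(length)]


def _enzyme_protein(gene: TemplateGene, rng: random.Random) -> str:
    body = _random_protein(rng, gene.length_aa, ENZYME_POOL)
    body[0] = "M"
    pos = 20
    for acc in gene.accessions:
        sentinel = SENTINELS[acc]
        body[pos:pos + len(sentinel)] = sentinel
        pos += len(sentinel) + 8
    if gene.pxp is True:
        body[-3:] = "PVP"
    elif gene.pxp is False:
        # keep the C-terminal window clear of any Pro-x-Pro
        tail_pool = ENZYME_POOL
        body[-10:] = [rng.choice(tail_pool) for _ in range(10)]
    return "".join(body)


#: codons whose reverse-complement frames translate without Ser/Thr/Cys;
#: used for precursor CDSs so the antisense "shadow" of a cyclizable-dense
#: core cannot itself read as a high-scoring precursor ORF
_SHADOW_SAFE_CODONS = {"S": "TCC", "T": "ACC", "C": "TGC", "G": "GGG"}


def _back_translate(protein: str, rng: random.Random, shadow_safe: bool = False) -> str:
    dna = []
    for i, aa in enumerate(protein):
        if aa == "M" and i == 0:
            dna.append(_CODONS[aa][0])
        elif shadow_safe and aa in _SHADOW_SAFE_CODONS:
            dna.append(_SHADOW_SAFE_CODONS[aa])
        else:
            dna.append(rng.choice(_CODONS[aa]))
    dna.append(rng.choice(_STOPS))
    return "".join(dna)


def _revcomp(dna: str) -> str:
    return dna.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


#: minimum distance between planted clusters so their 12.5 kbp neighborhoods
#: never overlap and filters cannot cross-contaminate
CLUSTER_SPACING_BP = 13_000


def mock_annotate(genome: GenomeRecord) -> AnnotationTable:
    """Scan CDS translations for accession sentinels; the mock stand-in for
    an hmmsearch run over the same proteins."""
    table = AnnotationTable()
    for gene_id, protein in genome.proteins():
        for acc in sorted(SENTINELS):
            idx = protein.find(SENTINELS[acc])
            if idx >= 0:
                e_value = 1e-8 if acc == "YCAO_PUTATIVE" else 1e-30
                table.add(DomainHit(gene_id, acc, 150.0, e_value,
                                    idx + 1, idx + len(SENTINELS[acc])))
    return table


def _check_sentinels(proteins: dict[str, str], assigned: dict[str, set[str]]) -> None:
    for gene_id, protein in proteins.items():
        for acc, sentinel in SENTINELS.items():
            if sentinel in protein and acc not in assigned.get(gene_id, set()):
                raise AssertionError(f"sentinel collision: {acc} in {gene_id}")


def make_genome(templates, n_background_genes: int = 8, rng_seed: int = 0,
                contig_id: str = "synth_contig",
                precursor_overrides: Optional[dict[int, tuple[str, dict]]] = None,
                ) -> tuple[GenomeRecord, AnnotationTable, GroundTruth]:
    """Assemble one contig carrying the given templates plus background genes.

    ``precursor_overrides`` maps template index -> (peptide, truths) to plant
    a pre-generated precursor (used by the family benchmark for controlled
    within-family divergence).  Deterministic under (arguments, rng_seed).
    """
    rng = random.Random(rng_seed)
    specs = [template_spec(t) if isinstance(t, str) else t for t in templates]
    precursor_overrides = precursor_overrides or {}

    # realize background genes
    background: list[tuple[str, int]] = []
    for _ in range(n_background_genes):
        length = int(round(math.exp(rng.uniform(math.log(100), math.log(400)))))
        protein = "".join(_random_protein(rng, length, BACKGROUND_POOL))
        background.append(("M" + protein[1:], rng.choice((1, -1))))

    # realize template genes
    planted = []
    for t_idx, spec in enumerate(specs):
        strand = rng.choice((1, -1))
        genes = []
        precursor_info = None
        for gene in spec.genes:
            if gene.precursor:
                if t_idx in precursor_overrides:
                    peptide, truths = precursor_overrides[t_idx]
                else:
                    peptide, truths = make_precursor(spec, rng.getrandbits(31))
                genes.append((gene.role, peptide, (), True))
                precursor_info = (gene.role, peptide, truths)
            else:
                genes.append((gene.role, _enzyme_protein(gene, rng), gene.accessions, False))
        planted.append((spec, strand, genes, precursor_info))

    # interleave: background genes between and around clusters
    per_slot = max(1, n_background_genes // (len(specs) + 1)) if specs else n_background_genes
    layout: list[tuple[str, object]] = []
    bg_iter = iter(background)
    for spec_item in planted:
        for _ in range(per_slot):
            nxt = next(bg_iter, None)
            if nxt is not None:
                layout.append(("background", nxt))
        layout.append(("cluster", spec_item))
    for nxt in bg_iter:
        layout.append(("background", nxt))

    chunks: list[str] = []
    cursor = 0
    features: list[GeneFeature] = []
    truth = GroundTruth()
    assigned: dict[str, set[str]] = {}
    proteins: dict[str, str] = {}
    gene_counter = 0
    last_cluster_end = -CLUSTER_SPACING_BP

    def _emit_gap(length: int) -> None:
        nonlocal cursor
        chunks.append(_random_dna(rng, length))
        cursor += length

    def _emit_gene(gene_id: str, protein: str, strand: int, guard: bool) -> tuple[int, int]:
        """Place one gene at the cursor; guard=True brackets the CDS with
        in-frame stop codons so the ORF scanner recovers its exact interval."""
        nonlocal cursor
        dna = _back_translate(protein, rng, shadow_safe=guard)
        if strand == -1:
            dna = _revcomp(dna)
        if guard:
            # upstream (in transcription order) in-frame stop
            if strand == 1:
                chunks.append("TAA")
            else:
                chunks.append(_random_dna(rng, 3))
            cursor += 3
        start = cursor
        chunks.append(dna)
        cursor += len(dna)
        end = cursor
        if guard:
            chunks.append("TTA" if strand == -1 else _random_dna(rng, 3))
            cursor += 3
        features.append(GeneFeature(gene_id, start, end, strand, protein))
        proteins[gene_id] = protein
        return start, end

    _emit_gap(rng.randint(400, 800))
    for kind, item in layout:
        if kind == "background":
            protein, strand = item
            gene_counter += 1
            _emit_gene(f"{contig_id}_{gene_counter:03d}", protein, strand, guard=False)
            _emit_gap(rng.randint(300, 800))
            continue
        spec, strand, genes, precursor_info = item
        if cursor < last_cluster_end + CLUSTER_SPACING_BP:
            _emit_gap(last_cluster_end + CLUSTER_SPACING_BP - cursor)
        gene_roles: dict[str, str] = {}
        boundary_start = None
        precursor_interval = None
        for i, (role, protein, accs, is_precursor) in enumerate(genes):
            gene_counter += 1
            gene_id = f"{contig_id}_{gene_counter:03d}"
            s, e = _emit_gene(gene_id, protein, strand, guard=is_precursor)
            gene_roles[gene_id] = role
            assigned[gene_id] = set(accs)
            if boundary_start is None:
                boundary_start = s
            boundary_end = e
            if is_precursor and precursor_info and role == precursor_info[0]:
                precursor_interval = (s, e)
            if i < len(genes) - 1:
                _emit_gap(rng.randint(*spec.gap_bp))
        last_cluster_end = cursor
        truth.clusters.append(PlantedClusterTruth(
            template=spec.name, contig_id=contig_id,
            start=boundary_start, end=boundary_end, strand=strand,
            gene_roles=gene_roles,
            precursor_interval=precursor_interval,
            precursor_peptide=precursor_info[1] if precursor_info else None,
            precursor_truths=precursor_info[2] if precursor_info else {},
            expected_status=spec.expected_status,
            expected_family=spec.expected_family,
        ))
        _emit_gap(rng.randint(300, 800))
    _emit_gap(rng.randint(400, 800))

    sequence = "".join(chunks)
    genome = GenomeRecord(contig_id, len(sequence), sequence, features)
    _check_sentinels(proteins, assigned)
    return genome, mock_annotate(genome), truth


def make_benchmark(n_per_family: int = 20, rng_seed: int = 7
                   ) -> tuple[list[tuple[GenomeRecord, AnnotationTable]], GroundTruth]:
    """The five-family classification/network benchmark: ``n_per_family``
    single-cluster genomes per family, within-family precursors diverged at
    a 10 % point-substitution rate from a family base precursor."""
    if n_per_family < 1:
        raise ValueError("n_per_family must be >= 1")
    genomes: list[tuple[GenomeRecord, AnnotationTable]] = []
    truth = GroundTruth()
    for fam_id, fam in enumerate(BENCHMARK_FAMILIES):
        base_seed = (rng_seed * 1009 + fam_id * 101) % (2 ** 31)
        base_peptide, base_truths = make_precursor(template_spec(fam), base_seed)
        for i in range(n_per_family):
            inst_rng = random.Random((base_seed + 7919 * (i + 1)) % (2 ** 31))
            peptide = mutate_precursor(base_peptide, base_truths, 0.10, inst_rng)
            genome, annot, g_truth = make_genome(
                [fam], n_background_genes=6,
                rng_seed=(rng_seed * 131071 + fam_id * 131 + i) % (2 ** 31),
                contig_id=f"{fam}_{i:02d}",
                precursor_overrides={0: (peptide, base_truths)},
            )
            for c in g_truth.clusters:
                c.family_id = fam_id
            genomes.append((genome, annot))
            truth.clusters.extend(g_truth.clusters)
    return genomes, truth
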