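"""Repeat, composition and cassette features of precursor peptides, and the
rule table assigning candidate clusters to sequence-pattern families.

The families are defined by diagnostic precursor features combined with the
cluster's gene complement:

* lactazolicin-like — E1-partnered clusters whose precursor carries a long
  run of Cys at stride 4 (the [Cxxx] motif) in an Arg/Lys-enriched segment;
* HCA-like (heterocycloanthracin) — ThiF-partnered clusters with a Cys
  stride-3 run ([Cxx]) in a glycine-rich segment;
* McB-like — E1-partnered clusters with the microcin-B17 gene complement
  (YcaO + E1 + dehydrogenase + transporter), split by the presence of a
  pentapeptide-repeat-protein (PRP) gene;
* flavazolicin-like — precursors carrying a duplicated core cassette
  (two similar Ser/Cys-rich segments separated by an internal leader).

Labels are sequence-pattern families only; no claim about bioactivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .mining import CandidateCluster

Interval = tuple[int, int]


@dataclass
class MotifConfig:
    """Operational thresholds for 'enriched'/'rich' and the repeat minima.

    All values are reported in the FamilyCall evidence so the decision is
    auditable; none comes from a published cutoff.
    """

    min_period4_repeats: int = 8
    min_period3_repeats: int = 5
    rk_min: float = 0.15
    rk_ratio: float = 1.5
    gly_min: float = 0.25
    cassette_min_offset: int = 15
    cassette_min_len: int = 15
    cassette_min_identity: float = 0.4


@dataclass
class MotifProfile:
    peptide: str
    period4_repeat_count: int
    period4_span: Optional[Interval]
    period3_repeat_count: int
    period3_span: Optional[Interval]
    rk_fraction_in_span: float
    rk_fraction_outside: float
    gly_fraction_in_span: float
    cassette: bool
    cassette_identity: float
    cassette_offsets: Optional[tuple[Interval, Interval]]


@dataclass
class FamilyCall:
    cluster_id: str
    label: str
    evidence: list[tuple[str, float, float]] = field(default_factory=list)


def max_stride_chain(peptide: str, stride: int, residue: str = "C") -> tuple[int, Optional[Interval]]:
    """Longest arithmetic chain of ``residue`` at the given stride.

    A chain is a maximal set of positions p, p+stride, p+2*stride, ... all
    holding ``residue``; the count is the number of occurrences and the span
    is [first, last+1).  Ties go to the leftmost chain; count 0 -> span None.
    """
    if stride < 2:
        raise ValueError("stride must be >= 2")
    best_count, best_span = 0, None
    n = len(peptide)
    for i in range(n):
        if peptide[i] != residue:
            continue
        if i - stride >= 0 and peptide[i - stride] == residue:
            continue  # not a chain start
        count = 1
        last = i
        while last + stride < n and peptide[last + stride] == residue:
            last += stride
            count += 1
        if count > best_count:
            best_count, best_span = count, (i, last + 1)
    return best_count, best_span


def composition_fractions(peptide: str, span: Optional[Interval]) -> tuple[float, float, float]:
    """(Arg+Lys fraction inside span, outside span, Gly fraction inside)."""
    if span is None or span[0] >= span[1]:
        return 0.0, 0.0, 0.0
    lo, hi = span
    if not (0 <= lo < hi <= len(peptide)):
        raise ValueError("span outside peptide")
    inside = peptide[lo:hi]
    outside = peptide[:lo] + peptide[hi:]
    rk_in = sum(1 for aa in inside if aa in "RK") / len(inside)
    rk_out = (sum(1 for aa in outside if aa in "RK") / len(outside)) if outside else 0.0
    gly_in = inside.count("G") / len(inside)
    return rk_in, rk_out, gly_in


def local_align(a: str, b: str, match: int = 2, mismatch: int = -1,
                gap: int = -2, min_diag_offset: int = 0
                ) -> tuple[int, float, Interval, Interval]:
    """Smith-Waterman local alignment with a linear gap penalty.

    Traceback is deterministic: the maximum cell is the first in row-major
    order, and ties during traceback prefer diagonal, then up (gap in b),
    then left (gap in a).  ``min_diag_offset`` zeroes all cells with
    |i - j| < offset, which restricts self-alignments to off-diagonal
    (repeat-detecting) solutions.  Identity is matches / alignment columns
    (gap columns included); the empty alignment has identity 0.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    m, n = len(a), len(b)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    best, bi, bj = 0, 0, 0
    for i in range(1, m + 1):
        row = H[i]
        prev = H[i - 1]
        ai = a[i - 1]
        for j in range(1, n + 1):
            if min_diag_offset and abs(i - j) < min_diag_offset:
                continue
            s = match if ai == b[j - 1] else mismatch
            v = prev[j - 1] + s
            up = prev[j] + gap
            if up > v:
                v = up
            left = row[j - 1] + gap
            if left > v:
                v = left
            if v > 0:
                row[j] = v
                if v > best:
                    best, bi, bj = v, i, j
    if best == 0:
        return 0, 0.0, (0, 0), (0, 0)
    i, j = bi, bj
    matches = columns = 0
    while i > 0 and j > 0 and H[i][j] > 0:
        s = match if a[i - 1] == b[j - 1] else mismatch
        if H[i][j] == H[i - 1][j - 1] + s:
            if a[i - 1] == b[j - 1]:
                matches += 1
            columns += 1
            i, j = i - 1, j - 1
        elif H[i][j] == H[i - 1][j] + gap:
            columns += 1
            i -= 1
        elif H[i][j] == H[i][j - 1] + gap:
            columns += 1
            j -= 1
        else:  # alignment start (cell equals s > 0 from zero)
            if a[i - 1] == b[j - 1]:
                matches += 1
            columns += 1
            i, j = i - 1, j - 1
            break
    identity = matches / columns if columns else 0.0
    return best, identity, (i, bi), (j, bj)


def detect_cassette(peptide: str, min_offset: int = 15, min_len: int = 15,
                    min_identity: float = 0.4) -> tuple[bool, float, Optional[tuple[Interval, Interval]]]:
    """Detect a duplicated core cassette via off-diagonal local self-alignment.

    Returns (cassette, identity, (earlier interval, later interval)); a
    cassette requires an alignment of at least ``min_len`` columns at
    identity >= ``min_identity`` whose two copies are offset by at least
    ``min_offset`` residues.
    """
    if len(peptide) < 2 * min_len:
        return False, 0.0, None
    score, identity, ia, ib = local_align(peptide, peptide, min_diag_offset=min_offset)
    if score == 0:
        return False, 0.0, None
    aligned_len = max(ia[1] - ia[0], ib[1] - ib[0])
    offsets = tuple(sorted([ia, ib]))
    is_cassette = aligned_len >= min_len and identity >= min_identity
    return is_cassette, identity, offsets


def compute_profile(peptide: str, cfg: Optional[MotifConfig] = None) -> MotifProfile:
    """All motif features of one precursor peptide.

    Arg/Lys fractions are taken over the [Cxxx] (stride 4) span, the Gly
    fraction over the [Cxx] (stride 3) span, matching the segments each
    enrichment diagnoses.  Repeats are computed over the whole precursor
    (no leader/core split is presumed); the spans are reported instead.
    """
    cfg = cfg or MotifConfig()
    p4_count, p4_span = max_stride_chain(peptide, 4, "C")
    p3_count, p3_span = max_stride_chain(peptide, 3, "C")
    rk_in, rk_out, _ = composition_fractions(peptide, p4_span)
    _, _, gly_in = composition_fractions(peptide, p3_span)
    cassette, cassette_identity, offsets = detect_cassette(
        peptide, cfg.cassette_min_offset, cfg.cassette_min_len, cfg.cassette_min_identity)
    return MotifProfile(
        peptide=peptide,
        period4_repeat_count=p4_count, period4_span=p4_span,
        period3_repeat_count=p3_count, period3_span=p3_span,
        rk_fraction_in_span=rk_in, rk_fraction_outside=rk_out,
        gly_fraction_in_span=gly_in,
        cassette=cassette, cassette_identity=cassette_identity,
        cassette_offsets=offsets,
    )


def classify_family(profile: MotifProfile, cluster: CandidateCluster,
                    cfg: Optional[MotifConfig] = None) -> FamilyCall:
    """First-match decision table over (MotifProfile, cluster flags, partner).

    1. cassette -> flavazolicin_like
    2. E1 partner, [Cxxx] repeats >= 8, Arg/Lys-enriched span -> lactazolicin_like
    3. ThiF partner, [Cxx] repeats >= 5, Gly-rich span -> hca_like
    4. E1 partner + PRP gene -> mcb_like_with_prp
    5. E1 partner + McB gene complement, no PRP -> mcb_like_no_prp
    6. otherwise unclassified

    Every criterion consulted is recorded in the evidence list as
    (criterion, value, threshold).
    """
    cfg = cfg or MotifConfig()
    flags = cluster.flags
    has_e1 = cluster.partner_class in ("E1", "both")
    has_thif = cluster.partner_class in ("ThiF", "both")
    rk_threshold = max(cfg.rk_min, cfg.rk_ratio * profile.rk_fraction_outside)
    mcb_complement = (flags.get("n_ycao_genes", 0) >= 1 and has_e1
                      and flags.get("has_dehydrogenase", False)
                      and flags.get("has_transporter", False))
    evidence = [
        ("cassette", float(profile.cassette), 1.0),
        ("cassette_identity", profile.cassette_identity, cfg.cassette_min_identity),
        ("partner_E1", float(has_e1), 1.0),
        ("partner_ThiF", float(has_thif), 1.0),
        ("period4_repeat_count", float(profile.period4_repeat_count), float(cfg.min_period4_repeats)),
        ("rk_fraction_in_span", profile.rk_fraction_in_span, rk_threshold),
        ("period3_repeat_count", float(profile.period3_repeat_count), float(cfg.min_period3_repeats)),
        ("gly_fraction_in_span", profile.gly_fraction_in_span, cfg.gly_min),
        ("has_prp", float(flags.get("has_prp", False)), 1.0),
        ("mcb_complement", float(mcb_complement), 1.0),
        ("precursor_length_aa", float(len(profile.peptide)), 0.0),
    ]
    if profile.cassette:
        label = "flavazolicin_like"
    elif (has_e1 and profile.period4_repeat_count >= cfg.min_period4_repeats
          and profile.rk_fraction_in_span >= rk_threshold):
        label = "lactazolicin_like"
    elif (has_thif and profile.period3_repeat_count >= cfg.min_period3_repeats
          and profile.gly_fraction_in_span >= cfg.gly_min):
        label = "hca_like"
    elif has_e1 and flags.get("has_prp", False):
        label = "mcb_like_with_prp"
    elif has_e1 and mcb_complement:
        label = "mcb_like_no_prp"
    else:
        label = "unclassified"
    return FamilyCall(cluster_id=cluster.cluster_id, label=label, evidence=evidence)


def write_family_tsv(calls: list[FamilyCall], path) -> None:
    """Tabular family report: cluster_id, label, every evidence triple."""
    with open(path, "w") as fh:
        fh.write("cluster_id\tlabel\tcriterion\tvalue\tthreshold\n")
        for call in calls:
            for criterion, value, threshold in call.evidence:
                fh.write(f"{call.cluster_id}\t{call.label}\t{criterion}"
                         f"\t{value:.4g}\t{threshold:.4g}\n")
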