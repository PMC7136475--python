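# Methods

This note documents the models and procedures implemented in `azolmine`,
the parameters that matter, the design of the synthetic benchmark, and the
numerical conventions — in enough detail that every choice can be audited
or changed.

## Mining model

The pipeline assumes annotated bacterial contigs (CDS features with
translations) and a protein→domain-accession table (hmmsearch
`--domtblout`, plain TSV, or the synthetic sentinel annotator).  Azoline
chemistry requires a YcaO cyclodehydratase plus a precursor-recognition
partner, so mining is seeded on YcaO domains and filtered on partner
presence:

* **Seeds.** A gene is a validated seed if it carries a hit from the YcaO
  accession set {TIGR03549, TIGR03604, PF02624} at e-value ≤ `seed_evalue_max`
  (default 10⁻⁵; no published threshold exists for this step, so the value
  is exposed in the config and recorded in every run report).  A separate
  `permissive_seed_accessions` set models a deliberately over-sensitive
  first-pass search: its hits create *unvalidated* seeds whose clusters are
  called and then rejected with status `rejected_invalid_seed`.  This keeps
  false-positive seeds visible and countable instead of silently dropped.
* **Neighborhood.** `window_bp` = 12,500 on each side of the seed gene,
  clipped to the contig; members are genes overlapping the window by ≥ 1 bp.
* **Cluster call.** The cluster is the maximal run of genes on the seed's
  strand with intergenic gaps ≤ `max_gap_bp` = 100.  Gaps are measured
  between half-open intervals (`next.start − prev.end`); exactly 100 bp
  joins, 101 bp splits.  Overlapping genes (negative gap) always join.  An
  opposite-strand gene terminates extension in that direction.  Clusters
  from different seeds that land in the same run are merged, retaining all
  seeds (`n_ycao_genes` then counts every YcaO gene in the run).
* **Filters.** Partner (E1/ThiF) and LanB exclusion are evaluated over the
  *full neighborhood*, not only the strand run: the inclusion/exclusion
  rules act on genomic regions, while the strand run defines the annotated
  cluster feature.  Rejection reasons are recorded in priority order
  invalid seed > LanB > no partner; all applicable reasons are kept so
  downstream analyses are insensitive to the priority choice.
* **PxP flag.** Azoline-forming YcaOs carry a catalytic C-terminal
  Pro-x-Pro; the flag is set when the pattern occurs within the last 10
  residues of any YcaO-hit protein in the cluster.  The 10-residue window
  is our operationalization of "C-terminal".
* **Seed deduplication.** Across genomes, seed proteins are greedily
  clustered longest-first (CD-HIT style) at ≥ 90 % identity and ≥ 90 %
  coverage; clusters whose every seed is a non-representative member are
  flagged `deduplicated` and excluded from classification and the network.
  Coverage is defined relative to the shorter sequence — one of several
  defensible readings; it is configurable (`dedup_identity`,
  `dedup_coverage`).

## Precursor prediction

Candidate precursors are (a) annotated CDS of 5–170 aa overlapping the
search region and (b) novel ORFs from a six-frame scan (start codons
ATG/GTG/TTG, first start after a stop, stop required in-region, initiator
read as Met).  The search region is the cluster boundary ± 1,000 bp,
because precursor genes can sit just outside the same-strand run.  Novel
ORFs that overlap an annotated CDS of ≥ 60 aa in the same strand and frame
are suppressed as enzyme fragments; identical intervals collapse to the
annotated copy.

Candidates are ranked by the **C-terminal cyclizable score**: the count of
Ser/Thr/Cys in the last ⌈n/2⌉ residues (the C-terminal "half" of an
odd-length peptide includes the middle residue).  Ties break by distance
to the seed gene (0 when overlapping), then leftmost start; the score is
the published selection criterion, the tie-break chain is ours.  The
length bounds (5–170 aa) bracket the known extremes of the class — a
7-residue precursor at the low end, ~106-residue repeat precursors with
margin at the high end — and are configurable.

## Motif features and the family decision table

* `max_stride_chain(p, stride, 'C')` formalizes the bracket motifs: the
  [Cxxx] motif is a maximal chain of Cys at stride 4 (intervening residues
  unconstrained), [Cxx] at stride 3.  Ties go to the leftmost chain.
  Repeats are computed over the whole precursor and the span is reported;
  no leader/core split is presumed, since the core boundary is not defined
  for unvalidated precursors.
* Composition: Arg+Lys fraction inside the [Cxxx] span vs. outside, Gly
  fraction inside the [Cxx] span.
* Cassette detection: the best local self-alignment (match +2, mismatch −1,
  linear gap −2) with all cells within `min_offset` = 15 of the main
  diagonal suppressed; a cassette requires ≥ `min_len` = 15 aligned columns
  at identity ≥ `min_identity` = 0.4.  The thresholds are calibrated so
  that exact and lightly mutated duplicated cores are always detected
  while uniform-random peptides are flagged at < 1 % (measured in the
  acceptance script).
* Decision table (first match wins), with every consulted criterion
  recorded as (criterion, value, threshold) evidence:
  1. cassette → `flavazolicin_like`
  2. E1 partner, ≥ 8 [Cxxx] repeats, Arg/Lys fraction in span
     ≥ max(0.15, 1.5 × outside) → `lactazolicin_like`
  3. ThiF partner, ≥ 5 [Cxx] repeats, Gly fraction ≥ 0.25 → `hca_like`
  4. E1 partner + PRP gene (PF00805) → `mcb_like_with_prp`
  5. E1 partner + McB-style complement (YcaO + E1 + dehydrogenase +
     transporter flags) without PRP → `mcb_like_no_prp`
  6. otherwise `unclassified`

  The enrichment thresholds operationalize the qualitative descriptions
  "enriched"/"rich"; they are configurable (`MotifConfig`) and appear in
  the evidence of every call.  The reported 83–106 aa lactazolicin length
  range is evidence only, never a gate.  Note that the klebsazolicin/
  phazolicin gene complement satisfies rule 5 — deliberately so, since the
  McB complement matches theirs; the label reads "McB-like gene complement
  without PRP", not a compound identification.

## Similarity network

BGC distance is `1 − (0.7·J + 0.3·P)`: J = Jaccard similarity of the two
clusters' domain-accession sets, P = global identity of the top-ranked
precursors (term dropped and the weights renormalized when either is
missing).  Edges at distance ≤ 0.5; families are connected components.
This is a declared functional stand-in for composite BGC similarity
indices: the families of interest are defined by gene-complement
similarity, which the blend captures directly.  The default cutoff was
chosen so the synthetic five-family benchmark separates with a wide margin
(within-family distance ≤ 0.3, cross-family ≥ 0.6 by construction of the
template domain sets); no fidelity claim is made to any published network.
Networks can be emitted per partner class (E1 panel / ThiF panel; clusters
with both partners appear in both).

## Alignment conventions

Two aligners are implemented in-package because their tie-breaking must be
exactly reproducible against independent test oracles:

* **Global (Gotoh)** for identity/coverage: match +1, mismatch 0, gap open
  −5 (first gap column), gap extend −1 (each further column); adjacent
  opposite-direction gaps disallowed.  Identity = matches / alignment
  columns (gap columns included); coverage = both-aligned columns / length
  of the shorter sequence.  Traceback ties prefer diagonal, then up, then
  left.  The row recurrences are vectorized with numpy via a prefix-max
  identity for the horizontal gap state.
* **Local (Smith–Waterman)** for cassette detection: linear gaps, maximum
  cell chosen first in row-major order, same tie priority.

Degenerate inputs: empty sequences raise; the empty local alignment has
identity 0; an all-gap global column count can never occur.  A shared
5-mer prefilter (skip DP when the shared-k-mer fraction vs. the shorter
sequence is < 0.5) accelerates greedy clustering; it can be disabled, and
correctness tests run with it disabled.

## Synthetic data

`azolmine.synth` generates annotated contigs with planted clusters and
JSON ground truth.  Templates fix the gene complements of the canonical
architectures (klebsazolicin `A,C,B,D,E`; phazolicin `E,A,C,B,D`; the
six-gene microcin C operon; lactazolicin `E,C,B,D2,X1,D1,X2` with a second
PxP-less YcaO; HCA; McB-like `E,B,C,D,A[,G]`; fused/split flavazolicin)
and three decoys (LanB carrier, invalid putative-YcaO seed, partnerless
YcaO).  Intergenic gaps inside clusters are 20–80 bp; planted clusters are
≥ 13 kbp apart so neighborhoods never overlap; background genes
(log-uniform 100–400 aa) carry no domain sentinels.

Mock annotation uses per-accession sentinel 12-mers containing the WW
dipeptide; every random residue pool excludes Trp, so sentinel hits cannot
arise by chance (a generation-time check asserts this).  The sentinel
annotator and a real hmmsearch run are interchangeable behind the
`AnnotationTable` contract; a domtblout-layout writer is provided for I/O
interchange tests.

The microcin C template marks its adenylating enzyme (a ThiF/E1-superfamily
protein) with the permissive putative-YcaO accession: a realistic
sensitive-search false positive that exercises the invalid-seed path while
the operon itself is correctly *called* as one six-gene cluster.

### Precursor generators

Each family generator plants exact, machine-checkable motif structure:

* lactazolicin: 83–106 aa; long leader; 8–12 exact [Cxxx] repeats whose
  single cyclizable spacer residue per repeat follows slot (r mod 3) and
  letter (S,T,T,S cycling) schedules, with Arg/Lys-enriched fillers from an
  anti-match stream; then a 16-residue Thr-dense C-terminal core.
* HCA: 7–10 exact [Cxx] repeats (one Gly and one scheduled cyclizable
  residue per spacer pair), linker, Thr-dense core.
* McB-like: long leader, a Ser-dense core (with sparse Cys) and a
  Thr-dense core separated by a linker.
* flavazolicin (fused): leader + 36–40 aa Ser/Cys-rich core + internal
  leader + the same core with 10 % substitutions — a true cassette; the
  split variant plants two separate single leader+core ORFs.
* microcin C: the literal heptapeptide MRTGNAN.

Several generator structures exist purely to make the planted truth
*identifiable* by the package's own detectors at their default thresholds:

* Cyclizable density is concentrated in dense cores of ≤ 28 residues, so
  an off-diagonal self-alignment inside a core can never reach the
  15-column cassette minimum, whatever its identity; adjacent dense cores
  use disjoint cyclizable alphabets (Ser-core vs. Thr-core) so they cannot
  align against each other.
* Repeat-spacer schedules guarantee that any two spacer residues that can
  align under a repeat-compatible self-alignment offset differ.
* Every non-cassette leader embeds a *sub-threshold self-alignment decoy*:
  an identical 10-mer pair at offset 15 whose flanking alphabets are
  mutually disjoint (the mid-segment letters Q/V/I/L are reserved for it
  alone).  Its alignment (score 20, 10 < 15 columns) outscores any
  spurious gap-assisted self-alignment that random sequence can produce,
  pinning the cassette call to a known negative.  Real cassettes score far
  higher (≈ 60+) and are unaffected.
* Precursor CDSs are back-translated with antisense-safe codons for
  S/T/C/G (TCC, ACC, TGC, GGG), so the reverse-strand "shadow" of a dense
  core does not itself translate into a cyclizable-rich ORF that would
  outrank the planted precursor.  All other genes sample synonymous codons
  uniformly.
* Planted precursor ORFs are bracketed by in-frame stop codons so the ORF
  scanner recovers their exact genomic interval.

The benchmark (`make_benchmark`) emits n genomes per family (default 20)
with within-family precursors diverged from a family base at a 10 % point
substitution rate applied to the leader pad (never to planted motif
structure), and family-distinctive domain complements chosen so that
within-family network distance is ≤ 0.3 and cross-family ≥ ~0.6 at the
default weights.  The two McB-like variants are given partially disjoint
transporter/E1 accessions so the benchmark separates them; in real data
PRP-bearing and PRP-less McB-like clusters share most accessions and would
co-cluster by gene complement alone — the benchmark is stylized for
separability, and a user should not expect that margin in nature.

**What passing the synthetic benchmark does and does not show.**  It shows
the plumbing is correct: boundaries match the stated rule exactly,
filters implement the stated logic, detectors recover planted structure,
and the stages compose deterministically.  It does not show performance on
real genomes: real precursors are not guaranteed to maximize the
cyclizable score in their cluster, real domain annotations have errors and
borderline e-values, real gene calls miss small ORFs, and real families
are not engineered to be separable.

## Problem sizes and determinism

Default verification sizes: 1,000 random layouts for the boundary rule,
80 planted clusters/decoys for the filter confusion matrix, a 100-cluster
five-family benchmark for recovery/classification/network checks, 10,000
random peptides for the repeat-detector oracle, 400 random peptides for
the cassette null, and 50 proteins for the deduplication oracle.  All
randomness flows from explicit integer seeds; identical inputs and seeds
reproduce byte-identical artifacts (reports serialize with sorted keys).

## Known limitations

* Profile-HMM scoring itself is out of scope; annotations arrive as
  domtblout/TSV or sentinels.  TfuA-partnered and standalone-YcaO clusters
  are not mined, and thiopeptide (LanB-bearing) regions are excluded by
  design.
* Remote-homology detection (RRE domains) is not attempted; the
  lactazolicin X1/X2 genes are carried as unannotated roles.
* The network distance is content-based; synteny and domain duplication do
  not contribute.
* The leader/core boundary of unvalidated precursors is not predicted;
  repeat spans are reported in whole-precursor coordinates.
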