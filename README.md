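# azolmine

Genome mining of biosynthetic gene clusters (BGCs) of azol(in)e-containing
RiPPs — ribosomally synthesized, post-translationally modified peptides in
which a YcaO cyclodehydratase converts Cys/Ser/Thr side chains of a short
precursor peptide into azoline heterocycles.  Several members of this
chemical class (klebsazolicin, phazolicin, microcin B17) are translation- or
gyrase-targeting antibiotics, which makes their gene clusters attractive
genome-mining targets.

`azolmine` is written for computational natural-product researchers.  It
implements the YcaO-seeded mining recipe end to end:

1. **Seed search** — genes annotated with a YcaO domain (TIGR03549,
   TIGR03604 or PF02624, e-value ≤ 10⁻⁵) seed the analysis; putative YcaO
   genes nominated only by a sensitive pre-annotation are tracked and
   rejected as invalid seeds.
2. **Seed deduplication** — greedy identity clustering of seed proteins at
   90 % identity / 90 % coverage removes copies from overrepresented taxa.
3. **Neighborhoods and cluster calling** — a 12.5 kbp window on each side of
   the seed is cut; the cluster is the maximal run of genes on the seed's
   strand separated by at most 100 bp (inclusive).
4. **Filters** — the neighborhood must encode an E1-like (PF00881,
   TIGR03603, TIGR04424) or ThiF-like (PF00899, TIGR02354, TIGR02356,
   TIGR03693, TIGR03736, TIGR03882) YcaO partner protein; neighborhoods
   carrying a lantipeptide-dehydratase (LanB) gene (PF14028, PF04738,
   TIGR03897, PF05147) are rejected as thiopeptide-like.
5. **Precursor prediction** — short ORFs in and around the cluster are
   enumerated in six frames and ranked by the number of cyclizable residues
   (Ser/Thr/Cys) in the C-terminal half of the peptide, the substrate
   signature of azoline installation.
6. **Family classification** — repeat motifs ([Cxxx] for lactazolicin-like,
   [Cxx] for heterocycloanthracin-like precursors), Arg/Lys and Gly
   enrichment, duplicated-core cassettes (flavazolicin-like) and the
   presence of a pentapeptide-repeat-protein gene (microcin-B17-like split)
   drive a transparent decision table.
7. **Similarity network** — clusters are connected when
   1 − (0.7·J + 0.3·P) ≤ 0.5, with J the Jaccard similarity of their domain
   complements and P the global identity of their top precursors; connected
   components are the candidate families (GraphML export).

Because no public per-cluster dataset accompanies this mining recipe, the
package ships a first-class synthetic-genome module (`azolmine.synth`) that
plants the canonical cluster architectures — klebsazolicin/phazolicin
operons, the microcin C operon, lactazolicin, heterocycloanthracin,
McB-like ± PRP, fused and split flavazolicin cassettes — plus decoy clusters
that the filters must reject, all with machine-readable ground truth.

## Worked example

Mine a synthetic genome carrying one planted lactazolicin-architecture
cluster:

```python
from azolmine.synth import make_genome
from azolmine.mining import mine_genome
from azolmine.precursors import find_cluster_precursors
from azolmine.motifs import compute_profile, classify_family

genome, annot, truth = make_genome(["lactazolicin"], rng_seed=42)
(cluster,) = mine_genome(genome, annot)
print(f"cluster {cluster.cluster_id}: status={cluster.status} "
      f"partner={cluster.partner_class} genes={len(cluster.member_gene_ids)} "
      f"n_ycao={cluster.flags['n_ycao_genes']} pxp={cluster.flags['has_pxp_ycao']}")
top = find_cluster_precursors(genome, cluster)[0]
print(f"rank-1 precursor: {top.length_aa} aa, score={top.score}/{top.cterm_half_len}, "
      f"source={top.source}")
profile = compute_profile(top.peptide)
print(f"[Cxxx] repeats: {profile.period4_repeat_count}  "
      f"Arg/Lys in span: {profile.rk_fraction_in_span:.2f}")
print(f"family: {classify_family(profile, cluster).label}")
```

prints

```
cluster synth_contig:5878-14323: status=passed partner=E1 genes=8 n_ycao=2 pxp=True
rank-1 precursor: 97 aa, score=30/49, source=annotated_cds
[Cxxx] repeats: 12  Arg/Lys in span: 0.18
family: lactazolicin_like
```

The cluster passes the filters (E1 partner present, no LanB), contains two
YcaO genes of which one carries the catalytic C-terminal PxP motif, and its
top-ranked precursor — the planted 97-residue peptide, with 30 of its 49
C-terminal residues cyclizable — shows twelve [Cxxx] repeats in an
Arg/Lys-enriched span, the lactazolicin signature.

The same stages are available from the shell on GenBank + annotation-table
inputs (hmmsearch `--domtblout` or plain TSV):

```bash
azolmine simulate --out-dir work --mode templates --templates klp_like --seed 3
azolmine mine work/genomes/*.gbk --annotations work/annotations --out work/clusters.json
azolmine classify work/genomes/*.gbk --clusters work/clusters.json --out-dir work
azolmine network --families work/families.json --out-dir work
azolmine run work/genomes/*.gbk --annotations work/annotations --out-dir work/full
```

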