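import random

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")

from azolmine.mining import MiningConfig
from azolmine.seq_records import AnnotationTable, DomainHit, GeneFeature, GenomeRecord


@pytest.fixture
def cfg():
    return MiningConfig()


def make_layout(genes, length=None, contig_id="test_contig", sequence=None):
    """Build a GenomeRecord from (start, end, strand) tuples with dummy
    proteins."""
    features = [
        GeneFeature(f"g{i}", start, end, strand, "M" + "A" * max(1, (end - start) // 3 - 2))
        for i, (start, end, strand) in enumerate(genes)
    ]
    total = length or (max(e for _, e, _ in genes) + 100)
    seq = sequence or ("A" * total)
    return GenomeRecord(contig_id, total, seq, features)


def annotate(hits):
    """hits: iterable of (gene_id, accession[, e_value])."""
    table = AnnotationTable()
    for hit in hits:
        gene_id, accession = hit[0], hit[1]
        e_value = hit[2] if len(hit) > 2 else 1e-30
        table.add(DomainHit(gene_id, accession, 100.0, e_value))
    return table


def random_layout(rng: random.Random, n_genes=None):
    """A random non-overlapping gene layout for boundary-rule tests; gaps
    concentrate around the 100 bp threshold so the inclusive boundary is
    exercised."""
    n = n_genes or rng.randint(2, 12)
    genes = []
    pos = rng.randint(0, 200)
    for _ in range(n):
        span = rng.randrange(90, 1500, 3)
        gap = rng.choice([rng.randint(0, 99), 100, 101, rng.randint(102, 400)])
        genes.append((pos, pos + span, rng.choice((1, -1))))
        pos += span + gap
    return genes
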