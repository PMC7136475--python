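import random

import pytest
from hypothesis import given, settings, strategies as st

from azolmine.mining import (MiningConfig, SeedHit, call_cluster,
                             extract_neighborhood, find_seeds, mine_genome)
from azolmine.synth import make_genome

from _oracles import strand_run_oracle
from conftest import annotate, make_layout, random_layout


def seed_for(genome, gene_id, validated=True):
    return SeedHit(genome.contig_id, gene_id, "PF02624", validated)


class TestFindSeeds:
    def test_ycao_hit_gives_validated_seed(self, cfg):
        genome = make_layout([(0, 300, 1)])
        annot = annotate([("g0", "PF02624")])
        (seed,) = find_seeds(genome, annot, cfg)
        assert seed.validated and seed.best_ycao_accession == "PF02624"

    def test_partner_accession_is_not_a_seed(self, cfg):
        genome = make_layout([(0, 300, 1)])
        assert find_seeds(genome, annotate([("g0", "PF00899")]), cfg) == []

    def test_evalue_threshold_excludes_weak_hits(self, cfg):
        genome = make_layout([(0, 300, 1)])
        weak = annotate([("g0", "PF02624", 1e-3)])
        assert find_seeds(genome, weak, cfg) == []
        strong = annotate([("g0", "PF02624", 1e-6)])
        assert len(find_seeds(genome, strong, cfg)) == 1

    def test_permissive_hit_gives_unvalidated_seed(self, cfg):
        genome = make_layout([(0, 300, 1)])
        (seed,) = find_seeds(genome, annotate([("g0", "YCAO_PUTATIVE")]), cfg)
        assert not seed.validated


class TestNeighborhood:
    def test_window_arithmetic(self, cfg):
        genome = make_layout([(20_000, 21_000, 1)], length=100_000)
        neigh = extract_neighborhood(genome, seed_for(genome, "g0"), cfg)
        assert (neigh.window_start, neigh.window_end) == (7_500, 33_500)

    def test_window_clipped_to_contig(self, cfg):
        genome = make_layout([(1_000, 2_000, 1)], length=50_000)
        neigh = extract_neighborhood(genome, seed_for(genome, "g0"), cfg)
        assert (neigh.window_start, neigh.window_end) == (0, 14_500)

    def test_single_bp_overlap_included(self, cfg):
        # window is [7500, 33500); a gene ending at 7501 overlaps by 1 bp
        genome = make_layout([(7_400, 7_501, 1), (20_000, 21_000, 1)],
                             length=100_000)
        neigh = extract_neighborhood(genome, seed_for(genome, "g1"), cfg)
        assert "g0" in neigh.member_gene_ids
        genome2 = make_layout([(7_400, 7_500, 1), (20_000, 21_000, 1)],
                              length=100_000)
        neigh2 = extract_neighborhood(genome2, seed_for(genome2, "g1"), cfg)
        assert "g0" not in neigh2.member_gene_ids


class TestCallCluster:
    def _call(self, genes, seed_idx, cfg):
        genome = make_layout(genes)
        seed = seed_for(genome, f"g{seed_idx}")
        neigh = extract_neighborhood(genome, seed, cfg)
        return call_cluster(neigh, genome, cfg)

    def test_gap_threshold_inclusive_at_100(self, cfg):
        """Gaps of 100 and 110: the 100 bp neighbor joins, the 110 one
        splits."""
        cluster = self._call([(0, 300, 1), (400, 700, 1), (810, 1000, 1)], 1, cfg)
        assert cluster.member_gene_ids == ["g0", "g1"]
        assert (cluster.start, cluster.end) == (0, 700)

    def test_opposite_strand_terminates_extension(self, cfg):
        cluster = self._call([(0, 300, -1), (350, 650, 1), (700, 1000, -1)], 1, cfg)
        assert cluster.member_gene_ids == ["g1"]

    def test_contiguous_run_fully_included(self, cfg):
        genes = [(i * 350, i * 350 + 300, 1) for i in range(10)]
        cluster = self._call(genes, 4, cfg)
        assert len(cluster.member_gene_ids) == 10

    def test_boundary_equals_union_of_member_spans(self, cfg):
        cluster = self._call([(0, 300, 1), (320, 900, 1), (850, 1000, 1)], 0, cfg)
        assert (cluster.start, cluster.end) == (0, 1000)

    def test_matches_brute_force_on_random_layouts(self, cfg):
        rng = random.Random(202)
        for _ in range(300):
            genes = random_layout(rng)
            idx = rng.randrange(len(genes))
            cluster = self._call(genes, idx, cfg)
            lo, hi = strand_run_oracle(genes, idx, cfg.max_gap_bp)
            assert cluster.member_gene_ids == [f"g{i}" for i in range(lo, hi + 1)]

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(0, 300))
    def test_raising_max_gap_never_shrinks_clusters(self, layout_seed, extra_gap):
        rng = random.Random(layout_seed)
        genes = random_layout(rng)
        idx = rng.randrange(len(genes))
        small = self._call(genes, idx, MiningConfig(max_gap_bp=100))
        big = self._call(genes, idx, MiningConfig(max_gap_bp=100 + extra_gap))
        assert set(small.member_gene_ids) <= set(big.member_gene_ids)


class TestFilters:
    def _mined(self, accession_sets, cfg, strands=None):
        """One gene per accession set, 50 bp apart, first gene = seed."""
        genes = []
        hits = []
        for i, accs in enumerate(accession_sets):
            strand = strands[i] if strands else 1
            genes.append((i * 400, i * 400 + 350, strand))
            for acc in accs:
                hits.append((f"g{i}", acc))
        genome = make_layout(genes)
        return mine_genome(genome, annotate(hits), cfg)

    def test_ycao_plus_e1_passes(self, cfg):
        (cluster,) = self._mined([{"PF02624"}, {"TIGR03603"}], cfg)
        assert cluster.status == "passed"
        assert cluster.partner_class == "E1"

    def test_lanb_rejection_overrides_partner(self, cfg):
        (cluster,) = self._mined([{"PF02624"}, {"PF00899"}, {"PF14028"}], cfg)
        assert cluster.status == "rejected_lanB"

    def test_lone_ycao_rejected_no_partner(self, cfg):
        (cluster,) = self._mined([{"PF02624"}], cfg)
        assert cluster.status == "rejected_no_partner"

    def test_partner_detected_across_strand_break(self, cfg):
        """The E1 partner sits on the opposite strand: outside the called
        cluster but inside the neighborhood, so the cluster still passes."""
        (cluster,) = self._mined([{"PF02624"}, {"TIGR04424"}], cfg,
                                 strands=[1, -1])
        assert cluster.member_gene_ids == ["g0"]
        assert cluster.status == "passed"

    def test_rejection_reasons_in_priority_order(self, cfg):
        genes = [(0, 350, 1), (400, 750, 1)]
        genome = make_layout(genes)
        annot = annotate([("g0", "YCAO_PUTATIVE"), ("g1", "PF14028"),
                          ("g1", "PF00899")])
        (cluster,) = mine_genome(genome, annot, cfg)
        assert cluster.rejection_reasons == ["rejected_invalid_seed", "rejected_lanB"]
        assert cluster.status == "rejected_invalid_seed"

    def test_flags_populated(self, cfg):
        (cluster,) = self._mined(
            [{"PF02624"}, {"TIGR04424"}, {"PF00805"}, {"PF00082"}], cfg)
        assert cluster.flags["has_prp"]
        assert cluster.flags["has_extra_protease"]
        assert not cluster.flags["has_lanB"]
        assert cluster.flags["n_ycao_genes"] == 1


class TestMineGenome:
    def test_planted_klp_cluster_recovered_exactly(self, cfg):
        genome, annot, truth = make_genome(["klp_like"], rng_seed=11)
        (cluster,) = mine_genome(genome, annot, cfg)
        planted = truth.clusters[0]
        assert cluster.status == "passed"
        assert cluster.partner_class == "E1"
        assert (cluster.start, cluster.end) == (planted.start, planted.end)
        assert set(cluster.member_gene_ids) == set(planted.gene_roles)

    def test_two_close_ycao_seeds_merge(self, cfg):
        genes = [(0, 350, 1), (400, 750, 1), (800, 1150, 1)]
        genome = make_layout(genes)
        annot = annotate([("g0", "PF02624"), ("g1", "TIGR03604"), ("g2", "TIGR03603")])
        clusters = mine_genome(genome, annot, cfg)
        assert len(clusters) == 1
        assert clusters[0].flags["n_ycao_genes"] == 2
        assert sorted(clusters[0].seed_gene_ids) == ["g0", "g1"]

    def test_no_ycao_no_clusters(self, cfg):
        genome = make_layout([(0, 350, 1)])
        assert mine_genome(genome, annotate([("g0", "PF00005")]), cfg) == []

    def test_determinism(self, cfg):
        genome, annot, _ = make_genome(["lactazolicin", "thiopeptide_decoy"],
                                       rng_seed=23)
        first = mine_genome(genome, annot, cfg)
        second = mine_genome(genome, annot, cfg)
        assert [(c.cluster_id, c.status, c.member_gene_ids) for c in first] == \
               [(c.cluster_id, c.status, c.member_gene_ids) for c in second]

    @pytest.mark.parametrize("template,expected_status", [
        ("thiopeptide_decoy", "rejected_lanB"),
        ("invalid_ycao_decoy", "rejected_invalid_seed"),
        ("partnerless_decoy", "rejected_no_partner"),
    ])
    def test_decoys_rejected_with_correct_status(self, template, expected_status, cfg):
        genome, annot, _ = make_genome([template], rng_seed=31)
        (cluster,) = mine_genome(genome, annot, cfg)
        assert cluster.status == expected_status

    def test_lactazolicin_cluster_has_two_ycao_and_pxp(self, cfg):
        genome, annot, _ = make_genome(["lactazolicin"], rng_seed=13)
        (cluster,) = mine_genome(genome, annot, cfg)
        assert cluster.flags["n_ycao_genes"] == 2
        assert cluster.flags["has_pxp_ycao"]
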