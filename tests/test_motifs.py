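import random

import pytest
from hypothesis import given, settings, strategies as st

from azolmine.mining import CandidateCluster, mine_genome
from azolmine.motifs import (classify_family, composition_fractions,
                             compute_profile, detect_cassette, local_align,
                             max_stride_chain, write_family_tsv)
from azolmine.precursors import find_cluster_precursors
from azolmine.synth import make_genome, make_precursor, template_spec

from _oracles import local_align_score_oracle, stride_chain_oracle

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestStrideChain:
    @pytest.mark.parametrize("peptide,stride,expected", [
        ("CAAACAAACAAAC", 4, (4, (0, 13))),
        ("AAAA", 4, (0, None)),
        ("CAAACAAAAACAAAC", 4, (2, (0, 5))),  # two chains of 2; leftmost wins
        ("CAACAACAA", 3, (3, (0, 7))),
    ])
    def test_examples(self, peptide, stride, expected):
        assert max_stride_chain(peptide, stride, "C") == expected

    def test_stride_below_two_rejected(self):
        with pytest.raises(ValueError):
            max_stride_chain("CCC", 1, "C")

    @settings(max_examples=300, deadline=None)
    @given(st.text(alphabet="CAST", min_size=0, max_size=60),
           st.integers(2, 6))
    def test_matches_brute_force_enumeration(self, peptide, stride):
        assert max_stride_chain(peptide, stride, "C") == \
               stride_chain_oracle(peptide, stride, "C")


class TestComposition:
    def test_rk_fraction(self):
        peptide = "AAAARKCARKCAAAAA"
        rk_in, rk_out, _ = composition_fractions(peptide, (4, 12))
        assert rk_in == pytest.approx(0.5)
        assert rk_out == 0.0

    def test_gly_fraction_and_whole_span(self):
        peptide = "GGGG"
        rk_in, rk_out, gly_in = composition_fractions(peptide, (0, 4))
        assert gly_in == 1.0
        assert rk_out == 0.0  # complement empty -> 0 by contract

    def test_empty_span_all_zeros(self):
        assert composition_fractions("ARK", None) == (0.0, 0.0, 0.0)


class TestLocalAlign:
    def test_identical_sequences(self):
        score, identity, ia, ib = local_align("ACDEFG", "ACDEFG")
        assert score == 12 and identity == 1.0
        assert ia == (0, 6) and ib == (0, 6)

    def test_no_similarity_gives_empty_alignment(self):
        score, identity, ia, ib = local_align("AAAA", "CCCC")
        assert score == 0 and identity == 0.0
        assert ia == (0, 0)

    def test_score_matches_independent_dp(self):
        rng = random.Random(55)
        for _ in range(30):
            a = "".join(rng.choice(AA) for _ in range(30))
            b = "".join(rng.choice(AA) for _ in range(30))
            assert local_align(a, b)[0] == local_align_score_oracle(a, b)

    def test_score_matches_oracle_with_diagonal_exclusion(self):
        rng = random.Random(56)
        for _ in range(15):
            a = "".join(rng.choice("ACST") for _ in range(40))
            assert local_align(a, a, min_diag_offset=15)[0] == \
                   local_align_score_oracle(a, a, min_diag_offset=15)


class TestDetectCassette:
    def test_exact_duplication_detected(self):
        core = "SCSTACSSTCGSCATSCSTG"
        peptide = "MDEILNKVQ" + core + "MELVNDKIH" + core
        cassette, identity, offsets = detect_cassette(peptide)
        assert cassette and identity == 1.0
        first, second = offsets
        assert first[1] <= second[0] or first[0] < second[0]

    def test_mutated_duplication_detected(self):
        core = "SCSTACSSTCGSCATSCSTG"
        mutated = core[:5] + "AAA" + core[8:]  # 3 substitutions in 20
        cassette, identity, _ = detect_cassette(
            "MDEILNKVQ" + core + "MELVNDKIH" + mutated)
        assert cassette
        assert identity >= 0.85

    def test_too_short_peptide(self):
        assert detect_cassette("MSCST") == (False, 0.0, None)

    def test_random_peptides_rarely_flagged(self):
        rng = random.Random(99)
        flagged = 0
        for _ in range(300):
            peptide = "".join(rng.choice(AA) for _ in range(60))
            flagged += detect_cassette(peptide)[0]
        assert flagged / 300 <= 0.01

    def test_symmetric_under_segment_swap(self):
        rng = random.Random(101)
        for _ in range(20):
            a = "".join(rng.choice("SCT" + AA) for _ in range(20))
            b = a[:4] + "GG" + a[6:]
            leader = "".join(rng.choice("DEILNKV") for _ in range(10))
            mid = "".join(rng.choice("DEILNKV") for _ in range(16))
            one = detect_cassette(leader + a + mid + b)
            two = detect_cassette(leader + b + mid + a)
            assert one[0] == two[0]


def _cluster(partner="E1", **flags):
    defaults = {"has_lanB": False, "has_prp": False, "n_ycao_genes": 1,
                "has_pxp_ycao": True, "has_extra_protease": False,
                "has_dehydrogenase": False, "has_transporter": False}
    defaults.update(flags)
    return CandidateCluster("c1", "ctg", 0, 1000, ["g0"], 1, "g0",
                            partner_class=partner, flags=defaults,
                            status="passed")


class TestClassify:
    def test_lactazolicin_template(self):
        peptide, truths = make_precursor(template_spec("lactazolicin"), 3)
        call = classify_family(compute_profile(peptide),
                               _cluster("E1", n_ycao_genes=2))
        assert call.label == "lactazolicin_like"

    def test_hca_template(self):
        peptide, _ = make_precursor(template_spec("hca"), 3)
        call = classify_family(compute_profile(peptide), _cluster("ThiF"))
        assert call.label == "hca_like"

    def test_cassette_takes_precedence(self):
        peptide, _ = make_precursor(template_spec("flavazolicin_fused"), 3)
        call = classify_family(compute_profile(peptide),
                               _cluster("E1", has_prp=True))
        assert call.label == "flavazolicin_like"

    def test_prp_split_of_mcb_like(self):
        peptide, _ = make_precursor(template_spec("mcb_with_prp"), 3)
        profile = compute_profile(peptide)
        complement = dict(has_dehydrogenase=True, has_transporter=True)
        with_prp = classify_family(profile, _cluster("E1", has_prp=True, **complement))
        without = classify_family(profile, _cluster("E1", **complement))
        assert with_prp.label == "mcb_like_with_prp"
        assert without.label == "mcb_like_no_prp"

    def test_featureless_profile_unclassified(self):
        call = classify_family(compute_profile("MAAAAELVNDKIAAAAAAELV"),
                               _cluster("none"))
        assert call.label == "unclassified"

    def test_evidence_records_all_criteria(self):
        call = classify_family(compute_profile("MAAAAELVNDKIAAAAAAELV"),
                               _cluster("E1"))
        names = {criterion for criterion, _, _ in call.evidence}
        assert {"cassette", "period4_repeat_count", "period3_repeat_count",
                "rk_fraction_in_span", "gly_fraction_in_span", "has_prp",
                "mcb_complement"} <= names

    def test_pure_function(self):
        peptide, _ = make_precursor(template_spec("lactazolicin"), 8)
        profile = compute_profile(peptide)
        cluster = _cluster("E1")
        assert classify_family(profile, cluster).label == \
               classify_family(profile, cluster).label

    def test_length_not_a_hard_gate(self):
        """A [Cxxx]-repeat precursor outside 83-106 aa still classifies by
        its repeats; length is reported as evidence only."""
        full, truths = make_precursor(template_spec("lactazolicin"), 4)
        span_start = truths["period4_span"][0]
        peptide = "MEL" + full[span_start:]  # leader stripped: well below 83 aa
        assert len(peptide) < 83
        call = classify_family(compute_profile(peptide), _cluster("E1"))
        assert call.label == "lactazolicin_like"
        lengths = [v for c, v, _ in call.evidence if c == "precursor_length_aa"]
        assert lengths == [float(len(peptide))]

    def test_family_tsv(self, tmp_path):
        peptide, _ = make_precursor(template_spec("hca"), 3)
        call = classify_family(compute_profile(peptide), _cluster("ThiF"))
        path = tmp_path / "fam.tsv"
        write_family_tsv([call], path)
        assert "hca_like" in path.read_text()


class TestEndToEndProfiles:
    def test_generator_detector_cross_check(self):
        """Planted repeat counts equal the detector's counts for every
        repeat-bearing family over many seeds."""
        for seed in range(25):
            pep4, truths4 = make_precursor(template_spec("lactazolicin"), seed)
            assert max_stride_chain(pep4, 4, "C")[0] == truths4["planted_period4"]
            pep3, truths3 = make_precursor(template_spec("hca"), seed)
            assert max_stride_chain(pep3, 3, "C")[0] == truths3["planted_period3"]

    def test_cluster_rank1_classification(self):
        genome, annot, truth = make_genome(["flavazolicin_fused"], rng_seed=77)
        (cluster,) = mine_genome(genome, annot)
        top = find_cluster_precursors(genome, cluster)[0]
        call = classify_family(compute_profile(top.peptide), cluster)
        assert call.label == truth.clusters[0].expected_family
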