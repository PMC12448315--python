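"""Candidate identification: novelty, frequency bands, effect, ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bsamap import (
    CandidateVariant,
    annotate_effect,
    find_novel_variants,
    frequency_match_filter,
    rank_candidates,
    variant_table_from_result,
)
from bsamap.genes import make_synthetic_suppressor_gene
from bsamap.scan import RegionCall


def toy_gene(strand="+", seed=0):
    gene, seq, lesions = make_synthetic_suppressor_gene(
        "toy",
        "ChrT",
        1000,
        np.random.default_rng(seed),
        strand=strand,
        n_codons=30,
        lesion_codons=(10,),
        exon_cds_lengths=(30, 30, 30),
        intron_lengths=(20, 20),
    )
    return gene, seq, lesions


def variant_at(pos, ref, alt, chrom="ChrT", mut=0.66, ctrl=0.0):
    return CandidateVariant(
        chromosome=chrom, position_bp=pos, ref=ref, alt=alt,
        control_freq=ctrl, mutant_freq=mut, control_depth=44, mutant_depth=44,
    )


class TestNovelVariants:
    def test_default_simulation_finds_lesions_and_uv_only(self, default_result):
        vt = variant_table_from_result(default_result)
        novel = find_novel_variants(vt)
        truth = default_result.counts
        expected = truth[truth["kind"] != "marker"]
        found = {(v.chromosome, v.position_bp) for v in novel}
        # every find is a true novel site (markers can never pass the
        # parent-2 hom-ref filter)
        truth_set = {(r.chrom, r.pos) for r in expected.itertuples()}
        assert found <= truth_set
        # the planted lesions are always recovered (mutant-pool frequency
        # ~2/3 at 44x cannot fall below the 3-read floor)
        for chrom, pos, _r, _a in default_result.parents.lesions:
            assert (chrom, pos) in found

    def test_variant_present_in_parent2_excluded(self, default_result):
        vt = variant_table_from_result(default_result)
        vt = vt.copy()
        # make one UV variant look inherited from parent 2
        novel_before = find_novel_variants(vt)
        target = novel_before[0]
        idx = vt[(vt["chrom"] == target.chromosome) & (vt["pos"] == target.position_bp)].index
        vt.loc[idx, "p2_alt_ad"] = 5
        after = {(v.chromosome, v.position_bp) for v in find_novel_variants(vt)}
        assert (target.chromosome, target.position_bp) not in after

    def test_missing_parent_columns_rejected(self, default_result):
        vt = variant_table_from_result(default_result).drop(columns=["p1_gt"])
        with pytest.raises(ValueError, match="p1_gt"):
            find_novel_variants(vt)


class TestFrequencyFilter:
    REGION = RegionCall("ChrT", 0, 10_000, 10.0, 1.0, 0.33)

    def test_lesion_like_frequencies_retained(self):
        v = variant_at(500, "C", "T", mut=0.7, ctrl=0.0)
        kept = frequency_match_filter([v], self.REGION)
        assert len(kept) == 1
        assert kept[0].in_region

    def test_unlinked_variant_near_half_rejected_by_control_band(self):
        # at depth 44 the control band is max(0.1, 0) around 0 -> 0.5 is out
        v = variant_at(500, "C", "T", mut=0.5, ctrl=0.5)
        assert frequency_match_filter([v], self.REGION) == []
        # and the band really is what rejects it: widen tolerance to admit
        assert frequency_match_filter([v], self.REGION, tolerance=0.5)

    def test_band_widens_with_shallow_depth(self):
        shallow = CandidateVariant(
            chromosome="ChrT", position_bp=500, ref="C", alt="T",
            control_freq=0.0, mutant_freq=0.35, control_depth=44, mutant_depth=5,
        )
        # 3*SE(2/3 at depth 5) ~ 0.63 admits 0.35; at depth 44 it would not
        assert len(frequency_match_filter([shallow], self.REGION)) == 1
        deep = CandidateVariant(
            chromosome="ChrT", position_bp=500, ref="C", alt="T",
            control_freq=0.0, mutant_freq=0.35, control_depth=44, mutant_depth=4400,
        )
        assert frequency_match_filter([deep], self.REGION) == []

    def test_zero_mutant_frequency_rejected(self):
        v = variant_at(500, "C", "T", mut=0.0, ctrl=0.0)
        assert frequency_match_filter([v], self.REGION) == []

    def test_out_of_region_variant_never_kept(self):
        v = variant_at(50_000, "C", "T")
        assert frequency_match_filter([v], self.REGION) == []


class TestEffectAnnotation:
    def test_caa_to_taa_is_stop_gained_plus_strand(self):
        gene, _seq, lesions = toy_gene("+")
        pos, ref, alt = lesions[0]
        ann = annotate_effect(variant_at(pos, ref, alt), gene)
        assert ann.effect == "stop_gained"
        assert ann.codon_index == 10
        assert ann.amino_acid_change == "Gln10Ter"

    def test_minus_strand_g_to_a_gives_same_stop_gain(self):
        gene, _seq, lesions = toy_gene("-")
        pos, ref, alt = lesions[0]
        assert (ref, alt) == ("G", "A")  # genomic strand complement of C>T
        ann = annotate_effect(variant_at(pos, ref, alt), gene)
        assert ann.effect == "stop_gained"
        assert ann.amino_acid_change == "Gln10Ter"

    def test_synonymous_third_position_change(self):
        gene, *_ = toy_gene("+")
        # find a codon where a third-position swap is synonymous (GCN = Ala)
        cds = gene.cds_sequence
        idx = next(
            i for i in range(1, len(cds) // 3 - 1) if cds[3 * i : 3 * i + 2] == "GC"
        )
        cds_pos = 3 * idx + 2
        gpos = gene.cds_to_genomic(cds_pos)
        old = cds[cds_pos]
        new = next(b for b in "ACGT" if b != old)
        ann = annotate_effect(variant_at(gpos, old, new), gene)
        assert ann.effect == "synonymous"

    def test_intronic_positions_split_by_junction_distance(self):
        gene, *_ = toy_gene("+")
        first_intron_start = gene.exons[0][1]
        near = annotate_effect(variant_at(first_intron_start, "G", "A"), gene)
        assert near.effect == "splice_adjacent"
        mid = annotate_effect(
            variant_at(first_intron_start + 9, "A", "C"), gene
        )
        assert mid.effect == "noncoding"

    def test_position_outside_gene_is_noncoding(self):
        gene, *_ = toy_gene("+")
        ann = annotate_effect(variant_at(10, "A", "C"), gene)
        assert ann.effect == "noncoding"
        assert ann.gene_id is None

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_genomic_cds_mapping_roundtrips(self, strand):
        gene, *_ = toy_gene(strand)
        n = len(gene.cds_sequence)
        for cds_pos in range(n):
            g = gene.cds_to_genomic(cds_pos)
            assert gene.genomic_to_cds(g) == cds_pos

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_mapping_never_places_intron_in_cds(self, offset):
        gene, *_ = toy_gene("+")
        pos = gene.start + offset % (gene.end - gene.start)
        cds_pos = gene.genomic_to_cds(pos)
        if cds_pos is not None:
            assert gene.cds_to_genomic(cds_pos) == pos


class TestRanking:
    def test_stop_gain_ranks_above_synonymous(self):
        gene, _s, lesions = toy_gene("+")
        pos, ref, alt = lesions[0]
        stop = annotate_effect(variant_at(pos, ref, alt), gene)
        syn = CandidateVariant(
            chromosome="ChrT", position_bp=1, ref="G", alt="A",
            control_freq=0.0, mutant_freq=2 / 3, control_depth=44, mutant_depth=44,
            effect="synonymous",
        )
        ranked = rank_candidates([syn, stop])
        assert ranked[0].effect == "stop_gained"
        assert ranked[0].rank_score > ranked[1].rank_score

    def test_planted_stop_gains_top_two_same_gene(self, default_pipeline):
        top2 = default_pipeline.candidates[:2]
        assert [v.effect for v in top2] == ["stop_gained", "stop_gained"]
        assert len({v.gene_id for v in top2}) == 1
        changes = {v.amino_acid_change for v in top2}
        assert changes == {"Gln335Ter", "Gln374Ter"}

    def test_empty_input_gives_empty_output(self):
        assert rank_candidates([]) == []

    def test_no_candidate_outside_called_region(self, default_pipeline):
        region = default_pipeline.scan.regions[0]
        for v in default_pipeline.candidates:
            assert region.contains(v.chromosome, v.position_bp)
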