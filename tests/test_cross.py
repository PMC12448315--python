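"""The synthetic cross generator: meiosis, parents, pools, pooled counts."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from bsamap import (
    build_parent_genomes,
    construct_pools,
    emit_vcf,
    read_vcf,
    simulate_gamete,
    simulate_pooled_counts,
    simulate_progeny_population,
)
from bsamap.cross import (
    ChromosomeSpec,
    CrossConfig,
    GenomeLayout,
    Individual,
    construct_null_pools,
    pool_alt_frequencies,
)
from conftest import mini_layout, mini_model


def haldane_r(d_morgans):
    return (1 - np.exp(-2 * d_morgans)) / 2


class TestMeiosis:
    def test_segments_tile_chromosome_exactly(self):
        layout = mini_layout(n_chromosomes=3)
        rng = np.random.default_rng(5)
        for _ in range(200):
            g = simulate_gamete(layout, rng)
            for c in layout.chromosomes:
                segs = g.segments(c.name, c.length_bp)
                assert segs[0][0] == 0 and segs[-1][1] == c.length_bp
                for (s1, e1, o1), (s2, e2, o2) in zip(segs, segs[1:]):
                    assert e1 == s2  # no gap, no overlap
                    assert o1 != o2  # origin alternates at each breakpoint

    def test_zero_map_length_means_no_crossovers(self):
        layout = GenomeLayout((ChromosomeSpec("ChrZ", 1_000_000, 0.0),))
        rng = np.random.default_rng(0)
        for _ in range(50):
            g = simulate_gamete(layout, rng)
            assert len(g.breakpoints["ChrZ"]) == 0
            origins = g.origins_at("ChrZ", np.array([0, 500_000, 999_999]))
            assert len(set(origins.tolist())) == 1

    def test_poisson_crossover_count_matches_map_length(self):
        layout = GenomeLayout((ChromosomeSpec("Chr01", 5_000_000, 100.0),))
        rng = np.random.default_rng(7)
        n = 10_000
        counts = [len(simulate_gamete(layout, rng).breakpoints["Chr01"]) for _ in range(n)]
        se = np.sqrt(1.0 / n)  # Poisson(1) mean has SD 1/sqrt(n)
        assert np.mean(counts) == pytest.approx(1.0, abs=3 * se)

    def test_recombinant_fraction_follows_haldane(self):
        layout = GenomeLayout((ChromosomeSpec("Chr01", 5_000_000, 100.0),))
        rng = np.random.default_rng(13)
        pos = np.array([2_000_000, 2_500_000])  # 10 cM apart
        n = 10_000
        rec = 0
        for _ in range(n):
            o = simulate_gamete(layout, rng).origins_at("Chr01", pos)
            rec += o[0] != o[1]
        expected = haldane_r(0.10)
        se = np.sqrt(expected * (1 - expected) / n)
        assert rec / n == pytest.approx(expected, abs=3 * se)


class TestParentGenomes:
    def test_zero_uv_mutations_leaves_only_planted_lesions(self):
        layout = mini_layout(n_chromosomes=2)
        cfg = CrossConfig(layout=layout, model=mini_model(layout), n_uv_mutations=0, seed=3)
        parents = build_parent_genomes(cfg)
        novel = parents.variants[parents.variants["kind"] != "marker"]
        assert set(novel["kind"]) == {"lesion"}
        assert len(novel) == 2

    def test_markers_have_distinct_parental_alleles(self, default_result):
        markers = default_result.parents.markers
        assert (markers["ref"] != markers["alt"]).all()

    def test_planted_lesions_are_coding_strand_c_to_t(self, default_result):
        parents = default_result.parents
        gene = parents.gene
        for chrom, pos, ref, alt in parents.lesions:
            assert chrom == gene.chromosome
            cds_ref = ref if gene.strand == "+" else {"G": "C", "C": "G"}[ref]
            cds_alt = alt if gene.strand == "+" else {"A": "T", "T": "A"}[alt]
            assert (cds_ref, cds_alt) == ("C", "T")
            # the FASTA, gene model and variant table agree at the lesion
            assert parents.chrom_sequences[chrom][pos] == ref

    def test_no_markers_inside_gene_span(self, default_result):
        parents = default_result.parents
        gene = parents.gene
        markers = parents.markers
        on_chrom = markers[markers["chrom"] == gene.chromosome]
        inside = on_chrom[(on_chrom["pos"] >= gene.start) & (on_chrom["pos"] < gene.end)]
        assert len(inside) == 0

    def test_gene_cds_recoverable_from_emitted_sequence(self, default_result):
        parents = default_result.parents
        gene = parents.gene
        seq = parents.chrom_sequences[gene.chromosome]
        spliced = "".join(seq[s:e] for s, e in gene.exons)
        assert spliced == gene.cds_sequence  # plus-strand default gene


@pytest.fixture(scope="module")
def mini_population():
    layout = mini_layout(n_chromosomes=2)
    model = mini_model(layout)
    cfg = CrossConfig(
        layout=layout, model=model, n_progeny=10_000, n_uv_mutations=0, seed=23
    )
    return cfg, simulate_progeny_population(cfg)


class TestProgenyAndPools:
    def test_quarter_of_progeny_non_suppressed(self, mini_population):
        cfg, pop = mini_population
        frac = np.mean([i.phenotype == "non_suppressed" for i in pop])
        se = np.sqrt(0.25 * 0.75 / len(pop))
        assert frac == pytest.approx(0.25, abs=3 * se)

    def test_unlinked_marker_frequency_is_half_over_all_progeny(self, mini_population):
        cfg, pop = mini_population
        # a marker far from both loci on chromosome 1
        origins = np.array([i.origin_at("Chr01", 10_000) for i in pop])
        se = np.sqrt(0.25 / len(pop))
        assert np.mean(origins == 2) == pytest.approx(0.5, abs=3 * se)

    def test_suppressed_individuals_lacking_selection_mutation_or_carrying_lesion(
        self, mini_population
    ):
        cfg, pop = mini_population
        for ind in pop[:500]:
            sel_origin, sup_origin = ind.genotype
            expected = "non_suppressed" if (sel_origin == 1 and sup_origin == 2) else "suppressed"
            assert ind.phenotype == expected

    def test_pools_have_requested_sizes(self, mini_population):
        cfg, pop = mini_population
        rng = np.random.default_rng(1)
        ctrl, mut = construct_pools(pop, 80, 98, rng, cfg.model)
        assert len(ctrl) == 80 and len(mut) == 98

    def test_all_control_members_carry_selection_mutation(self, mini_population):
        cfg, pop = mini_population
        rng = np.random.default_rng(2)
        ctrl, _ = construct_pools(pop, 80, 98, rng, cfg.model)
        assert all(i.genotype[0] == 1 for i in ctrl)

    def test_insufficient_individuals_raises(self, mini_population):
        cfg, pop = mini_population
        rng = np.random.default_rng(3)
        ctrl_pop = [i for i in pop if i.phenotype == "non_suppressed"]
        with pytest.raises(ValueError, match="increase n_progeny"):
            construct_pools(pop, len(ctrl_pop) + 1, 98, rng, cfg.model)

    def test_null_pools_ignore_phenotype(self, mini_population):
        cfg, pop = mini_population
        rng = np.random.default_rng(4)
        ctrl, mut = construct_null_pools(pop, 80, 98, rng)
        assert len(ctrl) == 80 and len(mut) == 98
        # a phenotype-blind control pool contains suppressed individuals
        assert any(i.phenotype == "suppressed" for i in ctrl)


def _fixed_individual(chrom, origin):
    return Individual(
        breakpoints={chrom: np.empty(0, dtype=np.int64)}, first_origin={chrom: origin}
    )


class TestPooledCounts:
    def _variants(self, n, alt_origin=1):
        return pd.DataFrame(
            {
                "chrom": "Chr01",
                "pos": np.arange(n) * 100,
                "ref": "C",
                "alt": "T",
                "kind": "uv",
                "alt_origin": alt_origin,
            }
        )

    def test_error_free_fixed_pool_yields_depth_or_zero(self):
        rng = np.random.default_rng(0)
        variants = self._variants(50)
        pool = [_fixed_individual("Chr01", 1) for _ in range(10)]
        counts = simulate_pooled_counts(pool, variants, 30.0, 0.0, rng)
        assert (counts["alt_count"] == counts["depth"]).all()
        pool0 = [_fixed_individual("Chr01", 2) for _ in range(10)]
        counts0 = simulate_pooled_counts(pool0, variants, 30.0, 0.0, rng)
        assert (counts0["alt_count"] == 0).all()

    def test_mean_observed_frequency_matches_one_third(self):
        rng = np.random.default_rng(8)
        variants = self._variants(10_000)
        pool = [_fixed_individual("Chr01", 1)] + [
            _fixed_individual("Chr01", 2) for _ in range(2)
        ]
        counts = simulate_pooled_counts(pool, variants, 44.0, 0.0, rng)
        freqs = counts["alt_count"] / counts["depth"]
        se_mean = np.sqrt((1 / 3) * (2 / 3) / 44 / len(variants))
        assert freqs.mean() == pytest.approx(1 / 3, abs=3 * se_mean)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pool_alt_frequencies([], self._variants(5))

    def test_nonpositive_depth_rejected(self):
        pool = [_fixed_individual("Chr01", 1)]
        with pytest.raises(ValueError, match="depth"):
            simulate_pooled_counts(pool, self._variants(5), 0.0, 0.0, np.random.default_rng(0))


class TestVcfRoundTrip:
    def test_emitted_vcf_reads_back_losslessly(self, default_result, tmp_path):
        path = tmp_path / "sim.vcf"
        emit_vcf(default_result, path)
        vt = read_vcf(path)
        counts = default_result.counts
        assert len(vt) == len(counts)
        assert (vt["pos"].to_numpy() == counts["pos"].to_numpy()).all()
        for col_vt, col_c in [
            ("ctrl_depth", "ctrl_depth"),
            ("ctrl_alt", "ctrl_alt"),
            ("mut_depth", "mut_depth"),
            ("mut_alt", "mut_alt"),
        ]:
            assert (vt[col_vt].to_numpy() == counts[col_c].to_numpy()).all()

    def test_novel_variants_are_parent_homref(self, default_result, tmp_path):
        path = tmp_path / "sim.vcf"
        emit_vcf(default_result, path)
        vt = read_vcf(path)
        counts = default_result.counts.reset_index(drop=True)
        novel = counts["kind"] != "marker"
        assert (vt.loc[novel.to_numpy(), "p1_gt"] == 0).all()
        assert (vt.loc[novel.to_numpy(), "p2_gt"] == 0).all()
        assert (vt.loc[novel.to_numpy(), "p2_alt_ad"] == 0).all()

    def test_lesions_emitted_at_configured_positions(self, default_result, tmp_path):
        path = tmp_path / "sim.vcf"
        emit_vcf(default_result, path)
        vt = read_vcf(path)
        for chrom, pos, ref, alt in default_result.parents.lesions:
            row = vt[(vt["chrom"] == chrom) & (vt["pos"] == pos)]
            assert len(row) == 1
            assert row["ref"].iloc[0] == ref and row["alt"].iloc[0] == alt

    def test_unsorted_records_rejected_on_emit(self, default_result, tmp_path):
        shuffled = dataclasses.replace(
            default_result,
            counts=default_result.counts.sample(frac=1, random_state=0),
        )
        with pytest.raises(ValueError, match="sorted"):
            emit_vcf(shuffled, tmp_path / "bad.vcf")
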