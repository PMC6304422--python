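import numpy as np
import pytest

from ldblock_enrich.io_formats import SnpRecord
from ldblock_enrich.ld_blocks import (BlockCallingParams, GenotypeMatrix,
                                      LdBlock, UninformativePairError,
                                      block_summary, call_blocks, dprime,
                                      dprime_ci, em_haplotype_freqs,
                                      pair_counts, pairwise_ld)
from ldblock_enrich.synthetic_data import (PlantedBlock, SyntheticGenomeSpec,
                                           simulate_genotypes)


def _coupled_haplotypes(rng, n, maf):
    """Two perfectly coupled loci: haplotype 1 carries both coded alleles."""
    hap = (rng.random((n, 2)) < maf).astype(np.int8)
    g = hap.sum(axis=1)
    return g, g.copy()


class TestEmHaplotypeFreqs:
    def test_identical_loci_force_complete_coupling(self):
        g = np.array([0, 1, 2, 0, 1, 2])
        ld = em_haplotype_freqs(g, g)
        assert ld.p_AB == pytest.approx(0.5, abs=1e-9)
        assert ld.p_Ab == pytest.approx(0.0, abs=1e-9)
        assert ld.p_aB == pytest.approx(0.0, abs=1e-9)
        assert ld.Dprime == pytest.approx(1.0)

    def test_frequencies_sum_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            g1 = rng.integers(0, 3, 40)
            g2 = rng.integers(0, 3, 40)
            try:
                ld = em_haplotype_freqs(g1, g2)
            except UninformativePairError:
                continue
            assert sum(ld.freqs) == pytest.approx(1.0, abs=1e-9)

    def test_independent_loci_factorize_within_3_se(self):
        rng = np.random.default_rng(1)
        n = 10_000
        g1 = rng.binomial(2, 0.3, n)
        g2 = rng.binomial(2, 0.4, n)
        ld = em_haplotype_freqs(g1, g2)
        pA = ld.p_AB + ld.p_Ab
        pB = ld.p_AB + ld.p_aB
        expected = pA * pB
        se = np.sqrt(expected * (1 - expected) / (2 * n))
        assert abs(ld.p_AB - expected) < 3 * se

    def test_monomorphic_locus_is_uninformative(self):
        with pytest.raises(UninformativePairError):
            em_haplotype_freqs(np.zeros(20, int), np.array([0, 1, 2] * 7)[:20])

    def test_missing_calls_deleted_pairwise(self):
        g1 = np.array([0, 1, 2, -1, 1, 2])
        g2 = np.array([0, 1, 2, 2, -1, 2])
        assert pair_counts(g1, g2).sum() == 4


class TestDprime:
    def test_complete_coupling_is_one(self):
        assert dprime((0.3, 0.0, 0.0, 0.7)) == pytest.approx(1.0)

    def test_independence_is_zero(self):
        # p_AB = pA * pB exactly
        assert dprime((0.12, 0.18, 0.28, 0.42)) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        # D = 0.4 - 0.25 = 0.15, D_max = 0.25, D' = 0.6
        assert dprime((0.4, 0.1, 0.1, 0.4)) == pytest.approx(0.6)

    @pytest.mark.parametrize("seed", range(10))
    def test_invariant_to_allele_and_locus_swaps(self, seed):
        rng = np.random.default_rng(seed)
        g1 = rng.binomial(2, rng.uniform(0.2, 0.5), 80)
        g2 = rng.binomial(2, rng.uniform(0.2, 0.5), 80)
        try:
            base = em_haplotype_freqs(g1, g2).Dprime
        except UninformativePairError:
            pytest.skip("monomorphic draw")
        for a, b in [(2 - g1, g2), (g1, 2 - g2), (2 - g1, 2 - g2), (g2, g1)]:
            assert em_haplotype_freqs(a, b).Dprime == pytest.approx(base,
                                                                    abs=1e-9)


class TestDprimeCi:
    def test_complete_ld_large_sample_pins_ci_high_at_one(self):
        rng = np.random.default_rng(0)
        g1, g2 = _coupled_haplotypes(rng, 2000, 0.3)
        lo, hi = dprime_ci(pair_counts(g1, g2))
        assert lo >= 0.9
        assert hi == 1.0

    def test_small_weak_sample_gives_wide_ci(self):
        rng = np.random.default_rng(0)
        g1 = rng.binomial(2, 0.3, 20)
        g2 = rng.binomial(2, 0.4, 20)
        lo, hi = dprime_ci(pair_counts(g1, g2))
        assert hi - lo > 0.5

    @pytest.mark.parametrize("seed", range(8))
    def test_bounds_ordered_within_unit_interval_and_cover_mle(self, seed):
        rng = np.random.default_rng(seed)
        g1 = rng.binomial(2, 0.4, 100)
        g2 = rng.binomial(2, 0.3, 100)
        try:
            ld = pairwise_ld(g1, g2)
        except UninformativePairError:
            pytest.skip("monomorphic draw")
        assert 0 <= ld.ci_low <= ld.ci_high <= 1
        assert ld.ci_low - 0.011 <= ld.Dprime <= ld.ci_high + 0.011


class TestCallBlocks:
    def test_two_pools_with_free_recombination_give_two_blocks(self):
        spec = SyntheticGenomeSpec(
            chrom_lengths={"1": 1_000_000},
            planted_blocks=(PlantedBlock("1", 100_000, 140_000, 5),
                            PlantedBlock("1", 600_000, 640_000, 5)),
            n_samples=500, seed=2)
        matrix, truth = simulate_genotypes(spec)
        blocks = call_blocks(matrix)
        assert len(blocks) == 2
        assert [set(b.snp_ids) for b in blocks] == [set(t) for t in truth]

    def test_independent_loci_give_no_blocks(self):
        rng = np.random.default_rng(3)
        n, m = 500, 12
        snps = [SnpRecord(f"s{j}", "1", 1000 + j * 5000) for j in range(m)]
        calls = rng.binomial(2, 0.3, size=(n, m)).astype(np.int8)
        assert call_blocks(GenotypeMatrix([f"x{i}" for i in range(n)],
                                          snps, calls)) == []

    def test_no_block_exceeds_window(self):
        spec = SyntheticGenomeSpec(
            chrom_lengths={"1": 1_000_000},
            planted_blocks=(PlantedBlock("1", 100_000, 350_000, 10),),
            n_samples=400, seed=4)
        matrix, _ = simulate_genotypes(spec)
        params = BlockCallingParams(max_window_bp=200_000)
        for b in call_blocks(matrix, params):
            assert b.length_bp <= 200_000 + 1

    def test_blocks_never_overlap(self):
        spec = SyntheticGenomeSpec(
            chrom_lengths={"1": 2_000_000},
            planted_blocks=tuple(
                PlantedBlock("1", s, s + 40_000, 5)
                for s in range(100_000, 1_900_000, 300_000)),
            inter_block_snp_density=4.0, n_samples=300, seed=5)
        matrix, _ = simulate_genotypes(spec)
        blocks = call_blocks(matrix)
        assert blocks
        for a, b in zip(blocks, blocks[1:]):
            if a.chrom == b.chrom:
                assert a.end <= b.start

    def test_empty_matrix_gives_empty_list(self):
        m = GenotypeMatrix(["s1"], [], np.empty((1, 0), dtype=np.int8))
        assert call_blocks(m) == []


class TestBlockSummary:
    def test_hand_example(self):
        blocks = [LdBlock("1", (), 10, 20), LdBlock("1", (), 30, 70)]
        s = block_summary(blocks)
        assert (s.count, s.mean_bp, s.min_bp, s.max_bp) == (2, 25.0, 10, 40)

    def test_empty_is_missing_not_nan(self):
        s = block_summary([])
        assert s == (0, None, None, None)

    def test_planted_genome_summary_matches_plant(self):
        starts = (100_000, 400_000, 800_000)
        spec = SyntheticGenomeSpec(
            chrom_lengths={"1": 1_200_000},
            planted_blocks=tuple(PlantedBlock("1", s, s + 30_000, 6)
                                 for s in starts),
            n_samples=500, seed=6)
        matrix, _ = simulate_genotypes(spec)
        s = block_summary(call_blocks(matrix))
        assert s.count == 3
        assert s.max_bp <= 30_001


class TestGenotypeMatrix:
    def test_vcf_dosage_extraction(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC\n"
            "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
            "1\t200\trs2\tA\tG\t.\tPASS\t.\tGT\t0/1\t./.\t1/1\n")
        m = GenotypeMatrix.from_vcf(vcf)
        assert m.samples == ["A", "B", "C"]
        assert [s.snp_id for s in m.snps] == ["rs1", "rs2"]
        assert m.calls.tolist() == [[0, 1], [1, -1], [2, 2]]

    def test_dosage_table_round_trip(self, tmp_path):
        snps = [SnpRecord("a", "1", 10), SnpRecord("b", "1", 20)]
        calls = np.array([[0, 2], [1, -1]], dtype=np.int8)
        m = GenotypeMatrix(["s1", "s2"], snps, calls)
        path = tmp_path / "d.tsv"
        m.to_dosage_table(path)
        back = GenotypeMatrix.from_dosage_table(path)
        assert back.samples == m.samples
        assert np.array_equal(back.calls, m.calls)
        assert [s.pos for s in back.snps] == [10, 20]

    def test_unsorted_positions_rejected(self):
        snps = [SnpRecord("a", "1", 20), SnpRecord("b", "1", 10)]
        with pytest.raises(ValueError, match="strictly increasing"):
            GenotypeMatrix(["s"], snps, np.zeros((1, 2), dtype=np.int8))

    def test_bad_dosage_values_rejected(self):
        snps = [SnpRecord("a", "1", 10)]
        with pytest.raises(ValueError, match="dosage"):
            GenotypeMatrix(["s"], snps, np.array([[5]], dtype=np.int8))
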