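import numpy as np
import pytest

from ldblock_enrich.io_formats import (GenomicInterval, read_annotation_track,
                                       read_blocks_bed, read_snp_manifest)
from ldblock_enrich.ld_blocks import (UninformativePairError,
                                      em_haplotype_freqs)
from ldblock_enrich.synthetic_data import (PlantedBlock, SyntheticGenomeSpec,
                                           TrackSpec, generate_manifest,
                                           generate_track,
                                           make_paper_shaped_fixture,
                                           plant_block_map,
                                           simulate_genotypes)


class TestSimulateGenotypes:
    SPEC = SyntheticGenomeSpec(
        chrom_lengths={"1": 500_000},
        planted_blocks=(PlantedBlock("1", 100_000, 140_000, 6,
                                     maf_range=(0.3, 0.3)),
                        PlantedBlock("1", 300_000, 340_000, 6)),
        inter_block_snp_density=4.0, n_samples=500, missing_rate=0.02,
        seed=42)

    def test_same_seed_gives_identical_matrices(self):
        m1, t1 = simulate_genotypes(self.SPEC)
        m2, t2 = simulate_genotypes(self.SPEC)
        assert np.array_equal(m1.calls, m2.calls)
        assert [s.snp_id for s in m1.snps] == [s.snp_id for s in m2.snps]
        assert t1 == t2

    def test_within_block_pairs_in_near_complete_ld(self):
        matrix, truth = simulate_genotypes(self.SPEC)
        idx = {s.snp_id: j for j, s in enumerate(matrix.snps)}
        high = total = 0
        for members in truth:
            cols = [idx[m] for m in members]
            for a in range(len(cols)):
                for b in range(a + 1, len(cols)):
                    dp = em_haplotype_freqs(matrix.calls[:, cols[a]],
                                            matrix.calls[:, cols[b]]).Dprime
                    total += 1
                    if dp >= 0.95:
                        high += 1
        assert high / total >= 0.9

    def test_cross_block_ld_below_within_block_ld(self):
        matrix, truth = simulate_genotypes(self.SPEC)
        idx = {s.snp_id: j for j, s in enumerate(matrix.snps)}
        within = []
        for members in truth:
            cols = [idx[m] for m in members]
            within.append(em_haplotype_freqs(matrix.calls[:, cols[0]],
                                             matrix.calls[:, cols[1]]).Dprime)
        cross = []
        for a in truth[0]:
            for b in truth[1]:
                try:
                    cross.append(em_haplotype_freqs(
                        matrix.calls[:, idx[a]],
                        matrix.calls[:, idx[b]]).Dprime)
                except UninformativePairError:
                    pass
        assert np.mean(cross) < np.mean(within)

    def test_missing_rate_applied(self):
        matrix, _ = simulate_genotypes(self.SPEC)
        frac = float((matrix.calls == -1).mean())
        assert 0.005 < frac < 0.05


class TestGenerateManifest:
    def test_fraction_zero_yields_no_intronic(self):
        snps = generate_manifest({"1": 10 ** 6}, 200, 0.0, seed=0)
        assert all(s.category == "extragenic" for s in snps)

    def test_fraction_within_3_se_of_target(self):
        n = 10_000
        snps = generate_manifest({"1": 10 ** 8}, n, 0.5, seed=1)
        share = sum(s.category == "intronic" for s in snps) / n
        assert abs(share - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_excluded_regions_respected(self):
        region = GenomicInterval("1", 0, 900_000)
        snps = generate_manifest({"1": 10 ** 6}, 300, 0.5,
                                 excluded_regions=(region,), seed=2)
        assert all(not region.contains_pos(s.pos0) for s in snps)


class TestGenerateTrack:
    CHROMS = {"1": 5_000_000, "2": 5_000_000}

    def _disease_blocks(self):
        from ldblock_enrich.ld_blocks import LdBlock

        return [LdBlock("1", (), s, s + 50_000)
                for s in range(500_000, 4_000_000, 500_000)]

    def test_factor_zero_leaves_disease_blocks_empty(self):
        blocks = self._disease_blocks()
        elems = generate_track(TrackSpec("circRNA", 50.0, 0.0, (200, 2000)),
                               blocks, self.CHROMS, seed=3)
        for e in elems:
            for b in blocks:
                if b.chrom == e.chrom:
                    assert not (e.start < b.end and b.start < e.end)

    def test_factor_one_density_ratio_near_unity(self):
        blocks = self._disease_blocks()
        inside = outside = 0
        in_len = sum(b.length_bp for b in blocks)
        out_len = sum(self.CHROMS.values()) - in_len
        for seed in range(30):
            elems = generate_track(
                TrackSpec("circRNA", 50.0, 1.0, (200, 2000)),
                blocks, self.CHROMS, seed=seed)
            for e in elems:
                hit = any(b.chrom == e.chrom and e.start < b.end
                          and b.start < e.end for b in blocks)
                inside += hit
                outside += not hit
        ratio = (inside / in_len) / (outside / out_len)
        assert 0.8 < ratio < 1.3  # element length inflates "inside" slightly

    def test_poisson_spatial_uniformity_across_seeds(self):
        from scipy import stats

        # bin starts into 20 genome bins; chi-square against uniformity
        nonsig = 0
        n_seeds = 100
        for seed in range(n_seeds):
            elems = generate_track(TrackSpec("SE", 30.0, 1.0, (500, 501)),
                                   [], {"1": 10_000_000}, seed=seed)
            starts = np.array([e.start for e in elems])
            obs, _ = np.histogram(starts, bins=20, range=(0, 10_000_000))
            p = stats.chisquare(obs).pvalue
            nonsig += p > 0.01
        assert nonsig >= 95


class TestPaperShapedFixture:
    def test_dimensions_match_published_shape(self, paper_bundle):
        b = paper_bundle
        assert len(b.disease_snps) == 97
        assert len(b.disease_blocks) == 73
        assert set(b.tracks) == {"lncRNA", "circRNA", "miRNA", "SE"}
        assert b.constraints.n_snps == 94

    def test_reproducible_from_seed(self):
        a = make_paper_shaped_fixture(5, n_manifest=500)
        b = make_paper_shaped_fixture(5, n_manifest=500)
        assert [s.snp_id for s in a.disease_snps] == \
               [s.snp_id for s in b.disease_snps]
        assert [(e.chrom, e.start, e.end) for e in a.tracks["circRNA"]] == \
               [(e.chrom, e.start, e.end) for e in b.tracks["circRNA"]]
        assert [(blk.start, blk.end) for blk in a.blocks] == \
               [(blk.start, blk.end) for blk in b.blocks]

    def test_written_bundle_round_trips_through_readers(self, paper_bundle,
                                                        tmp_path):
        paths = paper_bundle.write(tmp_path / "bundle")
        manifest = read_snp_manifest(paths["manifest"])
        assert len(manifest) == len(paper_bundle.manifest)
        disease = read_snp_manifest(paths["disease_snps"])
        assert [s.snp_id for s in disease] == \
               [s.snp_id for s in paper_bundle.disease_snps]
        blocks = read_blocks_bed(paths["blocks"])
        assert {(b.chrom, b.start, b.end) for b in blocks} == \
               {(b.chrom, b.start, b.end) for b in paper_bundle.blocks}
        for cls, fmt in (("lncRNA", "gtf"), ("miRNA", "gff"),
                         ("circRNA", "circbase_tab"), ("SE", "bed")):
            back = read_annotation_track(paths[cls], fmt, cls)
            assert {(e.chrom, e.start, e.end) for e in back} == \
                   {(e.chrom, e.start, e.end)
                    for e in paper_bundle.tracks[cls]}

    def test_unenriched_classes_stay_null(self):
        """lncRNA and miRNA are planted at background density, so their
        enrichment p-values should stay clear of significance in most
        seeds."""
        from ldblock_enrich.enrichment import EnrichmentModel

        ok = 0
        seeds = (21, 22, 23, 24, 25)
        for seed in seeds:
            b = make_paper_shaped_fixture(seed, n_manifest=8000)
            model = EnrichmentModel(b.disease_snps, manifest=b.manifest,
                                    blocks=b.blocks, tracks=b.tracks,
                                    constraints=b.constraints)
            res = model.fit(100, seed=seed)
            ok += res.p_value["lncRNA"] > 0.05
        assert ok >= len(seeds) - 1


class TestPlantBlockMap:
    def test_blocks_tile_without_overlap(self):
        blocks = plant_block_map({"1": 5_000_000}, seed=9)
        for a, b in zip(blocks, blocks[1:]):
            assert a.end <= b.start
        assert all(10_000 <= b.length_bp <= 100_000 for b in blocks)
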