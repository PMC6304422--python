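"""Generators for every pipeline input, with known ground truth.

The genotype generator uses a haplotype-pool model: within each planted
block every sample's two haplotypes are drawn from a small shared pool,
which produces high pairwise D' across the block; between blocks loci
segregate independently, so block boundaries are sharp and known.  This is
deliberately not a coalescent simulation — the pipeline needs controllable
block structure, not realistic genealogies.

Annotation tracks are homogeneous Poisson processes: elements are placed at
a background density genome-wide and at ``background x enrichment_factor``
inside a designated set of "disease" blocks (superposition for factors > 1,
thinning for factors < 1), which matches the uniform-placement null the
bootstrap test assumes.

All generators are bit-reproducible from their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .enrichment import NullConstraints
from .io_formats import (AnnotationElement, GenomicInterval, SnpRecord,
                         chrom_sort_key, write_bed, write_circbase_tab,
                         write_gff3, write_gtf, write_snp_manifest)
from .ld_blocks import GenotypeMatrix, LdBlock

__all__ = [
    "PlantedBlock",
    "SyntheticGenomeSpec",
    "TrackSpec",
    "FixtureBundle",
    "simulate_genotypes",
    "generate_manifest",
    "generate_track",
    "plant_block_map",
    "make_paper_shaped_fixture",
]


@dataclass(frozen=True)
class PlantedBlock:
    """One block to plant: interval, SNP count, haplotype pool, MAF range."""

    chrom: str
    start: int
    end: int
    n_snps: int
    pool_size: int = 2
    maf_range: tuple[float, float] = (0.2, 0.5)

    def __post_init__(self):
        if self.pool_size < 2:
            raise ValueError("haplotype pool size must be >= 2")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.n_snps < 2:
            raise ValueError("a planted block needs >= 2 SNPs")


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    chrom_lengths: dict[str, int]
    planted_blocks: tuple[PlantedBlock, ...]
    inter_block_snp_density: float = 0.0  # SNPs per Mb outside blocks
    n_samples: int = 500
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("need at least one sample")
        per_chrom: dict[str, list[PlantedBlock]] = {}
        for b in self.planted_blocks:
            per_chrom.setdefault(b.chrom, []).append(b)
        for chrom, bs in per_chrom.items():
            bs = sorted(bs, key=lambda b: b.start)
            for a, b in zip(bs, bs[1:]):
                if a.end > b.start:
                    raise ValueError(f"planted blocks overlap on chr{chrom}")


def simulate_genotypes(spec: SyntheticGenomeSpec):
    """Generate genotypes plus the true block partition.

    Returns ``(matrix, truth)`` where ``truth`` is a list of tuples of
    member SNP ids, one per planted block (in spec order).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    per_snp: list[tuple[SnpRecord, np.ndarray]] = []
    truth: list[tuple[str, ...]] = []
    used_pos: dict[str, set[int]] = {c: set() for c in spec.chrom_lengths}

    for blk in spec.planted_blocks:
        span = blk.end - blk.start
        if span < blk.n_snps:
            raise ValueError("block too short for requested SNP count")
        pos0 = np.sort(rng.choice(span, size=blk.n_snps, replace=False)
                       + blk.start)
        K = blk.pool_size
        if K == 2:
            pool = np.vstack([np.zeros(blk.n_snps, dtype=np.int8),
                              np.ones(blk.n_snps, dtype=np.int8)])
            f = rng.uniform(*blk.maf_range)
            freqs = np.array([1 - f, f])
        else:
            pool = rng.integers(0, 2, size=(K, blk.n_snps)).astype(np.int8)
            # keep every locus polymorphic within the pool
            for j in range(blk.n_snps):
                if pool[:, j].min() == pool[:, j].max():
                    pool[rng.integers(K), j] ^= 1
            freqs = rng.dirichlet(np.ones(K))
        picks = rng.choice(K, size=(n, 2), p=freqs)
        dosages = pool[picks[:, 0]] + pool[picks[:, 1]]
        ids = []
        for k, p0 in enumerate(pos0):
            p0 = int(p0)
            used_pos.setdefault(blk.chrom, set()).add(p0)
            snp = SnpRecord(f"s{blk.chrom}_{p0 + 1}", blk.chrom, p0 + 1)
            per_snp.append((snp, dosages[:, k].astype(np.int8)))
            ids.append(snp.snp_id)
        truth.append(tuple(ids))

    # independent inter-block SNPs
    if spec.inter_block_snp_density > 0:
        blocks_by_chrom: dict[str, list[PlantedBlock]] = {}
        for b in spec.planted_blocks:
            blocks_by_chrom.setdefault(b.chrom, []).append(b)
        for chrom, length in spec.chrom_lengths.items():
            bs = sorted(blocks_by_chrom.get(chrom, []),
                        key=lambda b: b.start)
            gaps = []
            cursor = 0
            for b in bs:
                if b.start > cursor:
                    gaps.append((cursor, b.start))
                cursor = b.end
            if cursor < length:
                gaps.append((cursor, length))
            gap_len = sum(e - s for s, e in gaps)
            if gap_len == 0:
                continue
            n_extra = rng.poisson(spec.inter_block_snp_density
                                  * gap_len / 1e6)
            if n_extra == 0:
                continue
            offsets = np.sort(rng.choice(gap_len, size=min(n_extra, gap_len),
                                         replace=False))
            edges = np.cumsum([e - s for s, e in gaps])
            for off in offsets:
                g = int(np.searchsorted(edges, off, side="right"))
                p0 = int(gaps[g][0] + off - (edges[g - 1] if g else 0))
                if p0 in used_pos.setdefault(chrom, set()):
                    continue
                used_pos[chrom].add(p0)
                maf = rng.uniform(0.05, 0.5)
                snp = SnpRecord(f"s{chrom}_{p0 + 1}", chrom, p0 + 1)
                per_snp.append((snp, rng.binomial(2, maf, size=n)
                                .astype(np.int8)))

    per_snp.sort(key=lambda t: (chrom_sort_key(t[0].chrom), t[0].pos))
    snps = [t[0] for t in per_snp]
    calls = (np.stack([t[1] for t in per_snp], axis=1) if per_snp
             else np.empty((n, 0), dtype=np.int8))
    if spec.missing_rate > 0 and calls.size:
        mask = rng.random(calls.shape) < spec.missing_rate
        calls = np.where(mask, np.int8(-1), calls)
    samples = [f"sample{i + 1}" for i in range(n)]
    return GenotypeMatrix(samples, snps, calls), truth


def generate_manifest(chrom_lengths: dict[str, int], n_snps: int,
                      intronic_fraction: float,
                      excluded_regions=(), rng=None,
                      seed: int | None = None) -> list[SnpRecord]:
    """Uniformly placed array-manifest SNPs with i.i.d. intronic labels.

    SNPs are never placed inside ``excluded_regions``; categories are
    intronic with probability ``intronic_fraction``, extragenic otherwise.
    """
    if not (0 <= intronic_fraction <= 1):
        raise ValueError("intronic_fraction must be in [0, 1]")
    rng = rng if isinstance(rng, np.random.Generator) \
        else np.random.default_rng(seed if rng is None else rng)
    chroms = sorted(chrom_lengths, key=chrom_sort_key)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=np.float64)
    weights = lengths / lengths.sum()
    excl: dict[str, list[GenomicInterval]] = {}
    for r in excluded_regions:
        excl.setdefault(r.chrom, []).append(r)
    out: list[SnpRecord] = []
    used: set[tuple[str, int]] = set()
    while len(out) < n_snps:
        ci = int(rng.choice(len(chroms), p=weights))
        chrom = chroms[ci]
        pos0 = int(rng.integers(0, chrom_lengths[chrom]))
        if any(iv.contains_pos(pos0) for iv in excl.get(chrom, ())):
            continue
        if (chrom, pos0) in used:
            continue
        used.add((chrom, pos0))
        cat = "intronic" if rng.random() < intronic_fraction else "extragenic"
        out.append(SnpRecord(f"m{chrom}_{pos0 + 1}", chrom, pos0 + 1, cat))
    return out


@dataclass(frozen=True)
class TrackSpec:
    """Poisson placement parameters for one synthetic annotation track."""

    element_class: str
    background_density: float  # elements per Mb
    enrichment_factor: float = 1.0
    length_range: tuple[int, int] = (500, 5000)

    def __post_init__(self):
        if self.background_density < 0 or self.enrichment_factor < 0:
            raise ValueError("density and factor must be >= 0")
        lo, hi = self.length_range
        if not (0 < lo <= hi):
            raise ValueError("invalid length_range")


def generate_track(track_spec: TrackSpec, disease_blocks,
                   chrom_lengths: dict[str, int], rng=None,
                   seed: int | None = None) -> list[AnnotationElement]:
    """Place elements by a Poisson process, enriched inside disease blocks.

    ``enrichment_factor > 1`` superposes extra elements inside the disease
    blocks; ``< 1`` thins background elements that touch them (factor 0
    leaves the disease blocks empty).
    """
    rng = rng if isinstance(rng, np.random.Generator) \
        else np.random.default_rng(seed if rng is None else rng)
    cls = track_spec.element_class
    lo, hi = track_spec.length_range
    chroms = sorted(chrom_lengths, key=chrom_sort_key)
    blocks_by_chrom: dict[str, list] = {}
    for b in disease_blocks:
        blocks_by_chrom.setdefault(b.chrom, []).append(b)

    def rand_len():
        return int(rng.integers(lo, hi + 1))

    counter = 0
    out: list[AnnotationElement] = []

    def add(chrom, start, length):
        nonlocal counter
        counter += 1
        end = min(start + length, chrom_lengths[chrom])
        if end <= start:
            return
        out.append(AnnotationElement(cls, f"{cls}_{counter:06d}", chrom,
                                     int(start), int(end), "synthetic"))

    factor = track_spec.enrichment_factor
    for chrom in chroms:
        L = chrom_lengths[chrom]
        n_bg = rng.poisson(track_spec.background_density * L / 1e6)
        starts = np.sort(rng.integers(0, L, size=n_bg))
        dblocks = blocks_by_chrom.get(chrom, ())
        for s in starts:
            length = rand_len()
            if factor < 1 and dblocks:
                touches = any(s < b.end and b.start < s + length
                              for b in dblocks)
                if touches and rng.random() >= factor:
                    continue
            add(chrom, int(s), length)
        if factor > 1:
            for b in dblocks:
                n_extra = rng.poisson(track_spec.background_density
                                      * (factor - 1) * b.length_bp / 1e6)
                for _ in range(n_extra):
                    add(chrom, int(rng.integers(b.start, b.end)), rand_len())
    return out


def plant_block_map(chrom_lengths: dict[str, int], rng=None,
                    seed: int | None = None,
                    gap_range: tuple[int, int] = (5_000, 35_000),
                    length_range: tuple[int, int] = (10_000, 100_000),
                    ) -> list[LdBlock]:
    """Tile each chromosome with non-overlapping blocks separated by gaps.

    Emulates a genome-wide Plink/Haploview block map without genotypes;
    each block gets two synthetic border-member SNP ids.
    """
    rng = rng if isinstance(rng, np.random.Generator) \
        else np.random.default_rng(seed if rng is None else rng)
    blocks: list[LdBlock] = []
    for chrom in sorted(chrom_lengths, key=chrom_sort_key):
        L = chrom_lengths[chrom]
        cursor = 0
        while True:
            gap = int(rng.integers(*gap_range))
            length = int(rng.integers(*length_range))
            start = cursor + gap
            end = start + length
            if end >= L:
                break
            blocks.append(LdBlock(
                chrom=chrom,
                snp_ids=(f"b{chrom}_{start + 1}", f"b{chrom}_{end}"),
                start=start, end=end))
            cursor = end
    return blocks


@dataclass
class FixtureBundle:
    """A complete, coherent input set with known planted structure."""

    chrom_lengths: dict[str, int]
    blocks: list[LdBlock]
    disease_blocks: list[LdBlock]
    disease_snps: list[SnpRecord]
    manifest: list[SnpRecord]
    tracks: dict[str, list[AnnotationElement]]
    track_specs: dict[str, TrackSpec]
    constraints: NullConstraints
    seed: int

    def write(self, outdir) -> dict[str, str]:
        """Write every input in its native on-disk format plus a run config.

        Returns a mapping of logical names to paths.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "blocks": outdir / "blocks.bed",
            "disease_snps": outdir / "disease_snps.tsv",
            "manifest": outdir / "manifest.tsv",
            "lncRNA": outdir / "lncrna.gtf",
            "miRNA": outdir / "mirna.gff3",
            "circRNA": outdir / "circrna.tsv",
            "SE": outdir / "se.bed",
            "config": outdir / "config.yaml",
        }
        write_bed(self.blocks, paths["blocks"])
        write_snp_manifest(self.disease_snps, paths["disease_snps"])
        write_snp_manifest(self.manifest, paths["manifest"])
        write_gtf(self.tracks["lncRNA"], paths["lncRNA"])
        write_gff3(self.tracks["miRNA"], paths["miRNA"])
        write_circbase_tab(self.tracks["circRNA"], paths["circRNA"])
        write_bed(self.tracks["SE"], paths["SE"])
        c = self.constraints
        config = {
            "manifest": str(paths["manifest"]),
            "disease_snps": str(paths["disease_snps"]),
            "blocks_bed": str(paths["blocks"]),
            "tracks": {
                "lncRNA": {"path": str(paths["lncRNA"]), "format": "gtf"},
                "miRNA": {"path": str(paths["miRNA"]), "format": "gff"},
                "circRNA": {"path": str(paths["circRNA"]),
                            "format": "circbase_tab"},
                "SE": {"path": str(paths["SE"]), "format": "bed"},
            },
            "null": {
                "mode": c.mode,
                "n_snps": c.n_snps,
                "target_length_bp": c.target_length_bp,
                "intronic_fraction": c.intronic_fraction,
                "excluded_regions": [f"{r.chrom}:{r.start}-{r.end}"
                                     for r in c.excluded_regions],
                "excluded_chroms": sorted(c.excluded_chroms),
            },
            "iterations": 1000,
            "seed": self.seed,
            "outdir": str(outdir / "results"),
        }
        with open(paths["config"], "w") as fh:
            yaml.safe_dump(config, fh, sort_keys=False)
        return {k: str(v) for k, v in paths.items()}


#: study-condition defaults for the paper-shaped fixture
_FIXTURE_CHROMS = {str(i): 30_000_000 for i in range(1, 9)}
_FIXTURE_HLA = GenomicInterval("6", 25_000_000, 30_000_000)
_FIXTURE_TRACKS = {
    "lncRNA": TrackSpec("lncRNA", background_density=8.0,
                        enrichment_factor=1.0, length_range=(1_000, 50_000)),
    "circRNA": TrackSpec("circRNA", background_density=60.0,
                         enrichment_factor=3.0, length_range=(200, 8_000)),
    "miRNA": TrackSpec("miRNA", background_density=1.0,
                       enrichment_factor=1.0, length_range=(60, 120)),
    "SE": TrackSpec("SE", background_density=2.0, enrichment_factor=3.0,
                    length_range=(5_000, 30_000)),
}


def make_paper_shaped_fixture(seed: int,
                              n_manifest: int = 20_000) -> FixtureBundle:
    """Input bundle mirroring the published analysis dimensions.

    97 disease SNPs, of which 73 land in distinct blocks and 24 in none;
    a genome-wide block map over eight 30-Mb chromosomes; a 20k-SNP
    manifest (half intronic); and four tracks with circRNA and SE densities
    planted 3x inside the disease blocks, lncRNA and miRNA left at
    background.  The null constraints use 94 random SNPs per iteration (the
    published Random set I draw size) and exclude an HLA-like interval on
    chromosome 6.
    """
    rng = np.random.default_rng(seed)
    chrom_lengths = dict(_FIXTURE_CHROMS)
    blocks = plant_block_map(chrom_lengths, rng=rng)
    from .block_mapping import _BlockIndex
    index = _BlockIndex(blocks)

    eligible = [i for i, b in enumerate(blocks)
                if not (b.chrom == _FIXTURE_HLA.chrom
                        and b.end > _FIXTURE_HLA.start
                        and b.start < _FIXTURE_HLA.end)]
    chosen = rng.choice(np.array(eligible), size=73, replace=False)
    disease_blocks = [blocks[i] for i in sorted(chosen)]

    disease_snps: list[SnpRecord] = []
    for b in disease_blocks:
        pos0 = int(rng.integers(b.start, b.end))
        cat = "intronic" if rng.random() < 0.5 else "extragenic"
        disease_snps.append(SnpRecord(f"rs{len(disease_snps) + 1:06d}",
                                      b.chrom, pos0 + 1, cat))
    # 24 SNPs in no block at all
    chroms = sorted(chrom_lengths, key=chrom_sort_key)
    while len(disease_snps) < 97:
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos0 = int(rng.integers(0, chrom_lengths[chrom]))
        if index.lookup(chrom, pos0) >= 0:
            continue
        if _FIXTURE_HLA.chrom == chrom and _FIXTURE_HLA.contains_pos(pos0):
            continue
        cat = "intronic" if rng.random() < 0.5 else "extragenic"
        disease_snps.append(SnpRecord(f"rs{len(disease_snps) + 1:06d}",
                                      chrom, pos0 + 1, cat))

    manifest = generate_manifest(chrom_lengths, n_manifest, 0.5,
                                 excluded_regions=(_FIXTURE_HLA,), rng=rng)
    tracks = {c: generate_track(spec, disease_blocks, chrom_lengths, rng=rng)
              for c, spec in _FIXTURE_TRACKS.items()}

    n_int = sum(1 for s in disease_snps if s.category == "intronic")
    constraints = NullConstraints(
        mode="match_snp_count", n_snps=94,
        intronic_fraction=n_int / len(disease_snps),
        excluded_regions=(_FIXTURE_HLA,),
        excluded_chroms=frozenset({"X"}))
    return FixtureBundle(
        chrom_lengths=chrom_lengths, blocks=blocks,
        disease_blocks=disease_blocks, disease_snps=disease_snps,
        manifest=manifest, tracks=tracks,
        track_specs=dict(_FIXTURE_TRACKS), constraints=constraints,
        seed=seed)
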