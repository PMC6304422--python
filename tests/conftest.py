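import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

FIXTURE_SEED = 11


@pytest.fixture(scope="session")
def paper_bundle():
    """Synthetic input bundle with the published analysis dimensions
    (97 disease SNPs -> 73 blocks + 24 unassigned; circRNA/SE planted 3x)."""
    from ldblock_enrich.synthetic_data import make_paper_shaped_fixture

    return make_paper_shaped_fixture(FIXTURE_SEED)


@pytest.fixture(scope="session")
def paper_model(paper_bundle):
    from ldblock_enrich.enrichment import EnrichmentModel

    b = paper_bundle
    return EnrichmentModel(b.disease_snps, manifest=b.manifest,
                           blocks=b.blocks, tracks=b.tracks,
                           constraints=b.constraints)


@pytest.fixture(scope="session")
def table3_rows():
    """The printed cell-line circRNA table used as an overlap-count fixture."""
    import pathlib

    path = pathlib.Path(__file__).parent / "data" / "table3_circrnas.tsv"
    return pd.read_csv(path, sep="\t", dtype=str)


@pytest.fixture(scope="session")
def small_null_setup():
    """A small no-enrichment universe shared by null-behavior tests."""
    from ldblock_enrich.enrichment import NullConstraints
    from ldblock_enrich.synthetic_data import (TrackSpec, generate_manifest,
                                               generate_track,
                                               plant_block_map)

    rng = np.random.default_rng(7)
    chrom_lengths = {c: 10_000_000 for c in "12"}
    blocks = plant_block_map(chrom_lengths, rng=rng)
    manifest = generate_manifest(chrom_lengths, 3000, 0.5, rng=rng)
    tracks = {
        "circRNA": generate_track(
            TrackSpec("circRNA", 40.0, 1.0, (200, 5000)), [],
            chrom_lengths, rng=rng),
        "SE": generate_track(
            TrackSpec("SE", 3.0, 1.0, (5000, 20000)), [],
            chrom_lengths, rng=rng),
    }
    constraints = NullConstraints(
        mode="match_snp_count", n_snps=25, intronic_fraction=0.5,
        excluded_regions=(), excluded_chroms=frozenset())
    return {"chrom_lengths": chrom_lengths, "blocks": blocks,
            "manifest": manifest, "tracks": tracks,
            "constraints": constraints}
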