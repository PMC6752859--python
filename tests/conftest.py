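"""Shared fixtures: small synthetic datasets reused across test modules."""

import pandas as pd
import pytest

from temethyl import synthetic as syn
from temethyl import tiles as tl


@pytest.fixture(scope="session")
def archetype_dataset():
    """Genome with three H/M/L families, per-cytosine calls and tiles."""
    spec = syn.GenomeSpec(chrom_len=300_000, n_genes=10, seed=7)
    fams = [
        syn.TEFamilyConfig(name=f"fam{a}", superfamily=sf, n_members=10)
        for a, sf in zip("HML", ["RLG", "RLC", "DTA"])
    ]
    genome, genes, tes = syn.generate_reference(spec, fams)
    archetypes = {f"fam{a}": syn.DEFAULT_ARCHETYPES[a] for a in "HML"}
    calls = syn.simulate_methylome(genome, tes, archetypes, depth=20, seed=3)
    sizes = {c: len(s) for c, s in genome.items()}
    tiles = tl.tile_methylome(calls, sizes)
    return dict(genome=genome, genes=genes, tes=tes, calls=calls,
                tiles=tiles, sizes=sizes, archetypes=archetypes)


@pytest.fixture(scope="session")
def indel_pair():
    """Haplotype pair with deterministic 50 insertions + 10 excisions."""
    study = syn.simulate_polymorphism_study(
        chrom_len=700_000, n_genes=140, n_insertions=60,
        donor_families=[
            syn.TEFamilyConfig(name=f"don{i}", superfamily=sf,
                               min_len=600, max_len=900)
            for i, sf in enumerate(["RLG", "DTA", "DTT", "DTC", "RLC"])
        ],
        excision_fraction=10 / 60, with_background=False, seed=11,
    )
    return study


@pytest.fixture(scope="session")
def spread_study():
    """Insertions steered into unmethylated background with spreading."""
    return syn.simulate_polymorphism_study(
        chrom_len=1_200_000, n_genes=240, n_insertions=100,
        p_unmethylated=0.9, spread_probability=0.6, seed=23,
    )


@pytest.fixture(scope="session")
def spread_tiles(spread_study):
    sizes_a = {c: len(s) for c, s in spread_study.absent_genome.items()}
    sizes_p = {c: len(s) for c, s in spread_study.present_genome.items()}
    return (
        tl.tile_methylome(spread_study.calls_absent, sizes_a),
        tl.tile_methylome(spread_study.calls_present, sizes_p),
    )
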