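"""Shared fixtures: a small synthetic genome and its seven-sample panel.

Everything is generated at test time from fixed seeds; no data files ship
with the tests.
"""

import numpy as np
import pandas as pd
import pytest

from methatlas.genome import GenomeConfig, generate_genome
from methatlas.io import MethylomeTrack
from methatlas.simulate import default_archetypes, generate_methylome


@pytest.fixture(scope="session")
def small_genome():
    cfg = GenomeConfig(
        chromosomes=[("chr1", 900_000), ("chr2", 900_000), ("chrX", 800_000)],
        n_genes=72,
        gene_span=(5_000, 12_000),
        intergenic_regions_per_chrom=12,
    )
    return generate_genome(cfg, seed=7)


@pytest.fixture(scope="session")
def small_archetypes(small_genome):
    return default_archetypes(small_genome, seed=7)


@pytest.fixture(scope="session")
def nb_methylome(small_genome, small_archetypes):
    return generate_methylome(small_genome, small_archetypes["NB"], seed=11)


@pytest.fixture(scope="session")
def panel_tracks(small_genome, small_archetypes):
    """All seven sample tracks plus their truths (low noise for speed)."""
    out = {}
    for i, (sample, spec) in enumerate(small_archetypes.items()):
        out[sample] = generate_methylome(small_genome, spec, seed=100 + i)
    return out


def make_track(positions, levels, reads, chrom="chr1", sample="toy"):
    """Hand-built track helper used across test modules."""
    positions = np.asarray(positions, dtype=np.int64)
    levels = np.asarray(levels, dtype=float)
    reads = np.asarray(reads, dtype=np.int64)
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "strand": "+",
            "context": "CpG",
            "level": np.where(reads > 0, levels, np.nan),
            "reads": reads,
        }
    )
    return MethylomeTrack(sample, df)
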