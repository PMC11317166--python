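import numpy as np
import pandas as pd
import pytest

from poldeg.models import CountMatrix, CoverageTrack, GeneModel
from poldeg.simulate import SimulationConfig, simulate_annotation


@pytest.fixture
def plus_gene():
    return GeneModel("geneP", "chr1", 1000, 9000, "+")


@pytest.fixture
def minus_gene():
    return GeneModel("geneM", "chr1", 1000, 5000, "-")


@pytest.fixture
def toy_counts():
    """3 target + 5 spike-in genes, 2 samples; sample B = 3x A on spike-ins."""
    ids = [f"g{i}" for i in range(3)] + [f"s{i}" for i in range(5)]
    counts = pd.DataFrame(
        {
            "A": [10, 20, 30, 100, 200, 300, 400, 500],
            "B": [10, 20, 30, 300, 600, 900, 1200, 1500],
        },
        index=ids,
    )
    species = pd.Series(["target"] * 3 + ["spikein"] * 5, index=ids)
    lengths = pd.Series([1000, 2000, 500, 1000, 1000, 1000, 1000, 1000], index=ids)
    return CountMatrix(counts=counts, species=species, lengths=lengths)


def uniform_track(chrom="chr1", start=0, end=20000, value=2.0, strand="."):
    t = CoverageTrack(strand=strand)
    t.add_runs(chrom, [start], [end], [value])
    return t


@pytest.fixture
def small_annotation():
    cfg = SimulationConfig(n_genes=30, n_spikein_genes=8, seed=123)
    return simulate_annotation(cfg), cfg
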