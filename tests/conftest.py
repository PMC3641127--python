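import numpy as np
import pandas as pd
import pytest

from tdscreen import SimulationConfig, TranscriptModel, simulate


@pytest.fixture
def toy_transcripts():
    """Three genes on two chromosomes; gB has two overlapping isoforms."""
    return [
        TranscriptModel("gA", "txA", "chr1", "+", 100, 200),
        TranscriptModel("gB", "txB1", "chr1", "-", 500, 1500),
        TranscriptModel("gB", "txB2", "chr1", "-", 500, 1000),
        TranscriptModel("gC", "txC", "chr2", "+", 0, 800),
    ]


@pytest.fixture
def toy_gene_map(toy_transcripts):
    return pd.Series({t.transcript_id: t.gene_id for t in toy_transcripts})


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete simulated dataset, shared across tests."""
    config = SimulationConfig(n_genes=300, n_tfs=80, n_planted=8, seed=11)
    return simulate(config)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
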