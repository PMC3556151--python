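import pytest

from snpassay import synthfix

SEED = 20120


@pytest.fixture(scope="session")
def truth():
    """Small synthetic study shared by read-only tests."""
    return synthfix.make_transcriptome(
        n_genes=10, length_range=(300, 700), intron_rate=0.5,
        paralog_rate=0.25, identity=0.92, seed=SEED)


@pytest.fixture(scope="session")
def pileups(truth):
    return synthfix.make_pileups(truth, depth_mean=30.0, error_rate=0.005,
                                 seed=SEED)


@pytest.fixture(scope="session")
def blast_tables(truth):
    return synthfix.make_blast_tables(truth)
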