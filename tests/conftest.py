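import pytest
from hypothesis import HealthCheck, settings

from exomescreen import synthetic

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
    database=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_world():
    """Small two-chromosome genome with genes on both strands and an
    engineered reverse-strand causal gene; cheap enough for exhaustive
    per-base oracles."""
    genome, genes = synthetic.make_toy_genome(
        0,
        chrom_lengths={"9": 60_000, "2": 40_000},
        gene_positions={"9": [20_000, 40_000], "2": [10_000, 25_000]},
        causal_locus=("9", 30_000),
    )
    return genome, genes


@pytest.fixture(scope="session")
def tiny_config():
    """Screen configuration matching tiny_world's coordinates."""
    return synthetic.ScreenConfig(
        seed=0,
        chrom_lengths={"9": 60_000, "2": 40_000},
        causal_locus=("9", 30_000),
        marker_positions={"9": [10_000, 30_000, 50_000], "2": [20_000]},
    )


@pytest.fixture(scope="session")
def screen_world():
    """Default-scale screen world (25 + 15 Mbp); built once per session."""
    config = synthetic.ScreenConfig()
    genome, genes = synthetic.make_screen_world(config)
    return config, genome, genes
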