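import pytest

from q22screen.config import CnvParams, DeletionParams, SimulationConfig


@pytest.fixture
def small_config() -> SimulationConfig:
    """A scaled-down cohort for fast unit tests (structure unchanged)."""
    return SimulationConfig(
        region_length=1_000_000,
        n_genes=8,
        gene_length=20_000,
        n_variants=300,
        n_controls=40,
        deletion=DeletionParams(interval=(100_000, 400_000)),
        cnv=CnvParams(dup_interval=(600_000, 640_000)),
        seed=11,
    )


@pytest.fixture
def default_config() -> SimulationConfig:
    """The study-scale defaults (19 cases, 103 controls, trio, 8 Mb)."""
    return SimulationConfig(seed=3)
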