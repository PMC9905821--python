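import numpy as np
import pytest

from cottonbsa.config import CausalLocus, SimulationConfig


@pytest.fixture
def small_config():
    """A fast cross: 2 chromosomes x 200 markers, 80 plants."""
    return SimulationConfig(
        n_chromosomes=2,
        chrom_length_bp=10_000_000,
        chrom_length_cM=100.0,
        n_markers_per_chrom=200,
        n_plants=80,
        bulk_size=10,
        causal_loci=(CausalLocus("chr1", 5_000_000, 0.75, 0.1),),
        mean_depth=30.0,
        seed=11,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
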