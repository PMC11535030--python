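import numpy as np
import pytest

from neohic.simulate import SimConfig, generate_haplotypes, generate_reference


@pytest.fixture(scope="session")
def small_cfg():
    """A compact diploid genome: 2 x 300 kb at 5-kb resolution."""
    return SimConfig(
        seed=3, n_chrom=2, chrom_length=300_000, resolution=5_000,
        snp_rate=1e-3, tad_mean_size=40_000,
    )


@pytest.fixture(scope="session")
def small_ref(small_cfg):
    return generate_reference(small_cfg)


@pytest.fixture(scope="session")
def small_haps(small_cfg, small_ref):
    return generate_haplotypes(small_ref, small_cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(17)
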