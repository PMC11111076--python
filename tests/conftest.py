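import numpy as np
import pytest

from igwas.config import SimConfig
from igwas.synthetic import render_fundus_pair, simulate_genotypes, simulate_subjects


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(
        n_subjects=60, n_snps=60, ld_block_size=10, within_block_r=0.8,
        maf_range=(0.1, 0.5), seed=11, n_chromosomes=2,
        causal_map=[(3, "pigment", 0.3), (23, "vessel", 0.3)],
    )


@pytest.fixture(scope="session")
def small_panel(small_cfg):
    return simulate_genotypes(small_cfg)


@pytest.fixture(scope="session")
def small_subjects(small_cfg, small_panel):
    return simulate_subjects(small_panel, small_cfg)


@pytest.fixture(scope="session")
def small_images(small_cfg, small_subjects):
    images = []
    for s in small_subjects:
        left, right = render_fundus_pair(s, small_cfg, seed=7)
        images.extend([left, right])
    return images


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
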