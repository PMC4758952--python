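import numpy as np
import pytest

from ctdbalance.coverage import TagSet
from ctdbalance.synthetic import SyntheticConfig, generate_genes, generate_tags


def make_tags(positions, strands=None, chrom="chr1", name="t") -> TagSet:
    positions = np.asarray(positions, dtype=np.int64)
    if strands is None:
        strands = np.full(len(positions), "+", dtype=object)
    else:
        strands = np.asarray(strands, dtype=object)
    return TagSet(name, np.full(len(positions), chrom, dtype=object), positions, strands)


@pytest.fixture(scope="session")
def small_config():
    """A reduced synthetic run used by fast end-to-end unit tests."""
    return SyntheticConfig(
        n_active=60,
        n_prcr=20,
        n_inactive=40,
        chrom_length=3_000_000,
        depth_per_mark=40_000,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_run(small_config):
    genes = generate_genes(small_config)
    tagsets = generate_tags(genes, small_config)
    return genes, tagsets
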