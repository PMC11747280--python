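import numpy as np
import pytest

from breakscape.model import ContactMatrix, DSBSite, GenomicInterval
from breakscape.simulate import (
    GenomeParams,
    HicParams,
    JunctionParams,
    SimulationConfig,
    build_layout,
)


@pytest.fixture(scope="session")
def small_config():
    """A fast, small synthetic study: two 8 Mb chromosomes, four cuts."""
    return SimulationConfig(
        seed=7,
        genome=GenomeParams(
            n_chrom=2,
            chrom_length=8_000_000,
            n_asisi=8,
            n_cut=4,
            n_baits=2,
            min_cut_spacing=2_400_000,
        ),
        hic=HicParams(depth=3e5),
        junctions=JunctionParams(n_junctions=2_000),
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return build_layout(small_config)


@pytest.fixture(scope="session")
def default_config():
    """The generator's default study conditions (seed 7)."""
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def default_bundle(default_config):
    return build_layout(default_config)


@pytest.fixture()
def worked_matrix():
    """3-bin intra matrix with expected profile (4, 2, 1)."""
    counts = np.array([[4.0, 3.0, 1.0], [3.0, 4.0, 1.0], [1.0, 1.0, 4.0]])
    return ContactMatrix("chr1", "chr1", 100, counts)


def make_site(chrom: str, pos: int, site_id: str = "s", width: int = 1) -> DSBSite:
    return DSBSite(site_id, GenomicInterval(chrom, pos, pos + width))
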