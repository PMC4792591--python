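import pytest

from ctcwgs.genotyping import LodModelParams
from ctcwgs.synthetic_data import SimConfig, make_paper_fixture, simulate_truth


@pytest.fixture(scope="session")
def default_params():
    return LodModelParams()


@pytest.fixture(scope="session")
def paper_fixture():
    return make_paper_fixture()


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down study: same structure, desk-sized counts."""
    return SimConfig(
        genome_bins=300,
        n_germline_het=2000,
        n_founder=200,
        n_primary_private=60,
        n_met_private=60,
        n_ctc=4,
        n_cell_private_per_ctc=10,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return simulate_truth(small_config)
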