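import numpy as np
import pytest

from hrrbench.sequence_io import SourceClass
from hrrbench.synthetic_fixtures import (
    DonorModel,
    ReadSimParams,
    build_donor_pool,
    make_genome,
    simulate_pairs,
)


@pytest.fixture(scope="session")
def host_genome():
    return make_genome("host", 8000, SourceClass.HOST, seed=11)


@pytest.fixture(scope="session")
def target_genome():
    return make_genome("virus", 3000, SourceClass.TARGET, seed=12)


@pytest.fixture(scope="session")
def contaminant_genome():
    return make_genome("contam", 2000, SourceClass.CONTAMINANT, seed=13)


@pytest.fixture(scope="session")
def sim_params():
    return ReadSimParams(read_length=50, insert_mean=160.0, insert_sd=15.0, error_rate=0.0, seed=7)


@pytest.fixture(scope="session")
def donor_pools(host_genome, contaminant_genome, sim_params):
    """Three clean-ish donor pools of 400 pairs each (5% contaminants)."""
    pools = {}
    for i, did in enumerate(["D01", "D02", "D03"]):
        donor = DonorModel(
            donor_id=did,
            base_genome=host_genome,
            snp_rate=0.005,
            contamination_fraction=0.05,
            seed=100 + i,
        )
        pools[did] = build_donor_pool(donor, [contaminant_genome], 400, sim_params)
    return pools


@pytest.fixture(scope="session")
def viral_pool(target_genome, sim_params):
    return simulate_pairs(target_genome, 400, sim_params, SourceClass.TARGET, donor_id="S01")


@pytest.fixture()
def rng():
    return np.random.default_rng(20259)
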