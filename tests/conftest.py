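import warnings

import pytest

from wapflux.network import CoabundanceNetwork
from wapflux.qmp import SpikeSpec, qmp_auto
from wapflux.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def dataset():
    """Default synthetic survey (seed 1), shared across the suite."""
    return simulate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def qmp_table(dataset):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table, _report = qmp_auto(
            dataset.counts, dataset.metadata, SpikeSpec(), taxonomy=dataset.taxonomy
        )
    return table


@pytest.fixture(scope="session")
def network_results(qmp_table):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return CoabundanceNetwork(qmp_table).fit()
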