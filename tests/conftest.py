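import numpy as np
import pandas as pd
import pytest

from netmoss.io import AbundanceTable, CorrelationNetwork
from netmoss.simulate import SimulationSpec, simulate_pair


def make_network(mat, taxa=None, n=10, **kw):
    mat = np.asarray(mat, dtype=float)
    if taxa is None:
        taxa = [f"t{i}" for i in range(mat.shape[0])]
    return CorrelationNetwork(pd.DataFrame(mat, index=taxa, columns=taxa), n=n, **kw)


@pytest.fixture
def toy_table():
    """3 taxa x 4 samples, columns summing to one."""
    data = pd.DataFrame(
        {
            "s1": [0.5, 0.3, 0.2],
            "s2": [0.6, 0.3, 0.1],
            "s3": [0.4, 0.35, 0.25],
            "s4": [0.55, 0.25, 0.2],
        },
        index=["taxA", "taxB", "taxC"],
    )
    return AbundanceTable(data, study_id="toy", group="control")


@pytest.fixture(scope="session")
def default_pair():
    """One default-benchmark simulated pair, shared across tests."""
    return simulate_pair(SimulationSpec(seed=11))


@pytest.fixture(scope="session")
def small_spec():
    """A light two-module spec for fast pipeline tests."""
    return SimulationSpec(
        n_taxa=40,
        module_sizes=(25, 15),
        module_max_corr=(0.8, 0.8),
        module_span=(5, 5),
        migrate_fraction=0.6,
        seed=5,
    )
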