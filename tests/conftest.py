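import numpy as np
import pandas as pd
import pytest

from ocmeth.simulate import SimulationConfig, generate_methylation, simulate_all


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_probes=2000, n_genes=400, seed=11)


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate_all(small_config)


@pytest.fixture(scope="session")
def small_meth(small_config):
    return generate_methylation(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20130912)


@pytest.fixture()
def paired_design():
    def make(n_pairs):
        rows = []
        for i in range(n_pairs):
            rows.append({"sample": f"MO_D{i+1}", "donor": f"D{i+1}", "condition": "MO"})
            rows.append({"sample": f"OC_D{i+1}", "donor": f"D{i+1}", "condition": "OC"})
        return pd.DataFrame(rows)

    return make
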