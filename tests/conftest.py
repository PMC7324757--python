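import numpy as np
import pytest

from qconpipe import reference
from qconpipe.simulate import construct_for_truth, simulate_ground_truth, simulate_xic_table


@pytest.fixture(scope="session")
def table1():
    return reference.table1_quantification()


@pytest.fixture(scope="session")
def table2():
    return reference.table2_method_comparison()


@pytest.fixture(scope="session")
def noiseless_run():
    """A noiseless, fully detected simulated experiment plus its truth."""
    truth = simulate_ground_truth(noise_cv=0.0, detection_probability=1.0, seed=11)
    construct = construct_for_truth(truth)
    series = reference.default_spike_series(6, qprot=construct.name)
    observations = simulate_xic_table(truth, series, construct)
    return truth, construct, series, observations
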