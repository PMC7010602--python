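import numpy as np
import pytest

from calista.burst_model import TwoStateParams, build_param_table


@pytest.fixture(scope="session")
def table():
    """Default-grid parameter table, built once per session."""
    return build_param_table()


@pytest.fixture(scope="session")
def tiny_table():
    """Four-point grid for hand-checkable table lookups."""
    return build_param_table(
        {"theta_on": [0.5, 2.0], "theta_off": [1.0], "theta_t": [10.0, 120.0]},
        m_cap=200,
    )


@pytest.fixture(scope="session")
def three_cluster_data():
    """600 cells x 15 genes from three well-separated parameter sets."""
    from calista.synthetic import simulate_clusters

    params = [
        [TwoStateParams(1.0, 1.0, 5.0)] * 15,
        [TwoStateParams(1.0, 1.0, 40.0)] * 15,
        [TwoStateParams(1.0, 1.0, 150.0)] * 15,
    ]
    return simulate_clusters(3, 15, 200, params, seed=11)
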