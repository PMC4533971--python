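import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import rsnet

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1_raw():
    """Packaged worked example, raw labels (no synonym merging)."""
    net, attrs = rsnet.load_table1_fixture()
    return net, attrs


@pytest.fixture(scope="session")
def table1_canonical(table1_raw):
    net, attrs = table1_raw
    merged, _ = rsnet.canonicalize_driver_names(net, rsnet.table1_synonym_map())
    return merged, attrs


@pytest.fixture(scope="session")
def rsdb_like():
    """One database-scale synthetic dataset under the default conditions."""
    return rsnet.generate_rsdb_like(7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_network(edges, shifts=None, drivers=None):
    """Tiny literal network helper: edges as (shift, driver) pairs."""
    s = list(dict.fromkeys([e[0] for e in edges] + (shifts or [])))
    d = list(dict.fromkeys([e[1] for e in edges] + (drivers or [])))
    inc = np.zeros((len(s), len(d)), dtype=np.int8)
    for a, b in edges:
        inc[s.index(a), d.index(b)] = 1
    return rsnet.BipartiteNetwork(s, d, inc)
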