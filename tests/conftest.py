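import pytest

from acetoflux.fluxes import load_bundled_preset, solve_scheme
from acetoflux.network import load_bundled_network
from acetoflux.thermo import load_bundled_thermo_table


@pytest.fixture(scope="session")
def network():
    net = load_bundled_network()
    net.validate()
    return net


@pytest.fixture(scope="session")
def thermo_table():
    return load_bundled_thermo_table()


@pytest.fixture(scope="session")
def solved(network):
    """Solve each bundled preset once per session."""
    cache = {}

    def get(name):
        if name not in cache:
            cache[name] = solve_scheme(network, load_bundled_preset(name))
        return cache[name]

    return get
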