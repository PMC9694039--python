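import pytest

from hemosim.reaction_network import builtin_network_path, load_network


@pytest.fixture(scope="session")
def plasma_network():
    return load_network(builtin_network_path("plasma"))


@pytest.fixture(scope="session")
def mini_network():
    return load_network(builtin_network_path("mini"))
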