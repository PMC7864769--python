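import pytest

import healthledger as hl


@pytest.fixture(scope="session")
def demo_net():
    """A default 6-peer network with the worked scenario committed.

    Session-scoped and treated as read-only: tests that mutate topology,
    MSP or state build their own network.
    """
    net = hl.build_network(hl.NetworkConfig.default(seed=11))
    transcript = net.run_worked_example()
    return net, transcript


@pytest.fixture()
def fresh_net():
    def make(seed=0, batching=None):
        return hl.build_network(hl.NetworkConfig.default(seed=seed, batching=batching))

    return make
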