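import numpy as np
import pytest

import nessflow as nf


@pytest.fixture(scope="session")
def ab_network():
    return nf.make_ab()  # A<->B, k1=2, km1=1, total 1 M, closed


@pytest.fixture(scope="session")
def competitive_network():
    return nf.make_competitive()  # defaults: Keq=10 both channels, f=1


@pytest.fixture(scope="session")
def schlogl_network():
    return nf.make_schlogl()  # cubic (x-1)(x-2)(x-3)


@pytest.fixture(scope="session")
def frank_network():
    return nf.make_frank()  # flow inside the SMSB window


@pytest.fixture(scope="session")
def competitive_ness(competitive_network):
    states = nf.find_steady_states(competitive_network, n_starts=16, seed=11)
    assert len(states) == 1
    return states[0]


@pytest.fixture(scope="session")
def frank_states(frank_network):
    """All stationary states of the Frank preset: racemic + two scalemic."""
    states = nf.find_steady_states(frank_network, n_starts=32, seed=11)
    assert len(states) == 3
    return states


def random_compositions(rng, n_species, n=10, lo=0.05, hi=2.0):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=(n, n_species)))
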