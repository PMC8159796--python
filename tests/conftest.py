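import dataclasses

import pytest

import mrmediate as mm

CONF = mm.ConfounderLoadings(x=0.5, m=0.5, y=0.5)


@pytest.fixture(scope="session")
def confounded_config():
    """Standard confounded scenario: a=0.4, b=0.5, c'=0.3, loadings 0.5."""
    return mm.ScenarioConfig(confounder=CONF)


@pytest.fixture(scope="session")
def confounded_ds(confounded_config):
    return mm.simulate(dataclasses.replace(confounded_config, n=2000), seed=3)


@pytest.fixture(scope="session")
def chain_config():
    """Three mediators with M2 -> M3; total effect 0.5, combined indirect 0.205."""
    return mm.ScenarioConfig(
        a_paths=[0.2, 0.3, 0.1],
        b_paths=[0.25, 0.25, 0.5],
        mediator_chain=[("m2", "m3", 0.2)],
        c_prime=0.295,
        confounder=CONF,
    )
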