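import pytest

from phasloc.pipeline import discover
from phasloc.simulate import make_phas_scenario, make_rddm_scenario


@pytest.fixture(scope="session")
def planted_scenario():
    """The default planted 21-nt PHAS scenario (seed 7)."""
    return make_phas_scenario(7)


@pytest.fixture(scope="session")
def planted_discovery(planted_scenario):
    s = planted_scenario
    return discover(
        s.transcripts, [s.srna], [s.degradome], params={"k_values": [21]}
    )


@pytest.fixture(scope="session")
def rddm_scenario():
    return make_rddm_scenario(7)
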