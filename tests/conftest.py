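import numpy as np
import pytest

from fishprobes.pipeline import run_pipeline
from fishprobes.simulate import default_fixture_spec, generate_genome
from fishprobes.targets import DesignConfig


@pytest.fixture(scope="session")
def cfg():
    return DesignConfig()


@pytest.fixture(scope="session")
def sim():
    """The default ig-like fixture: 3 unique stretches, a 3-copy local
    repeat family, and a global family with copies outside the locus."""
    return generate_genome(default_fixture_spec(seed=1))


@pytest.fixture(scope="session")
def result(sim, cfg):
    """Full pipeline run on the default fixture."""
    return run_pipeline(sim.query, genome=[sim.genome], cfg=cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
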