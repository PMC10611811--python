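"""Shared fixtures: phantoms are generated once per session and reused."""

import numpy as np
import pytest

from ctpa_cade.config import RunConfig
from ctpa_cade.phantom import PhantomSpec, PhantomBundle, generate
from ctpa_cade.pipeline import run_pipeline


@pytest.fixture(scope="session")
def default_bundle() -> PhantomBundle:
    """A default phantom: population-median anatomy, 20 HU noise."""
    return generate(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def noisefree_bundle() -> PhantomBundle:
    return generate(PhantomSpec(noise_sd_hu=0.0, seed=7))


@pytest.fixture(scope="session")
def default_result(default_bundle):
    return run_pipeline(default_bundle.volume)


@pytest.fixture(scope="session")
def noisefree_result(noisefree_bundle):
    return run_pipeline(noisefree_bundle.volume)


@pytest.fixture()
def config() -> RunConfig:
    return RunConfig()
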