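import numpy as np
import pytest

from apgwave import fixture_suite, generate, SynthConfig


@pytest.fixture(scope="session")
def suite():
    """The four canonical synthetic regimes (fixed seeds)."""
    return fixture_suite()


@pytest.fixture(scope="session")
def stationary(suite):
    return suite["stationary"]


@pytest.fixture(scope="session")
def short_clean():
    """A small 10-beat clean record for per-beat assertions."""
    return generate(SynthConfig(duration_s=9.0, hr_bpm=72, hr_jitter_percent=0.0, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(20140925)
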