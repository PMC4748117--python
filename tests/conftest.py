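import numpy as np
import pytest

from isomix import SourceProfile, default_source_profiles


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def default_sources():
    return default_source_profiles()


@pytest.fixture
def two_sources():
    """Two maximally separated one-tracer sources for oracle fits."""
    return [
        SourceProfile(name="low", means={"t": 0.0}, sds={"t": 0.1}),
        SourceProfile(name="high", means={"t": 100.0}, sds={"t": 0.1}),
    ]
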