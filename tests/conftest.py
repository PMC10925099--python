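import pytest

from domfit.demography import default_european_demography
from domfit.expected import build_grid_cache, make_grid


@pytest.fixture(scope="session")
def grid():
    return make_grid()


@pytest.fixture(scope="session")
def demo10k():
    """Default synthetic-study demography (N_anc = 10,000)."""
    return default_european_demography(10_000.0)


@pytest.fixture(scope="session")
def cache_additive_864(demo10k):
    """Unit-theta expected spectra at h=0.5 for the study sample size."""
    return build_grid_cache(0.5, demo10k, 864, N_anc=10_000.0)


@pytest.fixture(scope="session")
def caches_864(cache_additive_864):
    return {0.5: cache_additive_864}
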