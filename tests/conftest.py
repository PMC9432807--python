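import numpy as np
import pytest

from cardiosnv import synthetic


@pytest.fixture(scope="session")
def reference_small():
    """1 Mb single-chromosome genome for fast unit tests."""
    return synthetic.generate_reference(1, 1_000_000, 0.41, seed=101)


@pytest.fixture(scope="session")
def reference_default():
    """The default 20 Mb study genome (2 x 10 Mb)."""
    return synthetic.generate_reference(2, 10_000_000, 0.41, seed=1)


@pytest.fixture(scope="session")
def germline_small(reference_small):
    return synthetic.generate_germline(reference_small, 0.67, seed=102)


@pytest.fixture(scope="session")
def default_mix():
    return {"SBS5_like": 0.7, "SBS18_like": 0.3}


@pytest.fixture(scope="session")
def diploid_cell(reference_small, germline_small, default_mix):
    """One diploid aged cell on the small genome."""
    return synthetic.simulate_cell(
        reference_small, germline_small, synthetic.AmplificationParams(),
        ploidy=2, age=80.0, rate_per_mb_per_year=0.01, intercept_per_mb=0.05,
        signature_mix=default_mix, seed=103,
    )
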