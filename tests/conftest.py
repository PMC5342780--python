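import pytest

from dirpscan.conservation import blosum45
from dirpscan.pipeline import run_synthetic


@pytest.fixture(scope="session")
def b45():
    return blosum45()


@pytest.fixture(scope="session")
def reference_run():
    """One full synthetic scan at the default conditions (seed 0), shared
    across the pipeline and acceptance tests."""
    return run_synthetic(seed=0)
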