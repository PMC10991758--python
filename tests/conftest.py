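import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests/oracles.py

from trialemu import default_config, generate_cohort


@pytest.fixture(scope="session")
def cohort478():
    """One study-sized cohort from the calibrated default configuration."""
    return generate_cohort(default_config(n=478, seed=7))


@pytest.fixture(scope="session")
def cohort5k():
    """A larger default cohort for balance / weighting checks."""
    return generate_cohort(default_config(n=5000, seed=11))
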