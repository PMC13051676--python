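import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracle helper

from swineval import CohortConfig, FarmerConfig, load_base_case


@pytest.fixture(scope="session")
def base_case():
    """The shipped published parameter set, ledger and reference values."""
    return load_base_case()


@pytest.fixture()
def cahw_config():
    """CAHW cohort with the secular shift disabled, so the round effect
    equals the planted program-attributable log odds ratio."""
    return CohortConfig.cahw_default(seed=11, secular_shift=0.0)


@pytest.fixture()
def farmer_config():
    return FarmerConfig(seed=11)
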