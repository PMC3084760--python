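import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from hcoclass.fingerprints import default_profiles
from hcoclass.simulate import generate_gold_standard, load_templates


@pytest.fixture(scope="session")
def templates():
    return load_templates()


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def small_refset():
    """Five families x 4 members at 10% substitution (fast unit-test set)."""
    return generate_gold_standard(per_type_n=4, rate=0.10, seed=11)
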