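import json
from pathlib import Path

import numpy as np
import pytest

from sweatvoc import EnoseSimConfig, GcmsSimConfig, simulate_enose, simulate_gcms

FIXTURES = Path(__file__).parent / "fixtures"


@pytest.fixture(scope="session")
def reference_counts() -> dict:
    with open(FIXTURES / "reference_confusion_counts.json") as fh:
        return json.load(fh)


@pytest.fixture(scope="session")
def gcms_matrix():
    """Default 65 × 187 synthetic GC-MS matrix (13 informative markers)."""
    return simulate_gcms(GcmsSimConfig(seed=20240901))


@pytest.fixture(scope="session")
def enose_recordings():
    """Default 68-recording synthetic E-nose cohort."""
    return simulate_enose(EnoseSimConfig(seed=20240902))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
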