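import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for helpers.py

from bpscreen import CohortConfig, apply_eligibility, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    return CohortConfig(
        n_regions=2, countries_per_region=3, n_per_country=[700] * 6, seed=42
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def eligible_cohort(small_cohort):
    df, _ = apply_eligibility(small_cohort)
    return df
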