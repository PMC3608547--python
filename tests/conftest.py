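import numpy as np
import pytest

from metacare import SyntheticConfig, build_design, generate_dataset
from metacare.mixed import MCMCSettings


@pytest.fixture(scope="session")
def paper_records():
    """One canonical synthetic dataset with the standard comparative shape
    (192 effects / 62 studies / 48 species / 29 families / 5 classes)."""
    records, truth = generate_dataset(SyntheticConfig.paper_like(seed=42))
    return records, truth


@pytest.fixture(scope="session")
def paper_bundle(paper_records):
    records, _ = paper_records
    return build_design(records)


def short_settings(seed: int = 0, n_chains: int = 1) -> MCMCSettings:
    """Small schedule for unit tests."""
    return MCMCSettings(iterations=3000, burn_in=1000, thin=2,
                        n_chains=n_chains, seed=seed)
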