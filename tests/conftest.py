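import pytest

from polarcnn import SyntheticConfig
from polarcnn.pipeline import synthesize_cases
from polarcnn.synth import with_separation


@pytest.fixture(scope="session")
def tiny_dataset():
    """12 well-separated cases rendered small — cheap fixture for training
    plumbing tests (the network input is still 256x256 after resize)."""
    cfg = with_separation(
        SyntheticConfig(
            n_cases=12, ischemic_fraction=0.5, image_size=256, seed=321
        )
    )
    return synthesize_cases(cfg)


@pytest.fixture(scope="session")
def easy_dataset_60():
    """60 well-separated cases at export resolution, for the stability
    protocol check."""
    cfg = with_separation(
        SyntheticConfig(n_cases=60, image_size=1024, seed=2024)
    )
    return synthesize_cases(cfg)
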