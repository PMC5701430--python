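import pytest

from popseg import SegmentationConfig, default_catalog


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def config():
    """Default segmentation parameters (index year 2012, 5-year look-back)."""
    return SegmentationConfig()
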