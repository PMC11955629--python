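from importlib import resources

import pytest
from hypothesis import HealthCheck, settings

from mockbench.mock_eval import load_zymo8
from mockbench.profiles import read_abundance_table

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


def _data_path(name: str) -> str:
    return str(resources.files("mockbench.data").joinpath(name))


@pytest.fixture(scope="session")
def zymo8():
    return load_zymo8()


@pytest.fixture(scope="session")
def extraction_observed():
    """Published percent profiles of the 7 mock extraction controls."""
    return read_abundance_table(_data_path("extraction_controls_observed.tsv"))


@pytest.fixture(scope="session")
def sequencing_observed():
    """Published percent profiles of the 7 mock sequencing (DNA) controls."""
    return read_abundance_table(_data_path("sequencing_controls_observed.tsv"))


@pytest.fixture(scope="session")
def extraction_confusion_path():
    return _data_path("extraction_controls_confusion.tsv")


@pytest.fixture(scope="session")
def sequencing_confusion_path():
    return _data_path("sequencing_controls_confusion.tsv")
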