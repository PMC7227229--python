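import pytest

from uplandghg import EFRegistry, RegionMap, run_records
from uplandghg.synth import GeneratorConfig, generate_activity, reference_fixture


@pytest.fixture(scope="session")
def registry():
    return EFRegistry.default()


@pytest.fixture(scope="session")
def region_map():
    return RegionMap.default()


@pytest.fixture(scope="session")
def fixture():
    return reference_fixture()


@pytest.fixture(scope="session")
def dataset():
    """One default synthetic dataset: 13x3 wheat + 19x3 maize records."""
    return generate_activity(GeneratorConfig(seed=42))


@pytest.fixture(scope="session")
def results(dataset, registry):
    return run_records(dataset, registry)
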