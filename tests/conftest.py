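import hypothesis
import pytest

from canalflow.geometry import CanalGeometry, Needle, RootCanalSystem
from canalflow.hydraulics import Fluid

hypothesis.settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("suite")


@pytest.fixture(scope="session")
def needle() -> Needle:
    return Needle()


@pytest.fixture(scope="session")
def fluid() -> Fluid:
    return Fluid()


@pytest.fixture(scope="session")
def separate_system() -> RootCanalSystem:
    return RootCanalSystem.separate_model()


@pytest.fixture(scope="session")
def anastomosis_system() -> RootCanalSystem:
    return RootCanalSystem.anastomosis_model()


@pytest.fixture(scope="session")
def canal() -> CanalGeometry:
    return CanalGeometry()
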