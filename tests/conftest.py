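import numpy as np
import pytest

from cogposet import adni2_battery, aibl_battery, build_model
from cogposet.battery import BatterySpec, TestSpec
from cogposet.response import TestResponseDistributions


@pytest.fixture(scope="session")
def adni2():
    return adni2_battery()


@pytest.fixture(scope="session")
def aibl():
    return aibl_battery()


@pytest.fixture(scope="session")
def adni2_model(adni2):
    return build_model(adni2)


@pytest.fixture(scope="session")
def aibl_model(aibl):
    return build_model(aibl)


@pytest.fixture(scope="session")
def toy_battery():
    """One attention-only test: collapses the 64 profiles to two states."""
    return BatterySpec(tests=(TestSpec(name="probe", requires_att=True),), name="toy")


@pytest.fixture(scope="session")
def toy_model(toy_battery):
    return build_model(toy_battery)


STRONG_CAPABLE = np.array([0.1, 0.1, 0.1, 0.7])
STRONG_NONCAPABLE = np.array([0.7, 0.1, 0.1, 0.1])


def strong_dists(battery):
    """Known strongly separated response distributions for every test."""
    return {
        t.name: TestResponseDistributions(
            t.name, STRONG_CAPABLE.copy(), STRONG_NONCAPABLE.copy(), True, 1, 1
        )
        for t in battery
    }


@pytest.fixture(scope="session")
def adni2_strong_dists(adni2):
    return strong_dists(adni2)
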