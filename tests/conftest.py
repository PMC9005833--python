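import pytest

from capacity_cea import (
    ArmProfile,
    CalibrationTargets,
    DiscountSpec,
    TestingParameters,
    calibrate_fixture,
    solve_consistency_system,
)


@pytest.fixture(scope="session")
def targets():
    return CalibrationTargets()


@pytest.fixture(scope="session")
def consistency(targets):
    return solve_consistency_system(targets)


@pytest.fixture(scope="session")
def fixture():
    """The calibrated synthetic baseline fixture (shared across tests)."""
    return calibrate_fixture()


@pytest.fixture(scope="session")
def discount():
    return DiscountSpec()


@pytest.fixture
def crizotinib_arm():
    return ArmProfile(
        name="crizotinib",
        pfs_median=8.4,
        os_median=21.8,
        utility_pf=0.75,
        utility_pd=0.55,
        cost_pf_cycle=2500.0,
        cost_pd_cycle=400.0,
    )


@pytest.fixture
def docetaxel_arm():
    return ArmProfile(
        name="docetaxel",
        pfs_median=3.0,
        os_median=8.0,
        utility_pf=0.75,
        utility_pd=0.55,
        cost_pf_cycle=600.0,
        cost_pd_cycle=400.0,
    )


@pytest.fixture
def test_params():
    return TestingParameters()
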