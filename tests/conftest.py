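import pytest

import roar


@pytest.fixture(scope="session")
def example_table():
    """Simulated RR>1 example: 70/30 events in the experimental arm vs 50/50."""
    return roar.DichotomousTable(70, 30, 50, 50)


@pytest.fixture(scope="session")
def mirror_table():
    """Arm-swapped twin of the RR>1 example (RR<1)."""
    return roar.DichotomousTable(50, 50, 70, 30)


@pytest.fixture(scope="session")
def meta_table():
    """Pooled vitamin-D meta-analysis table (five RCTs, n=39,197)."""
    return roar.DichotomousTable(397, 19204, 468, 19128)


@pytest.fixture(scope="session")
def nu05():
    return roar.critical_value(0.05)


@pytest.fixture(scope="session")
def example_surface(example_table, nu05):
    return roar.RoarSurface(example_table, roar.Direction.RR_GT_1, nu05)


@pytest.fixture(scope="session")
def meta_surface(meta_table, nu05):
    return roar.RoarSurface(meta_table, roar.Direction.RR_LT_1, nu05)


@pytest.fixture(scope="session")
def example_result(example_table):
    return roar.analyze(example_table)


@pytest.fixture(scope="session")
def meta_result(meta_table):
    return roar.analyze(meta_table)


@pytest.fixture(scope="session")
def fixture_tables():
    """25 seeded random significant tables for property checks."""
    return [roar.random_significant_table(seed) for seed in range(25)]


def coord_tol(reference: float) -> float:
    """Tolerance for FOCK coordinates and intercepts: max(0.15 abs, 2% rel)."""
    return max(0.15, 0.02 * abs(reference))
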