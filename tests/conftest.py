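import pytest
from hypothesis import settings

from gpcoverage import Panel, ScenarioConfig, UnitYearRecord

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

#: National aggregates of the 2009 and 2023 endpoints as published:
#: 10.5M enrolled in 2023 after a 793k decline, 1.8M -> 1.7M unassigned,
#: 5 650 -> 5 395 GP FTE.
NATIONAL_2009 = dict(enrolled=11_293_000, unassigned=1_800_000, gp_fte=5650.0)
NATIONAL_2023 = dict(enrolled=10_500_000, unassigned=1_700_000, gp_fte=5395.0)

FIXED_SEED = 2009


@pytest.fixture
def national_records():
    rec0 = UnitYearRecord("NATIONAL", "NATIONAL", 2009, **NATIONAL_2009)
    rec1 = UnitYearRecord("NATIONAL", "NATIONAL", 2023, **NATIONAL_2023)
    return rec0, rec1


@pytest.fixture
def small_panel():
    """Two units in one region plus one in another, over two years."""
    recs = [
        UnitYearRecord("A", "R1", 2020, 1000, 100, 2.0, elderly_share=0.10),
        UnitYearRecord("B", "R1", 2020, 3000, 500, 5.0, elderly_share=0.40),
        UnitYearRecord("C", "R2", 2020, 2000, 300, 4.0),
        UnitYearRecord("A", "R1", 2021, 1100, 150, 2.0, elderly_share=0.10),
        UnitYearRecord("B", "R1", 2021, 2900, 450, 5.5, elderly_share=0.40),
        UnitYearRecord("C", "R2", 2021, 2100, 280, 4.2),
    ]
    return Panel.from_records(recs)


@pytest.fixture(scope="session")
def default_config():
    return ScenarioConfig(seed=FIXED_SEED)


@pytest.fixture(scope="session")
def default_panel(default_config):
    from gpcoverage import generate_panel

    return generate_panel(default_config)
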