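import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

from sympatry.solar import sun_events
from sympatry.synthetic import SimDesign, simulate_activity, simulate_occupancy

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_bundle():
    """A small full survey: 25 stations, 4 years, survey-scale detection."""
    design = SimDesign(seed=11, n_stations=25)
    prs, hist, truth = simulate_occupancy(design)
    return design, prs, hist, truth


@pytest.fixture(scope="session")
def activity_bundle():
    """Activity events for all five species with truth overlaps."""
    design = SimDesign(seed=5)
    events, truth = simulate_activity(design, n_events=150)
    return design, events, truth


@pytest.fixture(scope="session")
def summer_anchors():
    """Mid-summer anchors at the arid-study latitude (29.4 N, 109.1 W)."""
    return sun_events(dt.date(2010, 6, 15), 29.4, -109.1, -7.0)
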