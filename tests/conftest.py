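import numpy as np
import pytest

from resno2.multizone import OUTDOORS, FlowPath, Floorplan, SimConfig, Zone


@pytest.fixture
def still_air_config():
    """No wind, no indoor/outdoor temperature difference: zero envelope driver."""
    return SimConfig(ambient_temperature=20.0, indoor_temperature=20.0, windspeed=0.0)


@pytest.fixture
def single_zone_factory():
    """Build a one-zone dwelling whose air-exchange rate is exactly k at the
    given config's envelope driver."""

    def build(k: float, config: SimConfig, volume: float = 100.0) -> Floorplan:
        driver = config.envelope_driver()
        if driver <= 0:
            raise ValueError("config has zero driver; choose wind or ΔT")
        return Floorplan(
            floorplan_id=f"one-zone-k{k}",
            zones=[Zone("kitchen", volume, "kitchen", has_window=True)],
            paths=[FlowPath("kitchen", OUTDOORS, "leakage", k * volume / driver)],
        )

    return build


@pytest.fixture
def three_zone_floorplan():
    zones = [
        Zone("kitchen", 40.0, "kitchen", has_window=True),
        Zone("living", 80.0, "living", has_window=True),
        Zone("bedroom1", 50.0, "bedroom", has_window=True),
    ]
    paths = [
        FlowPath("kitchen", "living", "interzone_opening", 90.0),
        FlowPath("living", "bedroom1", "interzone_opening", 70.0),
        FlowPath("kitchen", OUTDOORS, "leakage", 120.0),
        FlowPath("living", OUTDOORS, "leakage", 200.0),
        FlowPath("bedroom1", OUTDOORS, "leakage", 100.0),
        FlowPath("kitchen", OUTDOORS, "open_window", 400.0),
        FlowPath("living", OUTDOORS, "open_window", 400.0),
    ]
    return Floorplan("three-zone", zones, paths)


@pytest.fixture
def sealed_floorplan():
    """Two zones with interior mixing but a zero-driver envelope (see
    still_air_config): no outdoor exchange."""
    zones = [
        Zone("kitchen", 60.0, "kitchen", has_window=False),
        Zone("living", 90.0, "living", has_window=False),
    ]
    paths = [
        FlowPath("kitchen", "living", "interzone_opening", 100.0),
        FlowPath("kitchen", OUTDOORS, "leakage", 50.0),
    ]
    return Floorplan("sealed", zones, paths)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
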