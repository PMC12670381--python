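"""Weighted factorial scenario grids over occupant behavior and environment.

Exposure days are modeled over six axes: range-hood use, stove-use
intensity, room occupancy, ground windspeed, window-opening schedule, and
ambient temperature. Four of these (hood, stove, occupancy, windspeed) are
treated as geography independent — 4 × 3 × 5 × 3 = 180 scenarios per
floorplan — while window schedules and ambient temperature vary with
climate; the full grid is 4 × 3 × 5 × 3 × 3 × 4 = 2,160 scenarios per
floorplan (51,840 over a 24-floorplan library). Each axis level carries a
prevalence weight; a scenario's weight is the product of its level weights,
renormalized over the grid.

Within a stove-use level, days of the week are not identical: a level is a
weekly pattern of day types (e.g. light/typical/heavy cooking days weighted
2/7, 4/7, 1/7), combined downstream by :func:`resno2.exposure.weekly_expectation`.

Default level values and weights here are the package's synthetic behavioral
assumptions (kitchen-time percentiles near 5/35/150 min/day, hood-not-used
probability 0.64, daily stove NO2 emissions of roughly 0.64/31/199 mg/day at
the 5th/50th/95th use percentiles); every payload is overridable through
the axis constructors or a YAML config.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

AXIS_NAMES = (
    "hood_use",
    "stove_use",
    "occupancy",
    "windspeed",
    "window_schedule",
    "ambient_temperature",
)

#: Axes whose level weights do not vary with geography/climate.
GEOGRAPHY_INDEPENDENT = ("hood_use", "stove_use", "occupancy", "windspeed")

TEMPERATURE_BANDS = ("cold", "warm")  # <15 °C vs ≥15 °C climate mix


class GridError(ValueError):
    pass


@dataclass(frozen=True)
class AxisLevel:
    label: str
    payload: dict
    weight: float

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise GridError(f"level {self.label!r}: negative weight")


@dataclass
class ScenarioAxis:
    name: str
    levels: List[AxisLevel]

    def __post_init__(self) -> None:
        if self.name not in AXIS_NAMES:
            raise GridError(f"unknown axis {self.name!r}")
        if not self.levels:
            raise GridError(f"axis {self.name!r} has no levels")
        total = sum(l.weight for l in self.levels)
        if total <= 0:
            raise GridError(f"axis {self.name!r}: weights sum to {total}")
        if abs(total - 1.0) > 1e-9:
            self.levels = [
                AxisLevel(l.label, l.payload, l.weight / total) for l in self.levels
            ]


@dataclass(frozen=True)
class Scenario:
    """One cell of the factorial grid: a level label per axis plus weight."""

    levels: Tuple[Tuple[str, str], ...]  # (axis, level label) pairs
    payload: dict
    weight: float

    def level(self, axis: str) -> str:
        return dict(self.levels)[axis]


@dataclass
class DayTypeWeighting:
    """Weekly prevalence of day types within one stove-use level."""

    days: List[Tuple[str, float]]  # (day label, days per week)

    def __post_init__(self) -> None:
        total = sum(d for _, d in self.days)
        if abs(total - 7.0) > 1e-9:
            raise GridError(f"days per week must sum to 7, got {total}")


def weekly_weights(day_weighting: DayTypeWeighting) -> np.ndarray:
    """Normalized day-type weights: days/7."""
    return np.array([d for _, d in day_weighting.days]) / 7.0


def build_grid(axes: Sequence[ScenarioAxis]) -> List[Scenario]:
    """Full cartesian product of axis levels with product weights.

    The number of scenarios equals the product of level counts exactly and
    the weights sum to 1 (each axis's weights are normalized, so the
    product-weight renormalization is a no-op up to rounding).
    """
    names = [a.name for a in axes]
    if len(set(names)) != len(names):
        raise GridError("duplicate axes")
    scenarios = []
    for combo in itertools.product(*[a.levels for a in axes]):
        payload: dict = {}
        for axis, level in zip(axes, combo):
            payload[axis.name] = level.payload
        w = float(np.prod([l.weight for l in combo]))
        scenarios.append(
            Scenario(
                levels=tuple((a.name, l.label) for a, l in zip(axes, combo)),
                payload=payload,
                weight=w,
            )
        )
    total = sum(s.weight for s in scenarios)
    return [Scenario(s.levels, s.payload, s.weight / total) for s in scenarios]


def temperature_conditioned_grid(
    axes: Sequence[ScenarioAxis], temperature_band: str
) -> List[Scenario]:
    """180-scenario geography-independent core × 3 window schedules = 540.

    Window-schedule weights are conditioned on the climate band (people
    open windows more in warm climates); the geography-independent core
    weights are untouched by the band.
    """
    if temperature_band not in TEMPERATURE_BANDS:
        raise GridError(f"unknown temperature band {temperature_band!r}")
    by_name = {a.name: a for a in axes}
    core = [by_name[n] for n in GEOGRAPHY_INDEPENDENT]
    window = window_schedule_axis(temperature_band)
    return build_grid(core + [window])


# ---------------------------------------------------------------------------
# Default axes
# ---------------------------------------------------------------------------

def hood_use_axis(
    not_used_probability: float = 0.64,
    capture_levels: Sequence[Tuple[float, float]] = ((0.3, 0.5), (0.55, 0.33), (0.8, 0.17)),
) -> ScenarioAxis:
    """Four hood-use levels: not used (or recirculating, CE = 0) plus three
    capture-efficiency tiers splitting the remaining probability."""
    rest = 1.0 - not_used_probability
    levels = [AxisLevel("no_hood", {"capture_efficiency": 0.0, "used": False}, not_used_probability)]
    for ce, share in capture_levels:
        levels.append(
            AxisLevel(f"hood_ce{int(ce * 100)}", {"capture_efficiency": ce, "used": True}, rest * share)
        )
    return ScenarioAxis("hood_use", levels)


#: Default weekly day-type pattern: 2 light, 4 typical, 1 heavy cooking day,
#: with daily emissions scaled 0.5/1.0/2.0 so the weekly mean is the level's
#: nominal daily mass.
DEFAULT_DAY_TYPES: Tuple[Tuple[str, float, float], ...] = (
    ("light", 2.0, 0.5),
    ("typical", 4.0, 1.0),
    ("heavy", 1.0, 2.0),
)


def stove_use_axis(
    heavy_week_weight: float = 0.10,
    daily_mass_mg: Dict[str, float] | None = None,
) -> ScenarioAxis:
    """Three stove-use intensity levels (5th/50th/95th percentile of gas
    burned) with nominal daily NO2 masses and a weekly day-type pattern.

    ``heavy_week_weight`` is the prevalence of 95th-percentile use weeks
    (default 10%, with a 5% sensitivity setting used downstream)."""
    daily_mass_mg = daily_mass_mg or {"p5": 0.64, "p50": 31.0, "p95": 199.0}
    w95 = heavy_week_weight
    weights = {"p5": (1 - w95) * 0.28, "p50": (1 - w95) * 0.72, "p95": w95}
    levels = []
    for label in ("p5", "p50", "p95"):
        levels.append(
            AxisLevel(
                label,
                {
                    "daily_emission_mg": daily_mass_mg[label],
                    "day_types": DEFAULT_DAY_TYPES,
                    "heavy_week": label == "p95",
                },
                weights[label],
            )
        )
    return ScenarioAxis("stove_use", levels)


def occupancy_axis(
    kitchen_minutes: Sequence[Tuple[str, float, float, float]] = (
        # (label, kitchen min/day, outdoor h/day, weight)
        ("p5", 5.0, 8.0, 0.10),
        ("p25", 15.0, 3.0, 0.20),
        ("p50", 35.0, 2.0, 0.40),
        ("p75", 75.0, 1.0, 0.20),
        ("p95", 150.0, 0.5, 0.10),
    ),
) -> ScenarioAxis:
    """Five occupancy levels spanning kitchen-time percentiles (≈5, 35, and
    150 min/day at the 5th/50th/95th) and time spent outdoors."""
    levels = [
        AxisLevel(label, {"kitchen_minutes": km, "outdoor_hours": oh}, w)
        for label, km, oh, w in kitchen_minutes
    ]
    return ScenarioAxis("occupancy", levels)


def windspeed_axis(
    levels: Sequence[Tuple[str, float, float]] = (
        ("calm", 1.0, 0.30),
        ("moderate", 3.5, 0.50),
        ("windy", 7.0, 0.20),
    ),
) -> ScenarioAxis:
    return ScenarioAxis(
        "windspeed",
        [AxisLevel(lab, {"windspeed": v}, w) for lab, v, w in levels],
    )


#: Window-opening weights by climate band: cold climates keep windows closed
#: far more often.
WINDOW_WEIGHTS = {
    "cold": {"closed": 0.80, "open_4h": 0.15, "open_all_day": 0.05},
    "warm": {"closed": 0.40, "open_4h": 0.40, "open_all_day": 0.20},
}


def window_schedule_axis(temperature_band: str = "cold") -> ScenarioAxis:
    if temperature_band not in WINDOW_WEIGHTS:
        raise GridError(f"unknown temperature band {temperature_band!r}")
    w = WINDOW_WEIGHTS[temperature_band]
    payloads = {
        "closed": {"open_hours": 0.0},
        "open_4h": {"open_hours": 4.0},
        "open_all_day": {"open_hours": 24.0},
    }
    return ScenarioAxis(
        "window_schedule",
        [AxisLevel(lab, payloads[lab], w[lab]) for lab in ("closed", "open_4h", "open_all_day")],
    )


def ambient_temperature_axis(
    levels: Sequence[Tuple[str, float, float]] = (
        ("winter", -5.0, 0.20),
        ("cool", 8.0, 0.30),
        ("mild", 18.0, 0.30),
        ("hot", 28.0, 0.20),
    ),
) -> ScenarioAxis:
    return ScenarioAxis(
        "ambient_temperature",
        [AxisLevel(lab, {"ambient_temperature": t}, w) for lab, t, w in levels],
    )


def default_axes(
    heavy_week_weight: float = 0.10,
    temperature_band: str = "cold",
    hood_not_used: float = 0.64,
) -> List[ScenarioAxis]:
    """The six default axes with level counts (4, 3, 5, 3, 3, 4)."""
    return [
        hood_use_axis(not_used_probability=hood_not_used),
        stove_use_axis(heavy_week_weight=heavy_week_weight),
        occupancy_axis(),
        windspeed_axis(),
        window_schedule_axis(temperature_band),
        ambient_temperature_axis(),
    ]


def grid_to_frame(scenarios: Sequence[Scenario]):
    """One row per scenario: axis level labels plus weight."""
    import pandas as pd

    rows = []
    for i, s in enumerate(scenarios):
        row = {"scenario_id": i}
        row.update({axis: label for axis, label in s.levels})
        row["weight"] = s.weight
        rows.append(row)
    return pd.DataFrame(rows)
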