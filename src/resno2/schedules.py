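"""Turn scenario payloads into concrete 144-interval daily schedules.

Bridges the scenario grid (behavioral level payloads) and the simulator
(per-interval emission, window, and occupancy schedules). All schedules are
deterministic functions of the payload so a scenario maps to exactly one
modeled day per day type.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np

from .multizone import N_INTERVALS, OUTDOORS, Floorplan, SourceSchedule

#: Average burner emission rate while on, mg NO2/h (just-above-medium heat).
BURNER_EMISSION_MG_H = 48.0

#: Meal anchor start times as interval indices (breakfast, lunch, dinner).
MEAL_STARTS = (7 * 6 + 3, 12 * 6, 18 * 6)  # 07:30, 12:00, 18:00

#: Fraction of daily cooking at each meal.
MEAL_SHARES = (0.2, 0.3, 0.5)


def cooking_intervals(daily_emission_mg: float, burner_mg_h: float = BURNER_EMISSION_MG_H) -> np.ndarray:
    """Per-interval emission (mg/h) placing the day's cooking around meals.

    Total burner-on time is daily mass / burner rate, split across the three
    meal anchors; partial intervals get a proportionally reduced rate so the
    daily mass integrates exactly.
    """
    emission = np.zeros(N_INTERVALS)
    if daily_emission_mg <= 0:
        return emission
    total_hours = daily_emission_mg / burner_mg_h
    for start, share in zip(MEAL_STARTS, MEAL_SHARES):
        hours = total_hours * share
        n_full = int(hours * 6)  # full 10-min intervals
        remainder = hours * 6 - n_full
        for j in range(n_full):
            emission[(start + j) % N_INTERVALS] += burner_mg_h
        if remainder > 0:
            emission[(start + n_full) % N_INTERVALS] += burner_mg_h * remainder
    return emission


def build_source_schedule(
    floorplan: Floorplan,
    daily_emission_mg: float,
    capture_efficiency: float,
    hood_used: bool,
) -> SourceSchedule:
    emission = cooking_intervals(daily_emission_mg)
    return SourceSchedule(
        zone_id=floorplan.kitchen_id,
        emission_mg_h=emission,
        capture_efficiency=capture_efficiency if hood_used else 0.0,
        hood_on=(emission > 0) if hood_used else np.zeros(N_INTERVALS, dtype=bool),
    )


def build_window_schedule(open_hours: float) -> np.ndarray:
    """Boolean whole-house window-open schedule.

    ``open_hours`` of 0 keeps windows closed; 24 keeps them open; anything
    in between opens windows around the midday/evening cooking block
    (windows are opened during and after cooking).
    """
    sched = np.zeros(N_INTERVALS, dtype=bool)
    if open_hours <= 0:
        return sched
    if open_hours >= 24:
        return ~sched
    n_open = int(round(open_hours * 6))
    # split between lunch and dinner blocks
    half = n_open // 2
    sched[MEAL_STARTS[1] : MEAL_STARTS[1] + half] = True
    sched[MEAL_STARTS[2] : MEAL_STARTS[2] + (n_open - half)] = True
    return sched


def build_occupancy_schedule(
    floorplan: Floorplan, kitchen_minutes: float, outdoor_hours: float
) -> List[str]:
    """Zone-per-interval occupancy for a representative occupant.

    Nights (23:00–07:00) in a bedroom; ``kitchen_minutes`` split across the
    meal anchors; ``outdoor_hours`` as a midday outdoor block; the rest of
    the day in the living room (or the kitchen's neighbor when the plan has
    no living room).
    """
    bedroom = next((z.zone_id for z in floorplan.zones if z.zone_kind == "bedroom"), None)
    living = next((z.zone_id for z in floorplan.zones if z.zone_kind == "living"), None)
    kitchen = floorplan.kitchen_id
    default = living or bedroom or kitchen
    night = bedroom or default

    sched = [default] * N_INTERVALS
    for i in range(N_INTERVALS):
        hour = i / 6.0
        if hour >= 23.0 or hour < 7.0:
            sched[i] = night

    # outdoor block starting 13:00 (after lunch cooking)
    n_out = int(round(outdoor_hours * 6))
    start_out = 13 * 6
    for j in range(n_out):
        sched[(start_out + j) % N_INTERVALS] = OUTDOORS

    # kitchen time across meals (occupant cooks, so kitchen overrides outdoor)
    n_kitchen = max(0, int(round(kitchen_minutes / 10.0)))
    shares = np.array(MEAL_SHARES)
    per_meal = np.round(n_kitchen * shares).astype(int)
    # fix rounding so total matches
    while per_meal.sum() > n_kitchen:
        per_meal[np.argmax(per_meal)] -= 1
    while per_meal.sum() < n_kitchen:
        per_meal[np.argmax(shares)] += 1
    for start, count in zip(MEAL_STARTS, per_meal):
        for j in range(count):
            sched[(start + j) % N_INTERVALS] = kitchen
    return sched


def day_type_emissions(
    daily_emission_mg: float, day_types: Tuple[Tuple[str, float, float], ...]
) -> List[Tuple[str, float, float]]:
    """Expand a stove-use level into (label, days/week, daily mg) day types."""
    return [(label, days, daily_emission_mg * scale) for label, days, scale in day_types]
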