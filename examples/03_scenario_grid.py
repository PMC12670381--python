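"""The weighted behavioral scenario grid.

Six axes — hood use, stove-use intensity, occupancy, windspeed, window
schedule, ambient temperature — form a factorial grid; each scenario's
weight is the product of its level prevalences. Four axes are geography
independent (180 scenarios); adding the climate-conditioned window axis
gives 540 per climate band; the full grid is 2,160 per floorplan.
"""

from resno2.scenarios import (
    GEOGRAPHY_INDEPENDENT,
    build_grid,
    default_axes,
    temperature_conditioned_grid,
)

axes = default_axes()
core = build_grid([a for a in axes if a.name in GEOGRAPHY_INDEPENDENT])
cold = temperature_conditioned_grid(axes, "cold")
warm = temperature_conditioned_grid(axes, "warm")
full = build_grid(axes)

print(f"geography-independent core: {len(core)} scenarios (4 hood x 3 stove x 5 occupancy x 3 wind)")
print(f"per climate band:           {len(cold)} scenarios (core x 3 window schedules)")
print(f"full grid per floorplan:    {len(full)} scenarios")
print(f"24-floorplan library:       {24 * len(full)} scenarios")
print(f"weights sum to 1: cold {sum(s.weight for s in cold):.12f}, full {sum(s.weight for s in full):.12f}")

closed_cold = sum(s.weight for s in cold if s.level("window_schedule") == "closed")
closed_warm = sum(s.weight for s in warm if s.level("window_schedule") == "closed")
print(f"windows-closed prevalence: {closed_cold:.2f} in cold climates vs {closed_warm:.2f} in warm")
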