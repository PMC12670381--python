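"""From concentration series to chronic and acute personal exposure.

An occupant's 144-interval personal series yields: chronic exposure (the
24-h mean), acute exposure (the worst rolling 1-h mean), the scaling of
tracer infiltration to outdoor-attributable NO2, weekly day-type
expectations, and guideline exceedance days per year.
"""

import numpy as np

from resno2.exposure import (
    OutdoorScaling,
    PersonDayExposure,
    acute_exposure,
    chronic_exposure,
    exceedance_days_per_year,
    outdoor_attributable,
    weekly_expectation,
)

# a stylized cooking day: two meals raise kitchen NO2 to 80 and 240 ppbv
series = np.zeros(144)
series[72:76] = 80.0    # lunch: 40 min
series[108:117] = 240.0  # dinner: 90 min

chron = chronic_exposure(series)
acute = acute_exposure(series)
print(f"chronic (24-h mean) exposure: {chron:.1f} ppbv")
print(f"acute (max 1-h mean) exposure: {acute:.1f} ppbv -> exceeds the ~100 ppbv 1-h benchmarks")

oa = outdoor_attributable(OutdoorScaling(conta_exposure=45.0, outdoor_no2=8.0))
print(f"45% infiltration at 8 ppbv outdoors: {oa:.1f} ppbv outdoor-attributable")

days = [PersonDayExposure(1.0, 30.0), PersonDayExposure(3.0, 120.0), PersonDayExposure(8.0, 400.0)]
week = weekly_expectation(days, [2 / 7, 4 / 7, 1 / 7])
print(f"weekly expectation over light/typical/heavy days (2/7, 4/7, 1/7): "
      f"chronic {week.chron:.2f} ppbv, acute {week.acute:.1f} ppbv")

day_results = [(30.0, 0.45), (80.0, 0.45), (400.0, 0.10)]
low, high = exceedance_days_per_year(
    day_results, threshold=100.0, heavy_mask=[False, False, True], heavy_week_weights=(0.10, 0.05)
)
print(f"days/year above 100 ppbv 1-h: {low:.0f}-{high:.0f} "
      "(range from 5% vs 10% heavy-week prevalence; 2% of days = 7/year)")
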