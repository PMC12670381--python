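"""Occupant exposure statistics from zone concentration series.

An occupant moving between zones (or outdoors) experiences, at each 10-min
interval, the concentration of the zone they occupy. From the resulting
144-value personal series:

* chronic (long-term) exposure is the 24-h mean, interpreted as the
  long-run average if the modeled day repeated indefinitely;
* acute (short-term) exposure is the maximum hour-averaged value — the
  largest mean over any six consecutive intervals fully inside the day
  (139 complete windows; no wraparound, the day stands alone).

Day-level values are combined into scenario-level expectations with weekly
day-type weights (e.g. 2/7 light, 4/7 typical, 1/7 heavy cooking days), and
acute exceedances of a guideline threshold convert to days/year by × 365.

The infiltration tracer channel scales to outdoor-attributable NO2 as
``OANO2 = OACONTA × [NO2]_outdoor / 100``, the tracer's outdoor level being
pinned at 100 ppbv so its exposure reads as a percent infiltration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .multizone import (
    CONTA_OUTDOOR_PPBV,
    N_INTERVALS,
    OUTDOORS,
    ConcentrationSeries,
)

HOUR_WINDOW = 6  # 10-min intervals per hour

#: Outdoor concentration credited to an occupant while outdoors, per species.
#: Stove NO2 does not exist outdoors; the tracers equal their outdoor level.
OUTDOOR_VALUE = {"no2_stove": 0.0, "conta": CONTA_OUTDOOR_PPBV, "contb": CONTA_OUTDOOR_PPBV}


class ExposureError(ValueError):
    pass


def _check_series(series: np.ndarray) -> np.ndarray:
    series = np.asarray(series, dtype=float)
    if series.shape != (N_INTERVALS,):
        raise ExposureError(f"expected a length-{N_INTERVALS} series, got {series.shape}")
    return series


def person_series(
    series: ConcentrationSeries,
    occupancy: Sequence[str],
    species: str,
) -> np.ndarray:
    """Personal 144-value exposure series for one species.

    ``occupancy`` gives the occupied zone (or ``OUTDOORS``) per interval.
    Outdoor intervals contribute the species' outdoor concentration: zero
    for stove NO2, the 100-ppbv reference for the tracers.
    """
    if len(occupancy) != N_INTERVALS:
        raise ExposureError(f"occupancy schedule must have length {N_INTERVALS}")
    zone_index = {z: i for i, z in enumerate(series.zone_ids)}
    values = series.values[species]
    out = np.empty(N_INTERVALS)
    for i, zone in enumerate(occupancy):
        if zone == OUTDOORS:
            out[i] = OUTDOOR_VALUE[species]
        elif zone in zone_index:
            out[i] = values[zone_index[zone], i]
        else:
            raise ExposureError(f"occupancy references unknown zone {zone!r}")
    return out


def chronic_exposure(series: np.ndarray) -> float:
    """24-h mean of the 144-value personal series (ppbv)."""
    return float(_check_series(series).mean())


def acute_exposure(series: np.ndarray) -> float:
    """Maximum hour-averaged exposure: max over the 139 complete 6-interval
    windows of the window mean (ppbv)."""
    s = _check_series(series)
    windows = np.lib.stride_tricks.sliding_window_view(s, HOUR_WINDOW)
    return float(windows.mean(axis=1).max())


def hourly_series(series: np.ndarray) -> np.ndarray:
    """All 139 rolling hour-averaged values."""
    s = _check_series(series)
    return np.lib.stride_tricks.sliding_window_view(s, HOUR_WINDOW).mean(axis=1)


@dataclass(frozen=True)
class PersonDayExposure:
    """Chronic and acute exposure for one modeled person-day."""

    chron_day: float
    acute_day: float

    def __post_init__(self) -> None:
        if self.chron_day < 0 or self.acute_day < 0:
            raise ExposureError("exposures must be >= 0")
        if self.chron_day > self.acute_day + 1e-9:
            raise ExposureError("chronic exposure cannot exceed acute exposure")


def person_day(series: np.ndarray) -> PersonDayExposure:
    return PersonDayExposure(chron_day=chronic_exposure(series), acute_day=acute_exposure(series))


@dataclass(frozen=True)
class ScenarioExposure:
    """Week-expected chronic/acute exposure for one scenario, with weight."""

    chron: float
    acute: float
    weight: float


@dataclass(frozen=True)
class OutdoorScaling:
    """Scale an infiltration-tracer exposure to outdoor-attributable NO2."""

    conta_exposure: float
    outdoor_no2: float
    conta_reference: float = CONTA_OUTDOOR_PPBV

    def __post_init__(self) -> None:
        if not 0.0 <= self.conta_exposure <= self.conta_reference + 1e-9:
            raise ExposureError(
                f"tracer exposure {self.conta_exposure} outside [0, {self.conta_reference}]"
            )
        if self.outdoor_no2 < 0:
            raise ExposureError("outdoor NO2 must be >= 0")


def outdoor_attributable(scaling: OutdoorScaling) -> float:
    """OANO2 = OACONTA × [NO2] / [CONTA] (ppbv)."""
    return scaling.conta_exposure * scaling.outdoor_no2 / scaling.conta_reference


def weekly_expectation(
    day_exposures: Sequence[PersonDayExposure],
    day_weights: Sequence[float],
    scenario_weight: float = 1.0,
) -> ScenarioExposure:
    """Weight day-type exposures by weekly prevalence (e.g. 2/7, 4/7, 1/7)."""
    if len(day_exposures) != len(day_weights):
        raise ExposureError("day exposures and weights must align")
    w = np.asarray(day_weights, dtype=float)
    if abs(w.sum() - 1.0) > 1e-9:
        raise ExposureError("day weights must be normalized")
    chron = float(sum(d.chron_day * wi for d, wi in zip(day_exposures, w)))
    acute = float(sum(d.acute_day * wi for d, wi in zip(day_exposures, w)))
    return ScenarioExposure(chron=chron, acute=acute, weight=scenario_weight)


def exceedance_fraction(
    values: Sequence[float], weights: Sequence[float], threshold: float
) -> float:
    """Weighted fraction of values at or above ``threshold`` (indicator
    f(conc, threshold) = 1 iff conc ≥ threshold)."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise ExposureError("no values")
    if not np.isclose(w.sum(), 1.0, atol=1e-9):
        w = w / w.sum()
    return float(w[v >= threshold].sum())


def exceedance_days_per_year(
    day_results: Sequence[Tuple[float, float]],
    threshold: float,
    heavy_mask: Optional[Sequence[bool]] = None,
    heavy_week_weights: Tuple[float, float] = (0.10, 0.05),
) -> Tuple[float, float]:
    """Expected days/year with acute exposure above ``threshold``.

    ``day_results`` are (acute_day, weight) pairs; the weighted fraction of
    modeled days above the threshold is multiplied by 365. Because the
    prevalence of heavy-use (95th percentile) weeks is the dominant
    uncertainty, the calculation is repeated with that prevalence set to
    each value in ``heavy_week_weights`` (default 10% and 5%), reweighting
    the ``heavy_mask`` days; the result is the (low, high) range. Without a
    mask the plain fraction is used for both ends.
    """
    if threshold <= 0:
        raise ExposureError("threshold must be > 0")
    if len(day_results) == 0:
        raise ExposureError("no day results")
    acute = np.array([a for a, _ in day_results], dtype=float)
    w = np.array([wi for _, wi in day_results], dtype=float)
    w = w / w.sum()

    if heavy_mask is None:
        days = float(w[acute > threshold].sum() * 365.0)
        return (days, days)

    heavy = np.asarray(heavy_mask, dtype=bool)
    if heavy.shape != acute.shape:
        raise ExposureError("heavy mask must align with day results")
    results = []
    for hw in heavy_week_weights:
        w2 = w.copy()
        wh, wl = w[heavy].sum(), w[~heavy].sum()
        if wh > 0:
            w2[heavy] *= hw / wh
        if wl > 0:
            w2[~heavy] *= (1.0 - hw) / wl
        results.append(float(w2[acute > threshold].sum() * 365.0))
    return (min(results), max(results))
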